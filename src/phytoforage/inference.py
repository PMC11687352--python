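"""Behavioural-state segmentation and step-selection inference from tracks.

The chain mirrors the standard movement-ecology workflow:

1. :func:`track_to_steps` turns a position track into (step length, turn
   angle) pairs with start/end tile classes.
2. :func:`fit_hmm` fits a two-state hidden Markov model with gamma
   step-length and von Mises turn-angle emissions by EM (forward-backward),
   separating an "exploring" state (long steps) from a "resting/feeding"
   state (~10x shorter steps).
3. :func:`sample_available_steps` builds the case-control strata of
   integrated step-selection analysis (iSSA): each observed step is paired
   with A available steps drawn from a tentative gamma kernel with uniform
   turn angles.
4. :func:`fit_issa` fits the conditional-logistic likelihood by Newton
   iteration and converts the movement-covariate coefficients into an
   updated gamma kernel per start-tile class, from which the behavioural
   parameters are derived: arrestment a-hat as the ratio of updated scales
   (more-toxic start over less-toxic start) and immigration omega-hat as
   the exponentiated coefficient of the less-toxic-destination indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .landscape import ToxinLandscape
from .movement import GammaStepDist
from .simulate import Track

__all__ = [
    "track_to_steps",
    "HmmFit",
    "fit_hmm",
    "viterbi_path",
    "fit_tentative_gamma",
    "sample_available_steps",
    "conditional_loglik",
    "IssaFit",
    "fit_issa",
    "fit_issa_for_track",
    "ISSA_COVARIATES",
]

ISSA_COVARIATES = ("dest_less", "l", "log_l", "l_x_start_less", "log_l_x_start_less", "cos_theta")


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def track_to_steps(track: Track, landscape: ToxinLandscape) -> pd.DataFrame:
    """First-difference a track into per-step records.

    Columns: t (step index, 1-based), x_start/y_start/x_end/y_end, l (cm),
    heading (absolute direction, NaN for zero-length steps), theta (signed
    turn, counterclockwise positive, NaN where the current or reference
    heading is undefined), start_more/end_more (tile classes).  The turn at
    step t is measured against the most recent defined heading, so pauses
    do not destroy directional reference.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 positions to derive steps and turns")
    x, y = np.asarray(track.x_cm, float), np.asarray(track.y_cm, float)
    dx, dy = np.diff(x), np.diff(y)
    l = np.hypot(dx, dy)
    heading = np.where(l > 0, np.arctan2(dy, dx), np.nan)

    # reference heading: last defined heading strictly before each step
    ref = np.full(l.size, np.nan)
    last = np.nan
    for i in range(l.size):
        ref[i] = last
        if l[i] > 0:
            last = heading[i]
    theta = _wrap_angle(heading - ref)

    start_more = landscape.is_more_toxic_at(x[:-1], y[:-1])
    end_more = landscape.is_more_toxic_at(x[1:], y[1:])
    return pd.DataFrame(
        {
            "t": np.arange(1, l.size + 1),
            "x_start": x[:-1],
            "y_start": y[:-1],
            "x_end": x[1:],
            "y_end": y[1:],
            "l": l,
            "heading": heading,
            "theta": theta,
            "start_more": start_more,
            "end_more": end_more,
        }
    )


# ---------------------------------------------------------------------------
# Two-state HMM: gamma step lengths + von Mises turn angles
# ---------------------------------------------------------------------------

def _positive_floor(l: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace zero step lengths by half the minimum positive length."""
    pos = l[l > 0]
    if pos.size == 0:
        raise ValueError("all step lengths are zero")
    floor = 0.5 * pos.min()
    n_zero = int(np.sum(l <= 0))
    return np.where(l > 0, l, floor), n_zero


def _gamma_wmle(l: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE (shape, scale) by solving the digamma equation."""
    wsum = w.sum()
    m1 = float(np.sum(w * l) / wsum)
    mlog = float(np.sum(w * np.log(l)) / wsum)
    s = np.log(m1) - mlog
    if s <= 1e-12:
        return 1e3, m1 / 1e3  # near-degenerate: effectively deterministic
    f = lambda q: np.log(q) - special.digamma(q) - s
    q = optimize.brentq(f, 1e-6, 1e8)
    return float(q), float(m1 / q)


def _a1inv(r: float) -> float:
    """Inverse of the ratio I1/I0, the standard von Mises MLE approximation."""
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def _vonmises_wmle(theta: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted von Mises MLE (mu, kappa)."""
    wsum = w.sum()
    c = float(np.sum(w * np.cos(theta)) / wsum)
    s = float(np.sum(w * np.sin(theta)) / wsum)
    r = min(np.hypot(c, s), 1.0 - 1e-10)
    mu = float(np.arctan2(s, c))
    return mu, float(_a1inv(r))


@dataclass
class HmmFit:
    """A fitted two-state movement HMM.

    State 0 is the larger-mean-step "exploring" state, state 1 the
    "resting" state (ordering enforced after fitting).
    """

    gamma_q: np.ndarray
    gamma_sigma: np.ndarray
    vm_mu: np.ndarray
    vm_kappa: np.ndarray
    transmat: np.ndarray
    init: np.ndarray
    loglik: float
    loglik_history: np.ndarray
    converged: bool
    posteriors: np.ndarray = field(repr=False, default=None)
    path: np.ndarray = field(repr=False, default=None)
    n_zero_steps: int = 0

    state_names = ("exploring", "resting")

    @property
    def state_labels(self) -> np.ndarray:
        """Decoded labels as strings."""
        return np.asarray(self.state_names)[self.path]


def _emission_loglik(
    l: np.ndarray, theta: np.ndarray, q, sigma, mu, kappa
) -> np.ndarray:
    """(T, 2) per-observation emission log-likelihood.

    Turn angles contribute only where defined (NaNs add zero, so steps with
    no directional reference are judged on length alone).
    """
    T = l.size
    out = np.empty((T, 2))
    has_theta = np.isfinite(theta)
    for s in range(2):
        ll = stats.gamma.logpdf(l, a=q[s], scale=sigma[s])
        lt = np.zeros(T)
        lt[has_theta] = stats.vonmises.logpdf(theta[has_theta], kappa[s], loc=mu[s])
        out[:, s] = ll + lt
    return out


def _forward_backward(logb: np.ndarray, transmat: np.ndarray, init: np.ndarray):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    T, S = logb.shape
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    alpha = np.empty((T, S))
    c = np.empty(T)
    alpha[0] = init * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transmat) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, S))
    beta[-1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (transmat @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb / c[t + 1]) * transmat
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(logb.max(axis=1)))
    return loglik, gamma, xi_sum


def viterbi_path(logb: np.ndarray, transmat: np.ndarray, init: np.ndarray) -> np.ndarray:
    """Most-likely state path."""
    T, S = logb.shape
    log_t = np.log(transmat)
    delta = np.log(init) + logb[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_t
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(S)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def fit_hmm(
    steps: pd.DataFrame,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HmmFit:
    """Fit the two-state movement HMM by EM, best of seeded restarts.

    Each restart initializes the two states from a random quantile split of
    the step lengths; the restart with the highest log-likelihood wins.
    Decoding uses the most-likely (Viterbi) path.  States are re-ordered
    after fitting so state 0 has the larger mean step length.
    """
    if len(steps) < 3:
        raise ValueError("too few steps to fit a two-state model")
    l_raw = steps["l"].to_numpy(float)
    theta = steps["theta"].to_numpy(float)
    l, n_zero = _positive_floor(l_raw)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(restarts, 1)):
        split = rng.uniform(0.3, 0.7)
        thr = np.quantile(l, split)
        w_hi = (l > thr).astype(float) * 0.9 + 0.05
        w = np.column_stack([w_hi, 1.0 - w_hi])
        q = np.empty(2)
        sigma = np.empty(2)
        mu = np.zeros(2)
        kappa = np.full(2, 0.5)
        for s in range(2):
            q[s], sigma[s] = _gamma_wmle(l, w[:, s])
        stay = rng.uniform(0.8, 0.98)
        transmat = np.array([[stay, 1 - stay], [1 - stay, stay]])
        init = np.array([0.5, 0.5])

        prev = -np.inf
        history = []
        converged = False
        for _it in range(max_iter):
            logb = _emission_loglik(l, theta, q, sigma, mu, kappa)
            loglik, g, xi = _forward_backward(logb, transmat, init)
            history.append(loglik)
            if loglik - prev < tol and _it > 0:
                converged = True
                break
            prev = loglik
            # M-step
            init = g[0] / g[0].sum()
            transmat = xi / xi.sum(axis=1, keepdims=True)
            has_theta = np.isfinite(theta)
            for s in range(2):
                q[s], sigma[s] = _gamma_wmle(l, g[:, s])
                if has_theta.any():
                    mu[s], kappa[s] = _vonmises_wmle(
                        theta[has_theta], g[has_theta, s]
                    )
        if best is None or history[-1] > best[0]:
            best = (history[-1], q.copy(), sigma.copy(), mu.copy(), kappa.copy(),
                    transmat.copy(), init.copy(), np.array(history), converged)

    loglik, q, sigma, mu, kappa, transmat, init, history, converged = best
    if not converged:
        warnings.warn("EM did not converge; returning best iterate", stacklevel=2)

    # order states by mean step length, descending: state 0 = exploring
    order = np.argsort(-(q * sigma))
    q, sigma, mu, kappa = q[order], sigma[order], mu[order], kappa[order]
    init = init[order]
    transmat = transmat[np.ix_(order, order)]

    logb = _emission_loglik(l, theta, q, sigma, mu, kappa)
    loglik, g, _ = _forward_backward(logb, transmat, init)
    path = viterbi_path(logb, transmat, init)
    return HmmFit(
        gamma_q=q,
        gamma_sigma=sigma,
        vm_mu=mu,
        vm_kappa=kappa,
        transmat=transmat,
        init=init,
        loglik=loglik,
        loglik_history=history,
        converged=converged,
        posteriors=g,
        path=path,
        n_zero_steps=n_zero,
    )


# ---------------------------------------------------------------------------
# iSSA: availability sampling + conditional logistic fit
# ---------------------------------------------------------------------------

def fit_tentative_gamma(l: np.ndarray) -> GammaStepDist:
    """Maximum-likelihood gamma fit to observed step lengths (zeros floored)."""
    l, _ = _positive_floor(np.asarray(l, float))
    q, sigma = _gamma_wmle(l, np.ones_like(l))
    return GammaStepDist(q=q, sigma=sigma)


def sample_available_steps(
    steps: pd.DataFrame,
    tentative: GammaStepDist,
    landscape: ToxinLandscape,
    A: int = 20,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Build iSSA strata: each observed step plus A available alternatives.

    Available steps share the observed start point; their lengths are drawn
    from the tentative gamma kernel and their turn angles uniformly on
    (-pi, pi] relative to the same reference heading (directional
    persistence is left to the cos(theta) covariate).  Only steps with a
    defined turn angle form strata.  Destination tile classes are read off
    the landscape with out-of-arena endpoints clamped to the boundary tile.

    Returns a long DataFrame with one row per (stratum, candidate):
    stratum, case (1 = observed), l, log_l, cos_theta, dest_less,
    start_less, x_start, y_start (shared start point), t (observed step
    index).
    """
    if A < 1:
        raise ValueError("need at least one available step per stratum")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    usable = steps[np.isfinite(steps["theta"])].reset_index(drop=True)
    S = len(usable)
    if S == 0:
        raise ValueError("no steps with defined turn angles")

    x0 = usable["x_start"].to_numpy(float)
    y0 = usable["y_start"].to_numpy(float)
    heading = usable["heading"].to_numpy(float)
    theta_obs = usable["theta"].to_numpy(float)
    ref = _wrap_angle(heading - theta_obs)  # reference heading of each stratum

    l_av = rng.gamma(tentative.q, tentative.sigma, size=(S, A))
    th_av = rng.uniform(-np.pi, np.pi, size=(S, A))
    hd_av = ref[:, None] + th_av
    xa = x0[:, None] + l_av * np.cos(hd_av)
    ya = y0[:, None] + l_av * np.sin(hd_av)
    dest_more_av = landscape.is_more_toxic_at(xa, ya)

    l_obs, _ = _positive_floor(usable["l"].to_numpy(float))

    stratum = np.repeat(np.arange(S), A + 1)
    case = np.tile(np.r_[1, np.zeros(A, int)], S)
    l_all = np.column_stack([l_obs, l_av]).ravel()
    th_all = np.column_stack([theta_obs, th_av]).ravel()
    dest_more = np.column_stack(
        [usable["end_more"].to_numpy(bool), dest_more_av]
    ).ravel()
    start_less = np.repeat(~usable["start_more"].to_numpy(bool), A + 1)
    return pd.DataFrame(
        {
            "stratum": stratum,
            "case": case,
            "l": l_all,
            "log_l": np.log(l_all),
            "cos_theta": np.cos(th_all),
            "dest_less": (~dest_more).astype(float),
            "start_less": start_less.astype(float),
            "x_start": np.repeat(x0, A + 1),
            "y_start": np.repeat(y0, A + 1),
            "t": np.repeat(usable["t"].to_numpy(), A + 1),
        }
    )


def conditional_loglik(strata: pd.DataFrame, beta: np.ndarray) -> float:
    """Conditional-logistic log-likelihood at a given coefficient vector.

    At beta = 0 this equals -(number of strata) * log(A + 1) exactly.
    """
    X, case = issa_design(strata)
    stratum = strata["stratum"].to_numpy()
    sizes = np.bincount(stratum)
    G = sizes[0]
    Xr = X.reshape(sizes.size, G, X.shape[1])
    case_idx = case.reshape(sizes.size, G).argmax(axis=1)
    eta = Xr @ np.asarray(beta, float)
    return float(
        np.sum(eta[np.arange(sizes.size), case_idx])
        - np.sum(special.logsumexp(eta, axis=1))
    )


def issa_design(strata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, case) arrays in the canonical covariate order ISSA_COVARIATES."""
    X = np.column_stack(
        [
            strata["dest_less"],
            strata["l"],
            strata["log_l"],
            strata["l"] * strata["start_less"],
            strata["log_l"] * strata["start_less"],
            strata["cos_theta"],
        ]
    )
    return X, strata["case"].to_numpy(int)


def _clogit_newton(
    X: np.ndarray, case: np.ndarray, stratum: np.ndarray, max_iter: int = 50
):
    """Conditional-logistic ML for equal-size strata via Newton iteration.

    Strata must be contiguous with the case row first and equal size, which
    is how :func:`sample_available_steps` lays them out; the within-stratum
    softmax then vectorizes as a 3-D reshape.
    """
    sizes = np.bincount(stratum)
    G = sizes[0]
    if not np.all(sizes == G):
        raise ValueError("strata must be equal-sized")
    S = sizes.size
    p = X.shape[1]
    Xr = X.reshape(S, G, p)
    case_idx = case.reshape(S, G).argmax(axis=1)

    beta = np.zeros(p)
    x_case = Xr[np.arange(S), case_idx]
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = Xr @ beta
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        w /= w.sum(axis=1, keepdims=True)
        ll = float(np.sum(np.log(w[np.arange(S), case_idx])))
        xbar = np.einsum("sg,sgp->sp", w, Xr)
        grad = (x_case - xbar).sum(axis=0)
        xc = Xr - xbar[:, None, :]
        hess = -np.einsum("sg,sgp,sgq->pq", w, xc, xc)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("divergent conditional-logistic fit")
        if np.max(np.abs(grad)) < 1e-8 and ll - ll_prev < 1e-10:
            converged = True
            break
        try:
            step_dir = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step_dir = -np.linalg.pinv(hess) @ grad
        # step-halving to guarantee ascent
        t = 1.0
        while t > 1e-6:
            cand = beta + t * step_dir
            eta_c = Xr @ cand
            eta_c -= eta_c.max(axis=1, keepdims=True)
            wc = np.exp(eta_c)
            llc = float(
                np.sum(eta_c[np.arange(S), case_idx])
                - np.sum(np.log(wc.sum(axis=1)))
            )
            if llc >= ll:
                break
            t *= 0.5
        beta = beta + t * step_dir
        ll_prev = ll
    separated = np.max(np.abs(beta)) > 15.0
    if separated:
        warnings.warn("possible separation: coefficient capped at +/-15", stacklevel=2)
        beta = np.clip(beta, -15.0, 15.0)
    cov = np.linalg.pinv(-hess)
    return beta, cov, ll, converged and not separated


@dataclass
class IssaFit:
    """Conditional-logistic iSSA fit with derived behavioural parameters."""

    coef: pd.Series
    se: pd.Series
    cov: np.ndarray = field(repr=False)
    loglik: float
    n_strata: int
    converged: bool
    q0: float
    sigma0: float
    # updated kernels per start-tile class
    q_more: float = np.nan
    sigma_more: float = np.nan
    q_less: float = np.nan
    sigma_less: float = np.nan
    arrestment: float = np.nan
    arrestment_ci: tuple[float, float] = (np.nan, np.nan)
    immigration: float = np.nan
    immigration_ci: tuple[float, float] = (np.nan, np.nan)
    valid_kernel: bool = True
    state: str = ""

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "q_more": self.q_more,
            "sigma_more": self.sigma_more,
            "q_less": self.q_less,
            "sigma_less": self.sigma_less,
            "arrestment": self.arrestment,
            "arrestment_ci": list(self.arrestment_ci),
            "immigration": self.immigration,
            "immigration_ci": list(self.immigration_ci),
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "converged": self.converged,
            "valid_kernel": self.valid_kernel,
        }


def fit_issa(
    strata: pd.DataFrame,
    tentative: GammaStepDist,
    state: str = "",
) -> IssaFit:
    """Fit the iSSA conditional-logistic model and derive (a-hat, omega-hat).

    The movement covariates update the tentative kernel per start-tile
    class: q* = q0 + b_log_l and 1/sigma* = 1/sigma0 - b_l, with the
    interaction terms supplying the extra contribution on less-toxic starts.
    a-hat = sigma*(more-toxic start) / sigma*(less-toxic start);
    omega-hat = exp(coefficient of the less-toxic-destination indicator).
    Confidence intervals are Wald, via the delta method on the log scale for
    a-hat.
    """
    n_strata = strata["stratum"].nunique()
    if n_strata < 30:
        warnings.warn(f"only {n_strata} strata; estimates will be unstable", stacklevel=2)
    X, case = issa_design(strata)
    beta, cov, ll, converged = _clogit_newton(X, case, strata["stratum"].to_numpy())
    names = list(ISSA_COVARIATES)
    coef = pd.Series(beta, index=names)
    se = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names)

    q0, sigma0 = tentative.q, tentative.sigma
    q_more = q0 + coef["log_l"]
    q_less = q0 + coef["log_l"] + coef["log_l_x_start_less"]
    rate_more = 1.0 / sigma0 - coef["l"]
    rate_less = 1.0 / sigma0 - coef["l"] - coef["l_x_start_less"]
    valid = rate_more > 0 and rate_less > 0 and q_more > 0 and q_less > 0
    if not valid:
        warnings.warn("non-positive updated gamma kernel; arrestment flagged invalid",
                      stacklevel=2)

    fit = IssaFit(
        coef=coef,
        se=se,
        cov=cov,
        loglik=ll,
        n_strata=n_strata,
        converged=converged,
        q0=q0,
        sigma0=sigma0,
        state=state,
        valid_kernel=bool(valid),
    )
    z = stats.norm.ppf(0.975)
    b, s = coef["dest_less"], se["dest_less"]
    fit.immigration = float(np.exp(b))
    fit.immigration_ci = (float(np.exp(b - z * s)), float(np.exp(b + z * s)))
    if valid:
        fit.q_more, fit.sigma_more = float(q_more), float(1.0 / rate_more)
        fit.q_less, fit.sigma_less = float(q_less), float(1.0 / rate_less)
        # a-hat = sigma_more / sigma_less = rate_less / rate_more
        log_a = np.log(rate_less) - np.log(rate_more)
        # delta method: d log_a / d(b_l, b_lxs)
        gvec = np.zeros(len(names))
        i_l, i_ls = names.index("l"), names.index("l_x_start_less")
        gvec[i_l] = -1.0 / rate_less + 1.0 / rate_more
        gvec[i_ls] = -1.0 / rate_less
        var_log_a = float(gvec @ cov @ gvec)
        sd = np.sqrt(max(var_log_a, 0.0))
        fit.arrestment = float(np.exp(log_a))
        fit.arrestment_ci = (
            float(np.exp(log_a - z * sd)),
            float(np.exp(log_a + z * sd)),
        )
    return fit


def fit_issa_for_track(
    track: Track,
    landscape: ToxinLandscape,
    A: int = 20,
    seed: int = 0,
    state_labels: np.ndarray | None = None,
) -> dict[str, IssaFit]:
    """Full per-individual chain: steps -> (optional state split) -> iSSA.

    With ``state_labels`` (one per step, e.g. an HMM Viterbi path as
    strings), a separate fit is produced per state; otherwise a single
    'all' fit.  Each state uses its own tentative gamma kernel.
    """
    steps = track_to_steps(track, landscape)
    rng = np.random.default_rng(seed)
    if state_labels is None:
        groups = {"all": steps}
    else:
        state_labels = np.asarray(state_labels)
        if state_labels.size != len(steps):
            raise ValueError("state_labels must align with steps")
        groups = {
            str(s): steps[state_labels == s] for s in pd.unique(state_labels)
        }
    out: dict[str, IssaFit] = {}
    for name, grp in groups.items():
        grp_def = grp[np.isfinite(grp["theta"])]
        if len(grp_def) < 30:
            warnings.warn(f"state {name!r}: too few usable steps, skipped", stacklevel=2)
            continue
        tentative = fit_tentative_gamma(grp["l"].to_numpy())
        strata = sample_available_steps(grp, tentative, landscape, A=A, rng=rng)
        out[name] = fit_issa(strata, tentative, state=name)
    return out
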