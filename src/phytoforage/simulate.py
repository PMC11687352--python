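"""Individual-based foraging simulation and the in-silico clusteredness experiment.

An agent forages on a 12 x 12 cm arena of 1 cm diet tiles.  Every 6 minutes
it considers ``n_candidates`` candidate endpoints drawn from its current
(arrestment-adjusted) step-length kernel and turn-angle kernel, discards the
ones that leave the arena, and selects one with probability proportional to
the immigration weight of the destination tile.  Over 5 days at 6-minute
resolution a track has 1200 steps.

The in-silico experiment measures, for a given behavioural model, the
marginal effect of clusteredness: the paired difference p(beta=5) -
p(beta=-5) in the proportion of time spent on the more-toxic diet, each
replicate pairing one fresh clustered and one fresh dispersed landscape.

The engine is vectorized over replicate agents (each on its own landscape),
which is what makes thousand-replicate experiments cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import ToxinLandscape, make_landscape
from .movement import (
    DEFAULT_KERNEL,
    AgentBehaviour,
    GammaStepDist,
    GvMTurnDist,
    sample_turn,
)

__all__ = [
    "SimConfig",
    "Track",
    "EffectDistribution",
    "MODEL_LABELS",
    "behaviour_for_model",
    "simulate_track",
    "simulate_agents",
    "proportion_time_on_toxic",
    "run_insilico_experiment",
    "overlap_coefficient",
]

#: behavioural model labels for the in-silico experiment
MODEL_LABELS = (
    "null",
    "arrest",
    "immig",
    "arrest+immig",
    "arrest-clustered",
    "arrest-clustered+immig",
)

#: size-class behavioural parameters: (arrestment, immigration)
SIZE_PARAMS = {"small": (0.25, 0.80), "large": (4.0, 1.25)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    n_steps 1200 = 5 days at 6-minute intervals; n_candidates is the size of
    the importance set approximating the continuous redistribution kernel;
    boundary 'resample' redraws candidates that fall outside the arena
    (animals cannot leave), 'reflect' folds them back instead.
    """

    n_steps: int = 1200
    dt_s: float = 360.0
    n_candidates: int = 50
    boundary: str = "resample"
    seed: int = 0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2")
        if self.boundary not in ("resample", "reflect"):
            raise ValueError("boundary must be resample|reflect")


@dataclass
class Track:
    """A movement track at fixed time resolution (positions in cm)."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    states: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.t_s, "x_cm": self.x_cm, "y_cm": self.y_cm})
        if self.states is not None:
            df["state"] = self.states
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Track":
        df = pd.read_csv(path)
        states = df["state"].to_numpy() if "state" in df else None
        return cls(
            t_s=df["time_s"].to_numpy(float),
            x_cm=df["x_cm"].to_numpy(float),
            y_cm=df["y_cm"].to_numpy(float),
            states=states,
        )


def _reflect(v: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates into [0, hi] by reflection at the walls."""
    v = np.mod(v, 2.0 * hi)
    return np.where(v > hi, 2.0 * hi - v, v)


def simulate_agents(
    more_toxic: np.ndarray,
    arrestment: np.ndarray,
    immigration: np.ndarray,
    config: SimConfig,
    step: GammaStepDist | None = None,
    turn: GvMTurnDist | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate R agents in parallel, one landscape each.

    Parameters
    ----------
    more_toxic : bool array (R, n_rows, n_cols)
        Per-agent landscape: True where the tile is more toxic.
    arrestment, immigration : float arrays (R,)
        Per-agent behavioural parameters.
    config : SimConfig
    step, turn : kernels (default the reference Gamma/GvM kernel)
    rng : generator (default seeded from config.seed)

    Returns
    -------
    xs, ys : float arrays (R, n_steps + 1) of positions in cm.
    """
    if step is None or turn is None:
        dstep, dturn = DEFAULT_KERNEL
        step = step or dstep
        turn = turn or dturn
    if rng is None:
        rng = np.random.default_rng(config.seed)
    more_toxic = np.asarray(more_toxic, dtype=bool)
    R, n_rows, n_cols = more_toxic.shape
    width, height = float(n_cols), float(n_rows)
    arrestment = np.broadcast_to(np.asarray(arrestment, float), (R,))
    immigration = np.broadcast_to(np.asarray(immigration, float), (R,))
    C = config.n_candidates
    rep = np.repeat(np.arange(R), C).reshape(R, C)

    xs = np.empty((R, config.n_steps + 1))
    ys = np.empty((R, config.n_steps + 1))
    x = rng.uniform(0.0, width, size=R)
    y = rng.uniform(0.0, height, size=R)
    heading = rng.uniform(-np.pi, np.pi, size=R)
    xs[:, 0], ys[:, 0] = x, y

    def tile_is_more_toxic(px, py, rep_idx):
        col = np.clip(np.floor(px).astype(int), 0, n_cols - 1)
        row = np.clip(np.floor(py).astype(int), 0, n_rows - 1)
        return more_toxic[rep_idx, row, col]

    for t in range(config.n_steps):
        on_more = tile_is_more_toxic(x, y, np.arange(R))
        # arrestment scales the kernel on less-toxic tiles: sigma / a
        sigma_eff = np.where(on_more, step.sigma, step.sigma / arrestment)

        l = rng.gamma(step.q, 1.0, size=(R, C)) * sigma_eff[:, None]
        theta = sample_turn(turn, rng, size=R * C).reshape(R, C)
        if t == 0:
            # no previous heading: first step takes a uniform direction
            hd = rng.uniform(-np.pi, np.pi, size=(R, C))
        else:
            hd = heading[:, None] + theta
        cx = x[:, None] + l * np.cos(hd)
        cy = y[:, None] + l * np.sin(hd)

        if config.boundary == "reflect":
            cx = _reflect(cx, width)
            cy = _reflect(cy, height)
        else:
            invalid = (cx < 0) | (cx > width) | (cy < 0) | (cy > height)
            tries = 0
            shrink = np.ones((R, C))
            while invalid.any():
                tries += 1
                if tries > 200:
                    raise RuntimeError(
                        "could not place candidates inside the arena"
                    )
                if tries % 25 == 0:
                    # persistent rejections: shrink the proposal scale
                    shrink[invalid] *= 0.5
                k = int(invalid.sum())
                nl = rng.gamma(step.q, 1.0, size=k) * (
                    np.broadcast_to(sigma_eff[:, None], (R, C))[invalid]
                    * shrink[invalid]
                )
                nth = sample_turn(turn, rng, size=k)
                if t == 0:
                    nhd = rng.uniform(-np.pi, np.pi, size=k)
                else:
                    nhd = np.broadcast_to(heading[:, None], (R, C))[invalid] + nth
                cx[invalid] = np.broadcast_to(x[:, None], (R, C))[invalid] + nl * np.cos(nhd)
                cy[invalid] = np.broadcast_to(y[:, None], (R, C))[invalid] + nl * np.sin(nhd)
                hd[invalid] = nhd
                invalid = (cx < 0) | (cx > width) | (cy < 0) | (cy > height)

        dest_more = tile_is_more_toxic(cx, cy, rep)
        w = np.where(dest_more, 1.0, immigration[:, None])
        cum = np.cumsum(w, axis=1)
        u = rng.random(R) * cum[:, -1]
        choice = (cum < u[:, None]).sum(axis=1)

        ar = np.arange(R)
        nx, ny = cx[ar, choice], cy[ar, choice]
        dx, dy = nx - x, ny - y
        moved = np.hypot(dx, dy) > 0
        heading = np.where(moved, np.arctan2(dy, dx), heading)
        x, y = nx, ny
        xs[:, t + 1], ys[:, t + 1] = x, y

    return xs, ys


def simulate_track(
    landscape: ToxinLandscape,
    behaviour: AgentBehaviour,
    config: SimConfig,
    step: GammaStepDist | None = None,
    turn: GvMTurnDist | None = None,
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate a single agent on a landscape; fully reproducible given seed."""
    xs, ys = simulate_agents(
        landscape.more_toxic[None, :, :],
        np.array([behaviour.arrestment]),
        np.array([behaviour.immigration]),
        config,
        step=step,
        turn=turn,
        rng=rng,
    )
    t_s = np.arange(config.n_steps + 1) * config.dt_s
    return Track(t_s=t_s, x_cm=xs[0], y_cm=ys[0])


def proportion_time_on_toxic(track: Track, landscape: ToxinLandscape) -> float:
    """Fraction of time points whose tile is classified more-toxic."""
    on = landscape.is_more_toxic_at(track.x_cm, track.y_cm)
    return float(np.mean(on))


@dataclass
class EffectDistribution:
    """Per-replicate paired clusteredness effects p_beta5 - p_beta-5."""

    diffs: np.ndarray
    p_beta5: np.ndarray
    p_betaneg5: np.ndarray
    model: str = ""
    size: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.diffs))

    @property
    def quantiles(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.diffs, [0.025, 0.975])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": np.arange(self.diffs.size),
                "p_beta5": self.p_beta5,
                "p_betaneg5": self.p_betaneg5,
                "diff": self.diffs,
            }
        )


def behaviour_for_model(model: str, size: str) -> dict:
    """Resolve a behavioural-model label to per-treatment (a, omega).

    Returns a dict with keys ``a_clustered`` (arrestment on beta=5
    landscapes), ``a_dispersed`` (on beta=-5), and ``omega`` (applied on
    both).  The 'clustered' variants confine arrestment to the clustered
    treatment, with a=1 elsewhere.
    """
    if size not in SIZE_PARAMS:
        raise ValueError(f"unknown size {size!r}; use small|large")
    a_size, w_size = SIZE_PARAMS[size]
    table = {
        "null": (1.0, 1.0, 1.0),
        "arrest": (a_size, a_size, 1.0),
        "immig": (1.0, 1.0, w_size),
        "arrest+immig": (a_size, a_size, w_size),
        "arrest-clustered": (a_size, 1.0, 1.0),
        "arrest-clustered+immig": (a_size, 1.0, w_size),
    }
    if model not in table:
        raise ValueError(f"unknown model {model!r}; one of {MODEL_LABELS}")
    a_cl, a_di, omega = table[model]
    return {"a_clustered": a_cl, "a_dispersed": a_di, "omega": omega}


def _fresh_landscape_stack(
    beta: float, n_reps: int, seed_seq: np.random.SeedSequence
) -> np.ndarray:
    """Stack of n_reps independent more-toxic masks at the given beta."""
    seeds = seed_seq.generate_state(n_reps)
    masks = np.empty((n_reps, 12, 12), dtype=bool)
    for i, s in enumerate(seeds):
        masks[i] = make_landscape(beta=beta, variation="high", seed=int(s)).more_toxic
    return masks


def run_insilico_experiment(
    model: str,
    size: str,
    config: SimConfig | None = None,
    step: GammaStepDist | None = None,
    turn: GvMTurnDist | None = None,
) -> EffectDistribution:
    """Run one cell of the clusteredness experiment.

    For each replicate, a fresh beta=5 and a fresh beta=-5 landscape are
    generated; one agent with the model's (a, omega) is simulated on each
    (1200 steps by default) and the paired difference in proportion of time
    on the more-toxic diet is recorded.
    """
    config = config or SimConfig()
    params = behaviour_for_model(model, size)
    root = np.random.SeedSequence(config.seed)
    sq_land5, sq_landn5, sq_sim = root.spawn(3)
    R = config.n_reps

    masks5 = _fresh_landscape_stack(5.0, R, sq_land5)
    masksn5 = _fresh_landscape_stack(-5.0, R, sq_landn5)

    rng = np.random.default_rng(sq_sim)
    p = {}
    for key, masks, a in (
        ("beta5", masks5, params["a_clustered"]),
        ("betaneg5", masksn5, params["a_dispersed"]),
    ):
        xs, ys = simulate_agents(
            masks,
            np.full(R, a),
            np.full(R, params["omega"]),
            config,
            step=step,
            turn=turn,
            rng=rng,
        )
        col = np.clip(np.floor(xs).astype(int), 0, 11)
        row = np.clip(np.floor(ys).astype(int), 0, 11)
        on = masks[np.arange(R)[:, None], row, col]
        p[key] = on.mean(axis=1)

    return EffectDistribution(
        diffs=p["beta5"] - p["betaneg5"],
        p_beta5=p["beta5"],
        p_betaneg5=p["betaneg5"],
        model=model,
        size=size,
    )


def overlap_coefficient(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Overlap coefficient (OVL) of two sample distributions.

    The integral of the pointwise minimum of the two Gaussian kernel density
    estimates on a common grid spanning both samples: 1 for identical
    distributions, 0 for disjoint ones.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples in each distribution")
    kde_a = stats.gaussian_kde(a)
    kde_b = stats.gaussian_kde(b)
    pad = 3.0 * max(np.std(a), np.std(b), 1e-12)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, 1024)
    return float(np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid))
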