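"""Movement kernel distributions and behavioural-rule arithmetic.

A foraging bout is modelled as a discrete-time walk: every 6 minutes the
animal takes a step of length l ~ Gamma(q, sigma) (cm) and turns by
theta ~ GvM(kappa1, kappa2), the two-harmonic generalized von Mises
distribution on the circle.  Diet preference enters through two scalar
behaviours:

* **arrestment** ``a`` — the ratio of the gamma *scale* on more-toxic vs
  less-toxic tiles.  The base kernel is the one used on the more-toxic
  diet; on a less-toxic tile the scale becomes sigma / a, so a > 1 means
  the animal moves less (is arrested) on the less-toxic diet and a < 1
  means it is arrested on the more-toxic diet.
* **immigration** ``omega`` — the odds ratio of selecting a candidate step
  that ends on a less-toxic tile relative to one ending on a more-toxic
  tile.

Reference parameterization: Gamma(q=0.8, sigma=1 cm), GvM(kappa1=0.4,
kappa2=0.3); small animals a=0.25, omega=0.80; large animals a=4,
omega=1.25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path

import numpy as np
from scipy import integrate, stats

__all__ = [
    "GammaStepDist",
    "GvMTurnDist",
    "AgentBehaviour",
    "gvm_density",
    "sample_turn",
    "effective_step_dist",
    "selection_weight",
    "load_kernel_params",
    "DEFAULT_KERNEL",
]


@dataclass(frozen=True)
class GammaStepDist:
    """Gamma step-length distribution: shape q, scale sigma (cm)."""

    q: float
    sigma: float

    def __post_init__(self) -> None:
        if self.q <= 0 or self.sigma <= 0:
            raise ValueError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.q * self.sigma

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.gamma(self.q, self.sigma, size=size)

    def pdf(self, l: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(l, a=self.q, scale=self.sigma)

    def logpdf(self, l: np.ndarray) -> np.ndarray:
        return stats.gamma.logpdf(l, a=self.q, scale=self.sigma)


@dataclass(frozen=True)
class GvMTurnDist:
    """Generalized von Mises turn-angle distribution (two cosine harmonics).

    Density proportional to exp(kappa1*cos(theta - mu1) +
    kappa2*cos(2*(theta - mu2))) on (-pi, pi].  The normalizing constant has
    no convenient closed form and is computed by numerical quadrature.
    """

    kappa1: float
    kappa2: float
    mu1: float = 0.0
    mu2: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("concentration parameters must be non-negative")

    def _unnorm(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(
            self.kappa1 * np.cos(theta - self.mu1)
            + self.kappa2 * np.cos(2.0 * (theta - self.mu2))
        )

    @cached_property
    def norm_const(self) -> float:
        val, _ = integrate.quad(self._unnorm, -np.pi, np.pi, limit=200)
        return val

    @cached_property
    def _envelope_max(self) -> float:
        # bound of the smooth unnormalized density (at most four modes),
        # taken on a fine grid with head-room
        grid = np.linspace(-np.pi, np.pi, 4096, endpoint=False)
        return float(self._unnorm(grid).max() * (1.0 + 1e-9))


def gvm_density(theta: np.ndarray, dist: GvMTurnDist) -> np.ndarray:
    """Normalized GvM density at theta (radians)."""
    theta = np.asarray(theta, dtype=float)
    return dist._unnorm(theta) / dist.norm_const


def sample_turn(
    dist: GvMTurnDist, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw turn angles by rejection from a uniform envelope.

    The envelope constant is the maximum of the unnormalized density on a
    fine grid (the density is smooth with at most four modes, so a 4096-point
    grid bounds it to well under float precision of the acceptance test).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    m = dist._envelope_max
    out = np.empty(n)
    filled = 0
    # expected acceptance rate = Z / (2 pi m); draw with head-room
    accept_rate = max(dist.norm_const / (2.0 * np.pi * m), 1e-3)
    while filled < n:
        chunk = max(int((n - filled) / accept_rate * 1.2), 16)
        cand = rng.uniform(-np.pi, np.pi, size=chunk)
        keep = cand[rng.uniform(0.0, m, size=chunk) < dist._unnorm(cand)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out[0] if scalar else out


@dataclass(frozen=True)
class AgentBehaviour:
    """Behavioural parameters of one simulated forager.

    arrestment a and immigration omega as defined in the module docstring;
    ``size_class`` is carried for bookkeeping only.  ``state`` selects the
    behavioural mode; the resting/feeding kernel uses the exploration scale
    multiplied by ``state_scale_ratio`` (about a tenth) and expresses no
    diet preference.
    """

    arrestment: float = 1.0
    immigration: float = 1.0
    size_class: str = "small"
    state: str = "exploring"
    state_scale_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.arrestment <= 0:
            raise ValueError("arrestment must be positive")
        if self.immigration <= 0:
            raise ValueError("immigration must be positive")


def effective_step_dist(
    base: GammaStepDist, behaviour: AgentBehaviour, tile: str
) -> GammaStepDist:
    """Arrestment-adjusted step kernel for the current tile.

    ``base`` is the kernel on the more-toxic diet.  On a less-toxic tile the
    scale is divided by the arrestment ratio a = sigma_more / sigma_less.
    In the resting state the scale is additionally shrunk by
    ``state_scale_ratio`` and arrestment does not apply (no diet preference
    at rest).
    """
    if tile not in ("more", "less"):
        raise ValueError("tile must be 'more' or 'less'")
    sigma = base.sigma
    if behaviour.state == "resting":
        return replace(base, sigma=sigma * behaviour.state_scale_ratio)
    if tile == "less":
        sigma = sigma / behaviour.arrestment
    return replace(base, sigma=sigma)


def selection_weight(dest_tile: str, behaviour: AgentBehaviour) -> float:
    """Multiplicative selection weight of a candidate destination tile.

    omega for a less-toxic destination, 1 for a more-toxic one; at rest the
    animal is indifferent and every destination weighs 1.
    """
    if dest_tile not in ("more", "less"):
        raise ValueError("dest_tile must be 'more' or 'less'")
    if behaviour.state == "resting":
        return 1.0
    return behaviour.immigration if dest_tile == "less" else 1.0


#: the empirically parameterised exploration kernel
DEFAULT_KERNEL: tuple[GammaStepDist, GvMTurnDist] = (
    GammaStepDist(q=0.8, sigma=1.0),
    GvMTurnDist(kappa1=0.4, kappa2=0.3),
)


def load_kernel_params(path: str | Path) -> dict:
    """Read a kernel/behaviour parameter file.

    JSON with keys q, sigma_cm, kappa1, kappa2, arrestment, immigration,
    state_scale_ratio (all optional; defaults to the reference kernel and
    neutral behaviour).
    """
    raw = json.loads(Path(path).read_text())
    step = GammaStepDist(q=raw.get("q", 0.8), sigma=raw.get("sigma_cm", 1.0))
    turn = GvMTurnDist(kappa1=raw.get("kappa1", 0.4), kappa2=raw.get("kappa2", 0.3))
    behaviour = AgentBehaviour(
        arrestment=raw.get("arrestment", 1.0),
        immigration=raw.get("immigration", 1.0),
        state_scale_ratio=raw.get("state_scale_ratio", 0.1),
    )
    return {"step": step, "turn": turn, "behaviour": behaviour}
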