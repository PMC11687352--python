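"""Performance measure and proximal foraging variables.

From each trial the experiment derives one performance number — the hourly
relative growth rate, RGR = (ln m_t - ln m_0) / t — and a handful of
proximal variables computed from the movement track and the eaten-diet
mask: the mean 12-hour sliding-window variance of toxin-concentration
exposure, the log mean step length, the area of diet consumed, the mean
toxin concentration ingested, the proportion of time spent in the
exploration state, and the proportion of time spent on the more-toxic diet.

All quantities here are deterministic functions of their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import ToxinLandscape
from .simulate import Track

__all__ = [
    "PerformanceRecord",
    "rgr",
    "exposure_variance",
    "track_summaries",
    "consumption_summary",
    "logit",
]


@dataclass(frozen=True)
class PerformanceRecord:
    """Masses (mg) and exposure duration (h) of one individual."""

    m0: float
    mt: float
    t_hours: float
    pupation_days: float | None = None
    eclosed: bool | None = None

    def __post_init__(self) -> None:
        if self.m0 <= 0 or self.mt <= 0:
            raise ValueError("masses must be positive")
        if self.t_hours <= 0:
            raise ValueError("exposure duration must be positive")


def rgr(record: PerformanceRecord) -> float:
    """Hourly relative growth rate (ln m_t - ln m_0) / t; positive for growth."""
    return float((np.log(record.mt) - np.log(record.m0)) / record.t_hours)


def exposure_variance(
    track: Track, landscape: ToxinLandscape, window: int = 120
) -> float:
    """Mean sliding-window variance of toxin-concentration exposure.

    The occupied-tile concentration series is windowed (default 120
    observations = 12 h at one fix per 6 min, stride 1) and the population
    variance of each window is averaged over all windows.
    """
    conc = np.asarray(landscape.concentration_at(track.x_cm, track.y_cm), float)
    n = conc.size
    if n < window:
        raise ValueError(f"track length {n} shorter than window {window}")
    # population variance per window via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(conc)])
    c2 = np.concatenate([[0.0], np.cumsum(conc**2)])
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = s2 / window - (s1 / window) ** 2
    return float(np.mean(np.clip(var, 0.0, None)))


def track_summaries(
    l: np.ndarray,
    state_labels: np.ndarray | None = None,
    exploring_label: str = "exploring",
    floor: float = 1e-6,
) -> dict[str, float]:
    """Log mean step length (cm) and proportion of time spent exploring."""
    l = np.asarray(l, float)
    if l.size == 0:
        raise ValueError("empty step series")
    mean_l = float(np.mean(l))
    if mean_l <= 0:
        warnings.warn("all steps zero; log mean step floored", stacklevel=2)
        mean_l = floor
    out = {"log_mean_step": float(np.log(mean_l))}
    if state_labels is not None:
        state_labels = np.asarray(state_labels)
        out["prop_exploring"] = float(np.mean(state_labels == exploring_label))
    return out


def consumption_summary(
    mask: np.ndarray, landscape: ToxinLandscape, cell_area_cm2: float = 1.0
) -> dict[str, float]:
    """Area consumed (cm^2) and mean toxin ingested (mg/g) from an eaten mask.

    Mean ingested averages the concentration of eaten cells with equal
    weight per cell; an empty mask gives area 0 and NaN mean (flagged by a
    warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != landscape.grid.shape:
        raise ValueError("mask and landscape dimensions differ")
    n_eaten = int(mask.sum())
    if n_eaten == 0:
        warnings.warn("empty eaten mask: mean toxin ingested undefined", stacklevel=2)
        return {"area_cm2": 0.0, "mean_toxin_mg_g": float("nan")}
    return {
        "area_cm2": n_eaten * cell_area_cm2,
        "mean_toxin_mg_g": float(landscape.grid[mask].mean()),
    }


def logit(p: np.ndarray, eps: float = 0.005) -> np.ndarray:
    """Logit transform with a boundary adjustment pulling p into [eps, 1-eps]."""
    p = np.clip(np.asarray(p, float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))
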