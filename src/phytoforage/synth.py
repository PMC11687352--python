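"""Synthetic fixtures with recorded ground truth.

Everything downstream of the cameras can be emulated: movement tracks with
known behavioural parameters (via the individual-based simulator), latent
behavioural-state sequences, eaten-diet masks, and performance tables whose
RGR responds to the computed proximal metrics through known linear
coefficients.  Each bundle regenerates bit-identically from its seeds, so
recovery tests always know the truth they are recovering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import ToxinLandscape, make_landscape
from .metrics import PerformanceRecord, consumption_summary
from .movement import AgentBehaviour, GammaStepDist
from .simulate import SimConfig, Track, simulate_track

__all__ = [
    "TruthBundle",
    "make_tracks_with_truth",
    "make_two_state_steps",
    "make_eaten_mask",
    "make_performance_table",
    "TABLE_BEHAVIOUR_GRID",
]

#: the (arrestment, immigration) values used across the in-silico experiment
TABLE_BEHAVIOUR_GRID = tuple(
    (a, w) for a in (0.25, 1.0, 4.0) for w in (0.80, 1.0, 1.25)
)


@dataclass
class TruthBundle:
    """One synthetic individual: generating truth plus generated artifacts."""

    behaviour: AgentBehaviour
    beta: float
    landscape_seed: int
    track_seed: int
    landscape: ToxinLandscape = field(repr=False, default=None)
    track: Track = field(repr=False, default=None)
    state_labels: np.ndarray | None = field(repr=False, default=None)
    mask: np.ndarray | None = field(repr=False, default=None)
    record: PerformanceRecord | None = None


def make_tracks_with_truth(
    n: int,
    behaviour_grid=((1.0, 1.0),),
    beta: float = 5.0,
    config: SimConfig | None = None,
    seed: int = 0,
) -> list[TruthBundle]:
    """Generate n tracks cycling through a grid of (arrestment, immigration).

    Each bundle gets its own fresh landscape and simulation stream derived
    from ``seed``; regeneration from the recorded seeds is bit-identical.
    """
    config = config or SimConfig(n_steps=1200)
    root = np.random.SeedSequence(seed)
    land_seeds = root.spawn(1)[0].generate_state(n)
    track_seeds = np.random.SeedSequence(seed + 1).generate_state(n)
    bundles = []
    for i in range(n):
        a, w = behaviour_grid[i % len(behaviour_grid)]
        behaviour = AgentBehaviour(arrestment=a, immigration=w)
        ls = int(land_seeds[i] % (2**31))
        ts = int(track_seeds[i] % (2**31))
        landscape = make_landscape(beta=beta, variation="high", seed=ls)
        track = simulate_track(
            landscape, behaviour, config, rng=np.random.default_rng(ts)
        )
        bundles.append(
            TruthBundle(
                behaviour=behaviour,
                beta=beta,
                landscape_seed=ls,
                track_seed=ts,
                landscape=landscape,
                track=track,
            )
        )
    return bundles


def make_two_state_steps(
    n: int,
    q: tuple[float, float] = (0.8, 0.8),
    sigma: tuple[float, float] = (1.0, 0.1),
    kappa: tuple[float, float] = (0.5, 0.5),
    stay: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a labelled two-state (l, theta) series for HMM recovery tests.

    State 0 is the long-step state; steps are gamma, turns von Mises, and
    the state sequence a sticky Markov chain with self-transition ``stay``.
    Returns a step-series-shaped DataFrame with a ``true_state`` column.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(2)
    flips = rng.random(n - 1) > stay
    for i in range(1, n):
        states[i] = states[i - 1] ^ flips[i - 1]
    l = rng.gamma(np.asarray(q)[states], np.asarray(sigma)[states])
    theta = rng.vonmises(0.0, np.asarray(kappa)[states])
    return pd.DataFrame(
        {
            "t": np.arange(1, n + 1),
            "l": l,
            "theta": theta,
            "true_state": states,
        }
    )


def make_eaten_mask(
    track: Track,
    state_labels: np.ndarray,
    landscape: ToxinLandscape,
    visits_per_tile: int = 10,
    resting_label: str = "resting",
) -> np.ndarray:
    """Synthetic eaten-diet mask: a tile is eaten once the animal has rested
    on it for at least ``visits_per_tile`` observations.

    Stand-in for the image-derived mask of the real pipeline (labelled
    synthetic on purpose); monotone in the threshold by construction.
    """
    state_labels = np.asarray(state_labels)
    n_pts = len(track)
    if state_labels.size not in (n_pts, n_pts - 1):
        raise ValueError("state labels do not align with track")
    # per-step labels apply to the step's start position
    x = track.x_cm[: state_labels.size]
    y = track.y_cm[: state_labels.size]
    row, col = landscape.tile_index(x, y)
    resting = state_labels == resting_label
    counts = np.zeros(landscape.grid.shape, dtype=int)
    np.add.at(counts, (row[resting], col[resting]), 1)
    return counts >= visits_per_tile


def make_performance_table(
    bundles: list[TruthBundle],
    coef: dict[str, float] | None = None,
    intercept: float = 0.01,
    noise_sd: float = 0.0,
    t_hours: float = 120.0,
    m0_mg: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate performance records whose RGR follows a known linear model.

    RGR_i = intercept + sum_k coef[k] * metric_k(i) + N(0, noise_sd); final
    masses are back-solved as m_t = m0 * exp(RGR * t).  Metrics available as
    covariates: mean_toxin_mg_g, area_cm2, log_mean_step.  Bundles without a
    mask get a zero consumption row.
    """
    coef = coef or {}
    rng = np.random.default_rng(seed)
    rows = []
    for i, b in enumerate(bundles):
        metrics_i = {
            "log_mean_step": float(
                np.log(max(np.mean(np.hypot(np.diff(b.track.x_cm), np.diff(b.track.y_cm))), 1e-6))
            )
        }
        if b.mask is not None:
            cons = consumption_summary(b.mask, b.landscape)
            metrics_i["area_cm2"] = cons["area_cm2"]
            metrics_i["mean_toxin_mg_g"] = (
                0.0 if np.isnan(cons["mean_toxin_mg_g"]) else cons["mean_toxin_mg_g"]
            )
        else:
            metrics_i["area_cm2"] = 0.0
            metrics_i["mean_toxin_mg_g"] = 0.0
        value = intercept + sum(coef.get(k, 0.0) * v for k, v in metrics_i.items())
        value += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        mt = m0_mg * np.exp(value * t_hours)
        b.record = PerformanceRecord(m0=m0_mg, mt=mt, t_hours=t_hours)
        rows.append({"individual": i, "m0_mg": m0_mg, "mt_mg": mt,
                     "t_hours": t_hours, "rgr": value, **metrics_i})
    return pd.DataFrame(rows)
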