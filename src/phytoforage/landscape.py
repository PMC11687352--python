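"""Synthesis and diagnosis of 1/f^beta toxin landscapes.

The experimental arenas are 12 x 12 grids of 1 cm diet tiles whose toxin
(xanthotoxin) concentration takes exactly two values, arranged so that the
spatial pattern belongs to the 1/f^beta inverse-power-law noise family:
the variance carried by a spatial frequency f scales as 1/f^beta.  beta > 0
gives positively autocorrelated ("clustered") patterns, beta = 0 spatially
random ones, beta < 0 negatively autocorrelated ("dispersed") ones.

The pipeline here is: synthesize a real-valued field with the requested
spectrum (:func:`synthesize_field`), split it at the median into equal
numbers of high and low tiles (:func:`binarize_median`), and map the binary
pattern to concentrations (:func:`assign_concentrations`).  Two diagnostics,
:func:`estimate_spectral_exponent` and :func:`morans_i`, verify that the
generator actually delivers the requested spectral slope and clusteredness
ordering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralParams",
    "ToxinLandscape",
    "CONCENTRATIONS",
    "synthesize_field",
    "binarize_median",
    "assign_concentrations",
    "make_landscape",
    "estimate_spectral_exponent",
    "morans_i",
    "write_landscape",
    "read_landscape",
    "landscape_long_frame",
]

#: concentration pairs (low-tile, high-tile) in mg/g for each variation treatment
CONCENTRATIONS: dict[str, tuple[float, float]] = {
    "high": (0.0, 2.0),
    "low": (0.5, 1.5),
    "none": (1.0, 1.0),
}


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of the 1/f^beta spectral synthesis.

    Attributes
    ----------
    beta : float
        Spectral exponent; power at radial frequency f is proportional to
        f**(-beta).
    n_rows, n_cols : int
        Grid size in tiles. The product must be even so the downstream
        median split can be exactly half/half.
    seed : int
        Seed for the phase draw (and tie-breaking downstream).
    """

    beta: float
    n_rows: int = 12
    n_cols: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if (self.n_rows * self.n_cols) % 2 != 0:
            raise ValueError(
                "n_rows * n_cols must be even for the half/half median split"
            )


@dataclass(frozen=True)
class ToxinLandscape:
    """A binary-concentration toxin landscape on a regular grid.

    ``grid`` holds tile concentrations in mg/g; ``more_toxic`` flags the
    tiles carrying the higher concentration.  Row 0 is the top of the arena;
    the tile at (row i, col j) covers x in [j, j+1) cm, y in [i, i+1) cm.
    """

    grid: np.ndarray
    beta: float
    variation: str
    more_toxic: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def extent_cm(self) -> tuple[float, float]:
        """(width, height) of the arena in cm (1 cm tiles)."""
        return float(self.n_cols), float(self.n_rows)

    def tile_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map arena coordinates (cm) to (row, col) with half-open 1 cm bins.

        Positions exactly on the far boundary clamp into the last tile.
        """
        col = np.clip(np.floor(x).astype(int), 0, self.n_cols - 1)
        row = np.clip(np.floor(y).astype(int), 0, self.n_rows - 1)
        return row, col

    def is_more_toxic_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.tile_index(np.asarray(x), np.asarray(y))
        return self.more_toxic[row, col]

    def concentration_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.tile_index(np.asarray(x), np.asarray(y))
        return self.grid[row, col]


def _radial_frequency(n_rows: int, n_cols: int) -> np.ndarray:
    """Radial frequency magnitude in cycles per grid, FFT layout."""
    fy = np.fft.fftfreq(n_rows, d=1.0 / n_rows)  # integer wavenumbers
    fx = np.fft.fftfreq(n_cols, d=1.0 / n_cols)
    return np.hypot(fy[:, None], fx[None, :])


def synthesize_field(params: SpectralParams) -> np.ndarray:
    """Generate a real zero-mean field with power spectrum ~ f**(-beta).

    Fourier amplitudes are set deterministically to f**(-beta/2) (DC term
    zeroed); phases are independent uniform on [0, 2pi) subject to the
    conjugate symmetry that makes the inverse transform real.  The four
    self-conjugate frequencies (DC, Nyquist rows/columns on even grids) get
    random signs instead of phases.
    """
    n, m = params.n_rows, params.n_cols
    rng = np.random.default_rng(params.seed)

    f = _radial_frequency(n, m)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-params.beta / 2.0), 0.0)
    if not np.all(np.isfinite(amp)):
        raise ValueError(f"beta={params.beta} produces non-finite spectral amplitudes")

    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, m))
    sign = np.where(rng.random(size=(n, m)) < 0.5, 1.0, -1.0)

    iy, ix = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    cy, cx = (-iy) % n, (-ix) % m
    k = iy * m + ix
    ck = cy * m + cx
    self_conj = k == ck

    spec = amp * np.exp(1j * phase)
    spec[self_conj] = amp[self_conj] * sign[self_conj]
    # overwrite the non-canonical member of each conjugate pair
    noncanon = k > ck
    spec_flat = spec.ravel()
    spec_flat[k[noncanon]] = np.conj(spec_flat[ck[noncanon]])
    spec = spec_flat.reshape(n, m)

    out = np.fft.ifft2(spec)
    resid = np.max(np.abs(out.imag))
    scale = max(np.max(np.abs(out.real)), 1.0)
    if resid > 1e-9 * scale:
        raise RuntimeError(f"inverse transform not real: residual imag {resid:g}")
    field_ = out.real
    return field_ - field_.mean()


def binarize_median(field_: np.ndarray, seed: int = 0) -> np.ndarray:
    """Split a field at its median into exactly half high / half low cells.

    Ranks are computed on the values; ties are broken by a seeded random
    permutation so the split never depends on array order.  Returns a
    boolean grid, True = high.
    """
    field_ = np.asarray(field_, dtype=float)
    n_cells = field_.size
    if n_cells % 2 != 0:
        raise ValueError("cell count must be even for an exact half/half split")
    if np.ptp(field_) == 0:
        warnings.warn(
            "constant field: median split is an arbitrary seeded half/half",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    # stable sort of permuted values => ties resolved by the permutation
    order = perm[np.argsort(field_.ravel()[perm], kind="stable")]
    high = np.zeros(n_cells, dtype=bool)
    high[order[n_cells // 2 :]] = True
    return high.reshape(field_.shape)


def assign_concentrations(
    binary: np.ndarray,
    variation: str,
    *,
    beta: float = np.nan,
    seed: int | None = None,
) -> ToxinLandscape:
    """Map a binary high/low pattern to tile concentrations (mg/g).

    ``high`` variation uses 0 and 2 mg/g, ``low`` 0.5 and 1.5 mg/g; both
    keep the grid mean at exactly 1 mg/g.  ``none`` is the uniform 1 mg/g
    control (every tile identical; the binary pattern only sets the
    more-toxic labels, which are then meaningless).
    """
    if variation not in CONCENTRATIONS:
        raise ValueError(f"unknown variation {variation!r}; use high|low|none")
    binary = np.asarray(binary, dtype=bool)
    lo, hi = CONCENTRATIONS[variation]
    grid = np.where(binary, hi, lo)
    return ToxinLandscape(
        grid=grid, beta=beta, variation=variation, more_toxic=binary.copy(), seed=seed
    )


def make_landscape(
    beta: float,
    variation: str = "high",
    seed: int = 0,
    n_rows: int = 12,
    n_cols: int = 12,
) -> ToxinLandscape:
    """Convenience: synthesize, binarize, and assign in one call."""
    params = SpectralParams(beta=beta, n_rows=n_rows, n_cols=n_cols, seed=seed)
    field_ = synthesize_field(params)
    binary = binarize_median(field_, seed=seed)
    return assign_concentrations(binary, variation, beta=beta, seed=seed)


def estimate_spectral_exponent(field_: np.ndarray) -> float:
    """Estimate beta as minus the log-log slope of the radial power spectrum.

    Power is averaged within integer radial-frequency bins (DC excluded) and
    regressed on log frequency; the returned value is on the beta scale, so
    white noise gives ~0 and clustered fields give positive values.
    """
    field_ = np.asarray(field_, dtype=float)
    if field_.shape[0] < 4 or field_.shape[1] < 4:
        raise ValueError("need at least a 4x4 grid")
    if np.ptp(field_) == 0:
        raise ValueError("constant field has no spectrum to estimate")
    power = np.abs(np.fft.fft2(field_ - field_.mean())) ** 2
    f = _radial_frequency(*field_.shape)
    fbin = np.rint(f).astype(int)
    nyq = min(field_.shape) // 2
    radii = np.arange(1, nyq + 1)
    mean_power = np.array([power[fbin == r].mean() for r in radii])
    keep = mean_power > 0
    if keep.sum() < 2:
        raise ValueError("not enough non-empty frequency bins")
    slope = np.polyfit(np.log(radii[keep]), np.log(mean_power[keep]), 1)[0]
    return float(-slope)


def _grid_neighbour_pairs(shape: tuple[int, int], adjacency: str) -> tuple[np.ndarray, np.ndarray]:
    """Flat index pairs (i, j), i < j, of contiguous cells."""
    n, m = shape
    idx = np.arange(n * m).reshape(n, m)
    pairs = [
        (idx[:, :-1].ravel(), idx[:, 1:].ravel()),  # horizontal
        (idx[:-1, :].ravel(), idx[1:, :].ravel()),  # vertical
    ]
    if adjacency == "queen":
        pairs.append((idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()))
        pairs.append((idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()))
    elif adjacency != "rook":
        raise ValueError(f"unknown adjacency {adjacency!r}; use rook|queen")
    a = np.concatenate([p[0] for p in pairs])
    b = np.concatenate([p[1] for p in pairs])
    return a, b


def morans_i(grid: np.ndarray, adjacency: str = "rook") -> float:
    """Moran's I spatial autocorrelation with binary contiguity weights.

    I = (N / W) * sum_ij w_ij z_i z_j / sum_i z_i^2, with z the mean-centred
    values and W the total weight (each contiguous pair counted in both
    directions).  Positive for clustered grids, ~ -1/(N-1) for random ones,
    -1 for a perfect rook checkerboard.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    z = (grid - grid.mean()).ravel()
    denom = np.sum(z * z)
    if denom == 0:
        raise ValueError("constant grid: Moran's I undefined (zero variance)")
    a, b = _grid_neighbour_pairs(grid.shape, adjacency)
    cross = 2.0 * np.sum(z[a] * z[b])  # both directions
    w_total = 2.0 * a.size
    return float(z.size / w_total * cross / denom)


# ---------------------------------------------------------------------------
# File formats: TSV grid + JSON sidecar, and a long-format CSV
# ---------------------------------------------------------------------------

def write_landscape(landscape: ToxinLandscape, path: str | Path) -> None:
    """Write the concentration grid as TSV with a JSON sidecar (.json)."""
    path = Path(path)
    np.savetxt(path, landscape.grid, delimiter="\t", fmt="%.6g")
    sidecar = {
        "beta": None if np.isnan(landscape.beta) else landscape.beta,
        "variation": landscape.variation,
        "seed": landscape.seed,
        "more_toxic": landscape.more_toxic.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_landscape(path: str | Path) -> ToxinLandscape:
    path = Path(path)
    grid = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        more_toxic = np.asarray(meta.get("more_toxic"), dtype=bool)
        beta = meta.get("beta")
        return ToxinLandscape(
            grid=grid,
            beta=np.nan if beta is None else float(beta),
            variation=meta.get("variation", "high"),
            more_toxic=more_toxic,
            seed=meta.get("seed"),
        )
    # no sidecar: infer labels from the concentrations themselves
    more_toxic = grid > grid.mean()
    return ToxinLandscape(
        grid=grid, beta=np.nan, variation="high", more_toxic=more_toxic, seed=None
    )


def landscape_long_frame(landscape: ToxinLandscape) -> pd.DataFrame:
    """Long-format table: row, col (0-based, row 0 at top), conc, tile class."""
    n, m = landscape.grid.shape
    rows, cols = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "conc_mg_g": landscape.grid.ravel(),
            "tile_class": np.where(
                landscape.more_toxic.ravel(), "more-toxic", "less-toxic"
            ),
        }
    )
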