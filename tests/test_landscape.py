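"""Landscape synthesis: spectral law, median split, concentrations, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import phytoforage as pf
from phytoforage.landscape import SpectralParams, landscape_long_frame


def brute_force_morans_i(grid, adjacency="rook"):
    """Literal double-loop evaluation of the Moran's I formula (test oracle)."""
    grid = np.asarray(grid, float)
    n, m = grid.shape
    z = grid - grid.mean()
    num = 0.0
    w_total = 0.0
    for i in range(n):
        for j in range(m):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    if adjacency == "rook" and di != 0 and dj != 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m:
                        num += z[i, j] * z[ii, jj]
                        w_total += 1.0
    return (n * m) / w_total * num / np.sum(z * z)


class TestSynthesizeField:
    def test_zero_mean(self):
        for beta in (-5.0, 0.0, 5.0):
            f = pf.synthesize_field(SpectralParams(beta=beta, seed=3))
            assert abs(f.mean()) < 1e-9

    def test_deterministic(self):
        p = SpectralParams(beta=5.0, seed=42)
        assert np.array_equal(pf.synthesize_field(p), pf.synthesize_field(p))

    def test_white_noise_flat_spectrum(self):
        est = [
            pf.estimate_spectral_exponent(
                pf.synthesize_field(SpectralParams(beta=0.0, seed=s))
            )
            for s in range(100)
        ]
        assert abs(np.mean(est)) < 0.5

    def test_morans_ordering_by_beta(self):
        wins = 0
        for s in range(100):
            i5 = pf.morans_i(pf.synthesize_field(SpectralParams(5.0, seed=s)))
            i0 = pf.morans_i(pf.synthesize_field(SpectralParams(0.0, seed=s)))
            im5 = pf.morans_i(pf.synthesize_field(SpectralParams(-5.0, seed=s)))
            wins += i5 > i0 > im5
        assert wins >= 95

    def test_exponent_recovery_monotone(self):
        betas = [-5.0, -2.0, 0.0, 2.0, 5.0]
        means = [
            np.mean(
                [
                    pf.estimate_spectral_exponent(
                        pf.synthesize_field(SpectralParams(b, seed=s))
                    )
                    for s in range(30)
                ]
            )
            for b in betas
        ]
        assert np.all(np.diff(means) > 0)
        rho = stats.spearmanr(betas, means).statistic
        assert rho > 0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SpectralParams(beta=np.inf)
        with pytest.raises(ValueError):
            SpectralParams(beta=0.0, n_rows=3, n_cols=3)  # odd cell count
        with pytest.raises(ValueError):
            SpectralParams(beta=0.0, n_rows=1, n_cols=2)


class TestBinarizeMedian:
    def test_exact_half_split(self):
        f = pf.synthesize_field(SpectralParams(beta=5.0, seed=1))
        b = pf.binarize_median(f, seed=1)
        assert b.sum() == 72 and (~b).sum() == 72

    def test_negation_gives_complement(self):
        f = pf.synthesize_field(SpectralParams(beta=-5.0, seed=2))
        b = pf.binarize_median(f, seed=0)
        bn = pf.binarize_median(-f, seed=0)
        # distinct values only (ties on +/- pairs cannot occur for continuous fields)
        assert np.array_equal(b, ~bn)

    def test_constant_field_seeded_tiebreak(self):
        c = np.ones((4, 4))
        with pytest.warns(UserWarning, match="constant"):
            b1 = pf.binarize_median(c, seed=9)
        with pytest.warns(UserWarning):
            b2 = pf.binarize_median(c, seed=9)
        assert np.array_equal(b1, b2)
        assert b1.sum() == 8

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            pf.binarize_median(np.zeros((3, 3)), seed=0)


class TestAssignConcentrations:
    @pytest.mark.parametrize(
        "variation,var_expected",
        [("high", 1.0), ("low", 0.25), ("none", 0.0)],
    )
    def test_mean_and_variance_exact(self, variation, var_expected):
        ls = pf.make_landscape(beta=5.0, variation=variation, seed=4)
        assert ls.grid.mean() == 1.0
        assert ls.grid.var() == var_expected
        assert ls.more_toxic.sum() == 72

    def test_unknown_variation(self):
        with pytest.raises(ValueError):
            pf.assign_concentrations(np.zeros((2, 2), bool), "medium")

    def test_landscape_deterministic(self):
        a = pf.make_landscape(beta=5.0, variation="high", seed=12)
        b = pf.make_landscape(beta=5.0, variation="high", seed=12)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.more_toxic, b.more_toxic)


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        checker = np.indices((4, 4)).sum(axis=0) % 2
        assert pf.morans_i(checker, "rook") == pytest.approx(-1.0)
        assert brute_force_morans_i(checker, "rook") == pytest.approx(-1.0)

    def test_two_solid_halves_positive(self):
        grid = np.zeros((6, 6))
        grid[:3] = 1.0
        assert pf.morans_i(grid) > 0
        assert pf.morans_i(grid) == pytest.approx(brute_force_morans_i(grid))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(5, 7))
        for adj in ("rook", "queen"):
            assert pf.morans_i(grid, adj) == pytest.approx(
                brute_force_morans_i(grid, adj)
            )

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(6, 6))
        assert pf.morans_i(grid) == pytest.approx(pf.morans_i(grid + 100.0))

    def test_constant_grid_error(self):
        with pytest.raises(ValueError):
            pf.morans_i(np.ones((4, 4)))


class TestEstimateExponent:
    def test_scale_invariance(self):
        f = pf.synthesize_field(SpectralParams(beta=2.0, seed=5))
        assert pf.estimate_spectral_exponent(f) == pytest.approx(
            pf.estimate_spectral_exponent(3.7 * f)
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            pf.estimate_spectral_exponent(np.ones((6, 6)))
        with pytest.raises(ValueError):
            pf.estimate_spectral_exponent(np.zeros((2, 2)))


class TestIO:
    def test_roundtrip(self, tmp_path, high_landscape):
        path = tmp_path / "ls.tsv"
        pf.write_landscape(high_landscape, path)
        back = pf.read_landscape(path)
        assert np.array_equal(back.grid, high_landscape.grid)
        assert np.array_equal(back.more_toxic, high_landscape.more_toxic)
        assert back.beta == high_landscape.beta

    def test_long_frame(self, high_landscape):
        df = landscape_long_frame(high_landscape)
        assert len(df) == 144
        assert set(df["tile_class"]) == {"more-toxic", "less-toxic"}
        # row 0 at top: first rows of the frame correspond to grid row 0
        assert np.array_equal(
            df[df["row"] == 0]["conc_mg_g"].to_numpy(), high_landscape.grid[0]
        )
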