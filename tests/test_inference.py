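"""Track inference: step derivation, HMM segmentation, iSSA estimation."""

import numpy as np
import pytest
from statsmodels.discrete.conditional_models import ConditionalLogit

import phytoforage as pf
from phytoforage.inference import (
    ISSA_COVARIATES,
    conditional_loglik,
    fit_tentative_gamma,
    issa_design,
)


def straight_track(n=5, step=1.0):
    t = np.arange(n) * 360.0
    return pf.Track(t, np.arange(n) * step + 1.0, np.full(n, 1.0))


class TestTrackToSteps:
    def test_collinear_track_zero_turns(self, high_landscape):
        steps = pf.track_to_steps(straight_track(6), high_landscape)
        assert np.allclose(steps["theta"].to_numpy()[1:], 0.0)
        assert np.isnan(steps["theta"].iloc[0])  # first step has no reference

    def test_right_angle_left_turn_positive(self, high_landscape):
        # east then north: counterclockwise turn of +pi/2
        track = pf.Track(
            np.arange(3) * 360.0, np.array([1.0, 2.0, 2.0]), np.array([1.0, 1.0, 2.0])
        )
        steps = pf.track_to_steps(track, high_landscape)
        assert steps["theta"].iloc[1] == pytest.approx(np.pi / 2)

    def test_stationary_track_flagged(self, high_landscape):
        track = pf.Track(np.arange(4) * 360.0, np.full(4, 3.0), np.full(4, 3.0))
        steps = pf.track_to_steps(track, high_landscape)
        assert np.all(steps["l"] == 0.0)
        assert np.all(np.isnan(steps["theta"]))

    def test_pause_preserves_heading_reference(self, high_landscape):
        # east, pause, then north: the turn is measured against the east heading
        track = pf.Track(
            np.arange(4) * 360.0,
            np.array([1.0, 2.0, 2.0, 2.0]),
            np.array([1.0, 1.0, 1.0, 2.0]),
        )
        steps = pf.track_to_steps(track, high_landscape)
        assert steps["theta"].iloc[2] == pytest.approx(np.pi / 2)

    def test_too_short_rejected(self, high_landscape):
        with pytest.raises(ValueError):
            pf.track_to_steps(straight_track(2), high_landscape)

    def test_step_lengths_are_displacements(self, high_landscape, null_track):
        steps = pf.track_to_steps(null_track, high_landscape)
        manual = np.hypot(np.diff(null_track.x_cm), np.diff(null_track.y_cm))
        assert np.allclose(steps["l"], manual)


class TestFitHmm:
    def test_two_state_recovery(self):
        df = pf.make_two_state_steps(1000, seed=0)
        fit = pf.fit_hmm(df, restarts=10, seed=1)
        truth = df["true_state"].to_numpy()
        acc = max(np.mean(fit.path == truth), np.mean(fit.path == 1 - truth))
        assert acc > 0.95
        # state 0 is the long-step (exploring) state
        assert fit.gamma_q[0] * fit.gamma_sigma[0] > fit.gamma_q[1] * fit.gamma_sigma[1]
        # ~10:1 scale separation recovered
        assert fit.gamma_sigma[0] / fit.gamma_sigma[1] > 3.0

    def test_loglik_monotone_and_rows_stochastic(self):
        df = pf.make_two_state_steps(600, seed=3)
        fit = pf.fit_hmm(df, restarts=3, seed=2)
        assert np.all(np.diff(fit.loglik_history) >= -1e-8)
        assert np.allclose(fit.transmat.sum(axis=1), 1.0, atol=1e-10)
        assert fit.init.sum() == pytest.approx(1.0)

    def test_zero_steps_floored(self):
        df = pf.make_two_state_steps(400, seed=4)
        df.loc[:10, "l"] = 0.0
        fit = pf.fit_hmm(df, restarts=2, seed=0)
        assert fit.n_zero_steps == 11
        assert np.isfinite(fit.loglik)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_hmm(pf.make_two_state_steps(2, seed=0))


@pytest.fixture(scope="module")
def strata(high_landscape, null_track):
    steps = pf.track_to_steps(null_track, high_landscape)
    tentative = fit_tentative_gamma(steps["l"].to_numpy())
    return (
        pf.sample_available_steps(steps, tentative, high_landscape, A=20, rng=5),
        steps,
        tentative,
    )


@pytest.fixture(scope="module")
def fitted(high_landscape, arrested_track):
    steps = pf.track_to_steps(arrested_track, high_landscape)
    tentative = fit_tentative_gamma(steps["l"].to_numpy())
    strata_ = pf.sample_available_steps(steps, tentative, high_landscape, A=20, rng=6)
    return strata_, tentative, pf.fit_issa(strata_, tentative)


class TestAvailableSteps:
    def test_stratum_layout(self, strata):
        df, steps, _ = strata
        sizes = df.groupby("stratum").size()
        assert (sizes == 21).all()
        assert (df.groupby("stratum")["case"].sum() == 1).all()
        # observed row first in each stratum
        assert (df.groupby("stratum")["case"].first() == 1).all()

    def test_shared_start_points(self, strata):
        df, _, _ = strata
        assert (df.groupby("stratum")["x_start"].nunique() == 1).all()
        assert (df.groupby("stratum")["y_start"].nunique() == 1).all()

    def test_available_lengths_match_tentative_gamma(self, strata):
        from scipy import stats as ss

        df, _, tentative = strata
        l_av = df.loc[df["case"] == 0, "l"].to_numpy()
        ks = ss.kstest(l_av, ss.gamma(a=tentative.q, scale=tentative.sigma).cdf)
        assert ks.pvalue > 0.01

    def test_requires_positive_A(self, strata, high_landscape):
        _, steps, tentative = strata
        with pytest.raises(ValueError):
            pf.sample_available_steps(steps, tentative, high_landscape, A=0)


class TestIssaFit:
    def test_null_loglik_closed_form(self, fitted):
        strata, _, _ = fitted
        S = strata["stratum"].nunique()
        assert conditional_loglik(strata, np.zeros(6)) == pytest.approx(
            -S * np.log(21)
        )

    def test_matches_statsmodels_oracle(self, fitted):
        strata, _, fit = fitted
        X, case = issa_design(strata)
        sm_fit = ConditionalLogit(
            case, X, groups=strata["stratum"].to_numpy()
        ).fit(disp=False)
        # statsmodels' default optimizer stops at a looser tolerance than the
        # Newton solver, so compare coefficients loosely and log-likelihoods
        # exactly: ours must be at least as high at its own optimum.
        assert np.allclose(fit.coef.to_numpy(), sm_fit.params, atol=0.02)
        assert np.allclose(fit.se.to_numpy(), sm_fit.bse, rtol=0.05)
        sm_ll = conditional_loglik(strata, np.asarray(sm_fit.params))
        assert fit.loglik >= sm_ll - 1e-6

    def test_recovers_strong_arrestment(self, fitted):
        # generating track used a=4, omega=1.25 on a clustered landscape
        _, _, fit = fitted
        assert fit.valid_kernel
        # single-replicate estimates are noisy; the distributional recovery
        # (median within factor 1.5 over many replicates) is tested elsewhere
        assert fit.arrestment > 1.0
        assert 4.0 / 4.0 < fit.arrestment < 4.0 * 4.0

    def test_invariant_to_available_order(self, fitted):
        strata, tentative, fit = fitted
        rng = np.random.default_rng(0)
        # random sort key per row, but the observed row keeps the smallest key
        key = rng.random(len(strata)) - strata["case"].to_numpy()
        shuffled = (
            strata.assign(_key=key)
            .sort_values(["stratum", "_key"], kind="stable")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        refit = pf.fit_issa(shuffled, tentative)
        assert np.allclose(refit.coef.to_numpy(), fit.coef.to_numpy(), atol=1e-8)

    def test_covariate_order_documented(self):
        assert ISSA_COVARIATES[0] == "dest_less"


class TestFullChain:
    def test_null_track_covers_truth(self, high_landscape):
        cfg = pf.SimConfig(n_steps=1200, seed=41)
        track = pf.simulate_track(
            high_landscape, pf.AgentBehaviour(), cfg, rng=np.random.default_rng(41)
        )
        fit = pf.fit_issa_for_track(track, high_landscape, A=20, seed=42)["all"]
        lo, hi = fit.arrestment_ci
        assert lo < 1.0 < hi
        lo, hi = fit.immigration_ci
        assert lo < 1.0 < hi

    def test_state_stratified_chain_runs(self, high_landscape, arrested_track):
        steps = pf.track_to_steps(arrested_track, high_landscape)
        hmm = pf.fit_hmm(steps, restarts=3, seed=7)
        fits = pf.fit_issa_for_track(
            arrested_track,
            high_landscape,
            A=10,
            seed=8,
            state_labels=hmm.state_labels,
        )
        assert set(fits) <= {"exploring", "resting"}
        assert all(f.converged or np.isfinite(f.loglik) for f in fits.values())
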