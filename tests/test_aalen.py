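"""Dynamic path analysis: least-squares hazard increments (Nelson-Aalen
limit, hand-solved normal equations, parameter recovery), event-time mediator
regressions, and the cumulative-sum effect curves."""

import numpy as np
import pandas as pd
import pytest

import survmediate as sm
from survmediate.aalen import (
    CumulativeCoefficients,
    MediatorPathFit,
    estimate_aalen,
    estimate_effects,
    fit_additive_increments,
    fit_mediator_at_event_times,
)
from survmediate.scenarios import get_scenario


class TestAdditiveIncrements:
    def test_intercept_only_equals_nelson_aalen(self, toy_survival_cohort):
        """With an intercept-only design the cumulative coefficient is the
        Nelson-Aalen estimator sum d_j / Y_j."""
        cc = fit_additive_increments(
            toy_survival_cohort, covariates=(), mediator=None
        )
        na = np.cumsum([1 / 5, 1 / 4, 1 / 3])
        assert np.allclose(cc.event_times, [1.1, 1.9, 2.4])
        assert np.allclose(cc.cumulative[:, 0], na)
        assert cc.cumulative_at([1.0], "intercept")[0] == 0.0

    def test_single_event_matches_hand_normal_equations(self):
        """4 individuals, one binary covariate, one event: the increment is
        the hand-solved least-squares solution (0 intercept, 1/2 slope)."""
        cohort = pd.DataFrame(
            {"id": range(4), "A": [0, 0, 1, 1], "T": [4.0, 4.0, 1.5, 4.0],
             "E": [0, 0, 1, 0]}
        )
        cc = fit_additive_increments(cohort, covariates=("A",), mediator=None)
        # X'X = [[4,2],[2,2]], X'dN = [1,1] -> beta = (0, 0.5)
        assert np.allclose(cc.increments[0], [0.0, 0.5])
        assert cc.risk_size[0] == 4 and cc.n_events[0] == 1

    def test_recovers_exposure_coefficient(self):
        """B_A(t) grows at the generating slope alpha_A (reference
        mechanism), within 3 MC SEs of the replicate mean."""
        cfg = get_scenario("baseline", n=8000, seed=0)
        vals = []
        for rep in range(8):
            cohort = sm.simulate_cohort(cfg, seed=300 + rep)
            cc = fit_additive_increments(cohort)
            t0 = cc.event_times[0]
            vals.append(cc.cumulative_at([3.5], "A")[0] / (3.5 - t0))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - cfg.alpha_A) < 3 * se

    def test_censored_individuals_stay_at_risk_until_censoring(self):
        cohort = pd.DataFrame(
            {"id": range(3), "A": [0, 1, 0], "T": [2.0, 4.0, 3.0],
             "E": [1, 0, 1]}
        )
        cc = fit_additive_increments(cohort, covariates=(), mediator=None)
        assert list(cc.risk_size) == [3, 2]

    def test_singular_design_modes(self):
        """A constant covariate makes X'X singular: pinv proceeds with a
        warning, strict mode raises."""
        cohort = pd.DataFrame(
            {"id": range(4), "A": [1, 1, 1, 1], "T": [1.5, 2.5, 4.0, 4.0],
             "E": [1, 1, 0, 0]}
        )
        cc = fit_additive_increments(cohort, covariates=("A",), mediator=None)
        assert cc.rank_deficient.all()
        with pytest.raises(np.linalg.LinAlgError):
            fit_additive_increments(
                cohort, covariates=("A",), mediator=None, singular="raise"
            )


class TestMediatorFit:
    def test_hand_solved_ols(self):
        """3 at-risk individuals with known responses reproduce the
        hand-solved OLS coefficients (intercept 1, slope 1.5)."""
        cohort = pd.DataFrame(
            {"id": range(3), "A": [0, 1, 1], "M_0": [0.0, 0.0, 0.0],
             "M_1": [1.0, 2.0, 3.0], "M_2": [1.0, 2.0, 3.0],
             "M_3": [1.0, 2.0, 3.0], "T": [1.5, 4.0, 4.0], "E": [1, 0, 0]}
        )
        mf = fit_mediator_at_event_times(cohort, covariates=("A",))
        # OLS of (1,2,3) on A=(0,1,1): intercept 1, slope 1.5
        assert np.allclose(mf.coefs[0], [1.0, 1.5])

    def test_noie_exposure_coefficient_centred_on_zero(self):
        cfg = get_scenario("baseline", "NoIE", n=8000, seed=1)
        cohort = sm.simulate_cohort(cfg)
        mf = fit_mediator_at_event_times(cohort)
        bA = mf.coef("A")
        se = bA.std(ddof=1) / np.sqrt(len(bA))
        # event-time coefficients are highly serially correlated; the
        # naive SE is inflated 20x to stay conservative
        assert abs(bA.mean()) < 3 * 20 * se

    def test_recovers_mediator_exposure_effect_per_interval(self):
        """Mean exposure coefficient over event times in (k, k+1] recovers
        the generating beta_A."""
        cfg = get_scenario("baseline", n=8000, seed=2)
        means = []
        for rep in range(6):
            cohort = sm.simulate_cohort(cfg, seed=800 + rep)
            mf = fit_mediator_at_event_times(cohort)
            sel = (mf.event_times > 2) & (mf.event_times <= 3)
            means.append(mf.coef("A")[sel].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - cfg.beta_A_at(2)) < 3 * se

    def test_tiny_risk_sets_carry_forward(self):
        cohort = pd.DataFrame(
            {"id": range(5), "A": [0, 1, 0, 1, 0], "M_0": 0.0,
             "M_1": [1.0, 2.0, 1.5, 2.5, 1.8], "M_2": [1.0, 2.0, 1.5, 2.5, 1.8],
             "M_3": [1.0, 2.0, 1.5, 2.5, 1.8],
             "T": [1.5, 1.8, 2.2, 3.0, 3.5], "E": 1}
        )
        mf = fit_mediator_at_event_times(cohort, covariates=("A",))
        assert mf.n_carried_forward > 0
        assert not np.isnan(mf.coefs).any()


class TestEffectCurves:
    @staticmethod
    def _hand_objects():
        times = np.array([1.2, 1.8])
        cc = CumulativeCoefficients(
            event_times=times,
            increments=np.array([[0.0, 0.03, 0.01], [0.0, 0.01, 0.02]]),
            names=["intercept", "A", "M_current"],
            risk_size=np.array([10, 8]),
            n_events=np.array([1, 1]),
            rank_deficient=np.zeros(2, bool),
        )
        mf = MediatorPathFit(
            event_times=times,
            coefs=np.array([[0.0, 0.5], [0.0, 0.5]]),
            names=["intercept", "A"],
            risk_size=np.array([10, 8]),
        )
        return cc, mf

    def test_hand_computed_arithmetic(self):
        """IE(2) = exp(-(0.5*0.01 + 0.5*0.02)) and DE(2) = exp(-0.04)."""
        cc, mf = self._hand_objects()
        ec = estimate_effects(cc, mf, [2.0])
        row = ec.curves.iloc[0]
        assert row["IE"] == pytest.approx(np.exp(-0.015))
        assert row["DE"] == pytest.approx(np.exp(-0.04))
        assert row["TE"] == pytest.approx(np.exp(-0.055))

    def test_zero_mediator_path_gives_unit_ie(self):
        cc, mf = self._hand_objects()
        mf.coefs[:, 1] = 0.0
        ec = estimate_effects(cc, mf, [1.0, 1.5, 2.0])
        assert np.allclose(ec.curves["IE"], 1.0)
        assert ec.curves["DE"].iloc[0] == 1.0  # before the first event time

    def test_mismatched_grids_rejected(self):
        cc, mf = self._hand_objects()
        mf.event_times = mf.event_times + 0.1
        with pytest.raises(ValueError, match="grids"):
            estimate_effects(cc, mf, [2.0])

    def test_te_identity_and_positivity(self, reference_cohort):
        ec = estimate_aalen(reference_cohort, [1.5, 2.0, 2.5, 3.0, 3.5])
        c = ec.curves
        assert np.allclose(c["TE"], c["IE"] * c["DE"], rtol=1e-12)
        assert (c[["IE", "DE", "TE"]] > 0).all().all()

    def test_log_ie_slope_recovers_alpha_m_beta_a(self):
        """Under constant coefficients -log IE(t) grows linearly at rate
        alpha_M * beta_A after the first visit."""
        cfg = get_scenario("baseline", n=8000, seed=3)
        slopes = []
        for rep in range(6):
            cohort = sm.simulate_cohort(cfg, seed=900 + rep)
            ec = estimate_aalen(cohort, [1.5, 3.5])
            li = -np.log(ec.curves["IE"].to_numpy())
            slopes.append((li[1] - li[0]) / 2.0)
        slopes = np.asarray(slopes)
        expected = cfg.alpha_M_at(2) * cfg.beta_A_at(2)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - expected) < 3 * se
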