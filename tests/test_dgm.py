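"""Generator-level checks: baseline draws, mediator moments, wave-based event
times, determinism, sub-scenario switches, the scenario registry, and the
synthetic annual-review registry."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import survmediate as sm
from survmediate.dgm import (
    ConfigError,
    HazardPositivityError,
    RegistrySyntheticConfig,
    ScenarioConfig,
    draw_baseline,
    generate_event_times,
    simulate_cohort,
    simulate_mediator_paths,
    simulate_registry,
)
from survmediate.scenarios import SCENARIO_NAMES, get_scenario


class TestBaselineDraws:
    def test_marginal_confounder_probability_is_half(self):
        """P(Z0=1|A=1)=0.6 and P(Z0=1|A=0)=0.4 with P(A=1)=0.5 give marginal
        P(Z0=1)=0.5, and joint P(A=1, Z0=1)=0.30."""
        cfg = get_scenario("baseline", n=100_000, seed=11)
        rng = np.random.default_rng(0)
        base = draw_baseline(cfg, rng)
        n = len(base)
        se = 3 * np.sqrt(0.25 / n)
        assert abs(base["Z0"].mean() - 0.5) < se
        joint = ((base["A"] == 1) & (base["Z0"] == 1)).mean()
        se_joint = 3 * np.sqrt(0.30 * 0.70 / n)
        assert abs(joint - 0.30) < se_joint

    def test_degenerate_exposure_probability(self):
        cfg = replace(get_scenario("baseline", n=500, seed=1), p_A=0.0)
        base = draw_baseline(cfg, np.random.default_rng(0))
        assert (base["A"] == 0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError, match="p_A"):
            replace(get_scenario("baseline"), p_A=1.2).validate()


class TestMediatorPaths:
    def test_noise_free_trajectory_is_flat_at_the_intercept(self):
        """With all variances and slopes zeroed the mediator sits at its mean
        intercept 2.9 forever."""
        cfg = replace(
            get_scenario("baseline", n=20, seed=3),
            mediator_re_cov=((0.0, 0.0), (0.0, 0.0)),
            mediator_resid_sd=0.0,
            beta_Z0=0.0,
            beta_A_schedule=(0.0, 0.0, 0.0),
        )
        base = draw_baseline(cfg, np.random.default_rng(0))
        paths = simulate_mediator_paths(cfg, base, np.random.default_rng(1))
        for t in (0, 1, 2, 3):
            assert np.allclose(paths[f"M_{t}"], 2.9)

    def test_mediator_mean_matches_structural_equation(self):
        """E[M_2 | A=1, Z0=1] = mu_m0 + 2 E[mu_m1] + beta_Z0 + beta_A2."""
        cfg = get_scenario("baseline", n=200_000, seed=5)
        base = draw_baseline(cfg, np.random.default_rng(2))
        paths = simulate_mediator_paths(cfg, base, np.random.default_rng(3))
        sel = (base["A"] == 1) & (base["Z0"] == 1)
        expected = 2.9 + 2 * 0.0 + cfg.beta_Z0 + cfg.beta_A_at(2)
        var = 0.25 + 4 * 0.01 + 2 * 2 * (-0.015) + 1.0
        se = 3 * np.sqrt(var / sel.sum())
        assert abs(paths.loc[sel, "M_2"].mean() - expected) < se

    def test_mediator_covariance_matches_random_effects_model(self):
        """Cov(M_1, M_2) = [1,1] Sigma_M [1,2]' ; Var(M_t) adds sigma^2."""
        cfg = get_scenario("baseline", n=200_000, seed=5)
        base = draw_baseline(cfg, np.random.default_rng(2))
        paths = simulate_mediator_paths(cfg, base, np.random.default_rng(3))
        S = np.asarray(cfg.mediator_re_cov)
        resid = paths[["M_1", "M_2"]] - 0  # noqa: mediator values
        # remove fixed-effect part by conditioning within (A, Z0) cells
        cell = paths[["M_1", "M_2"]].copy()
        cell["g"] = base["A"].astype(str) + base["Z0"].astype(str)
        covs = cell.groupby("g").cov()
        c12 = covs.xs("M_1", level=1)["M_2"].mean()
        v1 = covs.xs("M_1", level=1)["M_1"].mean()
        expect_c12 = np.array([1, 1]) @ S @ np.array([1, 2])
        expect_v1 = np.array([1, 1]) @ S @ np.array([1, 1]) + 1.0
        assert abs(c12 - expect_c12) < 0.02
        assert abs(v1 - expect_v1) < 0.02


class TestEventTimes:
    def test_constant_hazard_limit_is_truncated_exponential(self):
        """With only alpha_0 = c the event times are Exponential(c) censored
        at tau: P(T > tau) = exp(-c * tau)."""
        c = 0.4
        cfg = replace(
            get_scenario("baseline", n=100_000, seed=0),
            alpha_0=c, alpha_A=0.0, alpha_Z0=0.0, alpha_M_schedule=(0.0,) * 4,
        )
        cohort = simulate_cohort(cfg)
        p_cens = np.exp(-c * cfg.admin_censor_time)
        se = 3 * np.sqrt(p_cens * (1 - p_cens) / len(cohort))
        assert abs((cohort["E"] == 0).mean() - p_cens) < se

    def test_survival_matches_product_of_exponentials_oracle(self):
        """The empirical survival curve matches the product-integral
        Pi_w exp(-lambda_w * delta) computed from the same stored hazards."""
        cfg = get_scenario("baseline", n=100_000, seed=13)
        base = draw_baseline(cfg, np.random.default_rng(8))
        paths = simulate_mediator_paths(cfg, base, np.random.default_rng(9))
        T, E = generate_event_times(cfg, base, paths, np.random.default_rng(10))
        A, Z0 = base["A"].to_numpy(), base["Z0"].to_numpy()
        for t_eval in (1.0, 2.0, 3.0, 4.0):
            logS = np.zeros(len(base))
            for w in range(int(t_eval)):
                lam = (
                    cfg.alpha_0 + cfg.alpha_A * A + cfg.alpha_Z0 * Z0
                    + cfg.alpha_M_at(w) * paths[f"M_{w}"].to_numpy()
                )
                logS -= lam
            oracle = np.exp(logS).mean()
            emp = (T > t_eval - 1e-9).mean() if t_eval < 4 else (E == 0).mean()
            assert abs(emp - oracle) < 3 * np.sqrt(oracle * (1 - oracle) / len(base)) + 1e-3

    def test_nonpositive_hazard_raises_named_error(self):
        cfg = replace(
            get_scenario("baseline", n=50, seed=3),
            alpha_0=-1.0, alpha_A=0.0, alpha_Z0=0.0, alpha_M_schedule=(0.0,) * 4,
        )
        with pytest.raises(HazardPositivityError, match="wave"):
            simulate_cohort(cfg)

    def test_event_fraction_monotone_in_baseline_hazard(self):
        fracs = []
        for a0 in (0.1, 0.3, 0.5):
            cfg = replace(get_scenario("baseline", n=20_000, seed=4), alpha_0=a0)
            fracs.append(simulate_cohort(cfg)["E"].mean())
        assert fracs[0] < fracs[1] < fracs[2]


class TestSimulateCohort:
    def test_seeded_reproducibility(self, reference_config):
        a = simulate_cohort(reference_config, seed=99)
        b = simulate_cohort(reference_config, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_prefix_stability_when_n_grows(self):
        small = simulate_cohort(get_scenario("baseline", n=1000, seed=21))
        large = simulate_cohort(get_scenario("baseline", n=5000, seed=21))
        pd.testing.assert_frame_equal(small, large.iloc[:1000])

    def test_censoring_invariant(self, reference_cohort, reference_config):
        tau = reference_config.admin_censor_time
        cens = reference_cohort["E"] == 0
        assert (reference_cohort.loc[cens, "T"] == tau).all()
        assert (reference_cohort["T"] > 0).all()
        assert (reference_cohort["T"] <= tau).all()

    def test_no_post_death_measurements(self, reference_cohort):
        for t in (1, 2, 3):
            dead_before = reference_cohort["T"] < t
            assert reference_cohort.loc[dead_before, f"M_{t}"].isna().all()
            alive = reference_cohort["T"] >= t
            assert reference_cohort.loc[alive, f"M_{t}"].notna().all()

    def test_noie_mediator_distribution_independent_of_exposure(self):
        """With beta_A = 0 the post-exposure mediators have the same law in
        both exposure groups conditional on Z0 (KS test, generous alpha)."""
        from scipy.stats import ks_2samp

        cfg = get_scenario("baseline", "NoIE", n=50_000, seed=17)
        c = simulate_cohort(cfg)
        alive = c["T"] >= 3
        for z in (0, 1):
            sel = alive & (c["Z0"] == z)
            m1 = c.loc[sel & (c["A"] == 1), "M_3"]
            m0 = c.loc[sel & (c["A"] == 0), "M_3"]
            assert ks_2samp(m1, m0).pvalue > 1e-4

    def test_published_event_fractions(self):
        """Baseline lands in 87-89% events; F2 in 78-87%."""
        c = simulate_cohort(get_scenario("baseline", n=30_000, seed=23))
        assert 87 <= 100 * c["E"].mean() <= 89
        c = simulate_cohort(get_scenario("F2", n=30_000, seed=23))
        assert 78 <= 100 * c["E"].mean() <= 87


class TestScenarioRegistry:
    @pytest.mark.parametrize("name", SCENARIO_NAMES)
    @pytest.mark.parametrize("sub", ["DE+IE", "NoDE", "NoIE"])
    def test_positivity_audit(self, name, sub):
        """Every bundled scenario/sub-scenario simulates without a hazard
        positivity violation."""
        simulate_cohort(get_scenario(name, sub, n=4000, seed=29))

    def test_sub_scenario_switches(self):
        node = get_scenario("L6", "NoDE")
        assert node.alpha_A == 0.0
        assert all(v == 0.0 for v in node.confounder_block.psi_A)
        noie = get_scenario("L6", "NoIE")
        assert all(v == 0.0 for v in noie.beta_A_schedule)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            get_scenario("Z9")

    def test_f_scenarios_generate_on_quarter_grid(self):
        cfg = get_scenario("F1")
        assert len(cfg.grid()) == 16
        c = simulate_cohort(get_scenario("F1", n=200, seed=1))
        assert "M_0.25" in c.columns and "M_3.75" in c.columns


class TestSyntheticRegistry:
    def test_diagnosis_flag_is_absorbing(self, synthetic_registry):
        for _, g in synthetic_registry.groupby("id"):
            flags = g.sort_values("age")["diagnosed"].to_numpy()
            assert (np.diff(flags) >= 0).all()

    def test_no_reviews_after_outcome(self, synthetic_registry):
        assert (
            synthetic_registry["age"] <= synthetic_registry["outcome_age"]
        ).all()

    def test_review_count_matches_enumeration(self, synthetic_registry):
        """Row counts per individual equal direct enumeration of review ages
        between entry and outcome/exit."""
        cfg = RegistrySyntheticConfig(n=400, seed=5)
        for i, g in synthetic_registry.groupby("id"):
            entry = int(g["entry_age"].iloc[0])
            out = float(g["outcome_age"].iloc[0])
            expected = len(
                [a for a in range(entry, cfg.exit_age + 1) if a <= out]
            )
            assert len(g) == expected
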