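"""Single-SNP interaction regression and the stratified approximation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from grex import (PreparedPhenotype, SimulationConfig, StratifiedPair,
                  ValidationError, default_panel, fit_all_snps,
                  fit_single_snp_interaction, generate_cohort,
                  infer_interaction_from_strata, inverse_normal_transform,
                  prepare, prepare_stratified, residualize, wald_from_ci)

PANEL1 = default_panel("FEV1_FVC", m=1)


def _plant(n, beta_int, seed):
    config = SimulationConfig(
        n=n, panel=PANEL1, beta_int=np.array([beta_int]), seed=seed,
        study_id="mc")
    return generate_cohort(config), config


class TestSaturatedModel:
    def test_noiseless_coefficients_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n = 2_000
        g = rng.binomial(2, 0.4, n).astype(float)
        ever = rng.binomial(1, 0.5, n).astype(float)
        packyears = ever * rng.gamma(2.0, 10.0, n)
        current = ever * rng.binomial(1, 0.3, n)
        truth = dict(b0=0.3, bg=-0.04, bint=-0.02, b1=-0.01, b2=-0.003, b3=-0.05)
        y = (truth["b0"] + truth["bg"] * g + truth["bint"] * g * ever
             + truth["b1"] * ever + truth["b2"] * packyears + truth["b3"] * current)
        cohort = generate_cohort(SimulationConfig(n=n, panel=PANEL1, seed=0))
        cohort.genotypes[:, 0] = g
        cohort.ever, cohort.packyears, cohort.current = ever, packyears, current
        fit, stat = fit_single_snp_interaction(
            PreparedPhenotype(values=y), cohort, 0, "ever")
        assert fit.beta0 == pytest.approx(truth["b0"], abs=1e-8)
        assert fit.beta_g == pytest.approx(truth["bg"], abs=1e-8)
        assert fit.beta_int == pytest.approx(truth["bint"], abs=1e-8)
        assert fit.beta_exposures[0] == pytest.approx(truth["b1"], abs=1e-8)
        assert fit.beta_exposures[1] == pytest.approx(truth["b2"], abs=1e-8)
        assert fit.beta_exposures[2] == pytest.approx(truth["b3"], abs=1e-8)

    def test_planted_effect_within_two_se_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            cohort, _ = _plant(20_000, -0.05, seed)
            prepared = prepare(cohort)
            _, stat = fit_single_snp_interaction(prepared, cohort, 0, "ever")
            if abs(stat.beta_int - (-0.05)) <= 2 * stat.se_int:
                hits += 1
        assert hits >= 93

    def test_null_calibration(self):
        rejections = 0
        for seed in range(100, 200):
            cohort, _ = _plant(5_000, 0.0, seed)
            prepared = prepare(cohort)
            _, stat = fit_single_snp_interaction(prepared, cohort, 0, "ever")
            if abs(stat.z) > 1.96:
                rejections += 1
        assert 0 <= rejections <= 12  # ~5% expected of 100

    def test_se_shrinks_like_inverse_sqrt_n(self):
        cohort_small, _ = _plant(5_000, -0.02, 42)
        cohort_big, _ = _plant(20_000, -0.02, 43)
        _, s_small = fit_single_snp_interaction(prepare(cohort_small), cohort_small, 0, "ever")
        _, s_big = fit_single_snp_interaction(prepare(cohort_big), cohort_big, 0, "ever")
        assert s_small.se_int / s_big.se_int == pytest.approx(2.0, rel=0.10)

    def test_monomorphic_snp_rejected(self, small_cohort):
        cohort, _ = small_cohort
        frozen = cohort.genotypes.copy()
        try:
            cohort.genotypes[:, 0] = 2.0
            with pytest.raises(ValidationError, match="monomorphic"):
                fit_single_snp_interaction(
                    PreparedPhenotype(values=np.zeros(cohort.n) + np.arange(cohort.n)),
                    cohort, 0, "ever")
        finally:
            cohort.genotypes[:] = frozen

    def test_collinear_design_rejected(self):
        cohort, _ = _plant(1_000, 0.0, 9)
        frozen = (cohort.ever.copy(), cohort.packyears.copy(), cohort.current.copy())
        cohort.packyears[:] = cohort.ever * 2.0  # pack-years collinear with ever
        try:
            with pytest.raises(ValidationError, match="collinear"):
                fit_single_snp_interaction(
                    PreparedPhenotype(values=np.linspace(-1, 1, cohort.n)),
                    cohort, 0, "ever")
        finally:
            cohort.ever, cohort.packyears, cohort.current = frozen


class TestFitAllSnps:
    def test_full_panel_yields_one_record_per_snp(self, small_cohort):
        cohort, config = small_cohort
        records = fit_all_snps(prepare(cohort), cohort, config.panel, "ever")
        assert len(records) == 26
        assert [r.snp_id for r in records] == config.panel.snp_ids

    def test_monomorphic_snp_logged_not_fatal(self, small_cohort):
        cohort, config = small_cohort
        frozen = cohort.genotypes.copy()
        try:
            cohort.genotypes[:, 3] = 0.0
            records = fit_all_snps(prepare(cohort), cohort, config.panel, "ever")
            assert len(records) == 25
            assert config.panel.snp_ids[3] not in {r.snp_id for r in records}
        finally:
            cohort.genotypes[:] = frozen


class TestStratifiedInference:
    def test_hand_example(self):
        pair = StratifiedPair(beta_ever=-0.02, se_ever=0.01,
                              beta_never=-0.01, se_never=0.01,
                              n_ever=100, n_never=100)
        stat = infer_interaction_from_strata(pair)
        assert stat.beta_int == pytest.approx(-0.01, abs=1e-12)
        assert stat.se_int == pytest.approx(0.014142, abs=1e-5)

    def test_identical_strata_give_zero(self):
        pair = StratifiedPair(-0.02, 0.01, -0.02, 0.02, 50, 50)
        assert infer_interaction_from_strata(pair).beta_int == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            StratifiedPair(-0.02, 0.0, -0.01, 0.01, 10, 10)

    def test_unbiased_under_null_with_stratified_int(self):
        """Mean stratified-inference estimate ~0 with no true interaction."""
        rng = np.random.default_rng(77)
        estimates = []
        n_per = 5_000
        for _ in range(500):
            g = rng.binomial(2, 0.4, 2 * n_per).astype(float)
            y = -0.03 * g + rng.normal(size=2 * n_per)
            parts = []
            for sl in (slice(0, n_per), slice(n_per, None)):
                yt = inverse_normal_transform(y[sl])
                X = np.column_stack([np.ones(n_per), g[sl]])
                beta, *_ = np.linalg.lstsq(X, yt, rcond=None)
                resid = yt - X @ beta
                var = (resid @ resid / (n_per - 2)
                       * np.linalg.inv(X.T @ X)[1, 1])
                parts.append((beta[1], np.sqrt(var)))
            pair = StratifiedPair(parts[0][0], parts[0][1],
                                  parts[1][0], parts[1][1], n_per, n_per)
            estimates.append(infer_interaction_from_strata(pair).beta_int)
        assert abs(np.mean(estimates)) < 0.002

    def test_agrees_with_saturated_model_on_shared_data(self):
        cohort, _ = _plant(20_000, -0.05, 1234)
        prepared = prepare(cohort)  # pooled normalization for both routes
        _, sat = fit_single_snp_interaction(prepared, cohort, 0, "ever")
        parts = {}
        for label, mask in (("ever", cohort.ever == 1), ("never", cohort.ever == 0)):
            y = prepared.values[mask]
            X = np.column_stack([np.ones(mask.sum()), cohort.genotypes[mask, 0]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            var = resid @ resid / (mask.sum() - 2) * np.linalg.inv(X.T @ X)[1, 1]
            parts[label] = (beta[1], np.sqrt(var), int(mask.sum()))
        pair = StratifiedPair(*parts["ever"][:2], *parts["never"][:2],
                              parts["ever"][2], parts["never"][2])
        strat = infer_interaction_from_strata(pair)
        assert np.sign(strat.beta_int) == np.sign(sat.beta_int)
        pooled_se = np.hypot(strat.se_int, sat.se_int)
        assert abs(strat.beta_int - sat.beta_int) < 2 * pooled_se


class TestWaldFromCi:
    def test_replication_estimate_p_matches_printed_value(self):
        se, z, p = wald_from_ci(-0.0025, -0.0165, 0.0115, 0.95)
        assert p == pytest.approx(0.72, abs=0.01)

    def test_zero_beta_symmetric_ci(self):
        se, z, p = wald_from_ci(0.0, -1.0, 1.0, 0.95)
        assert z == 0.0 and p == 1.0

    def test_se_recovery(self):
        se, _, _ = wald_from_ci(-0.0030, -0.0214, 0.0154, 0.95)
        assert se == pytest.approx(0.00939, abs=1e-5)

    def test_inverted_ci_rejected(self):
        with pytest.raises(ValidationError):
            wald_from_ci(0.0, 1.0, -1.0, 0.95)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-5, 5), st.floats(0.01, 2.0), st.floats(0.5, 0.99))
    def test_se_round_trips_through_ci(self, beta, se_true, level):
        zq = stats.norm.ppf((1 + level) / 2)
        se, _, _ = wald_from_ci(beta, beta - zq * se_true, beta + zq * se_true, level)
        assert se == pytest.approx(se_true, rel=1e-9)
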