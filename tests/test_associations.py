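"""Association statistics: predictor transforms, arm-specific odds
ratios, the treatment-interaction Wald test, BH adjustment, the weighted
binomial abundance GLM and Wilcoxon comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icbspatial.associations import (
    adjust_fdr,
    compare_contact_activation,
    compare_groups_wilcoxon,
    differential_abundance_glm,
    fit_arm_specific_or,
    treatment_interaction_test,
    transform_predictor,
)
from icbspatial.registry import PhenotypeRegistry
from icbspatial.simulate import SyntheticConfig, simulate_image


class TestTransform:
    @pytest.mark.parametrize(
        "family,value,expected",
        [
            ("density", 4.0, 2.0),
            ("proliferative_fraction", 0.25, 5.0),
            ("heterotypic", 0.0, 0.0),
            ("homotypic", 0.04, 20.0),
        ],
    )
    def test_examples(self, family, value, expected):
        assert transform_predictor([value], family)[0] == pytest.approx(expected)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            transform_predictor([-0.1], "density")

    def test_scaling_leaves_p_value_unchanged(self, rng):
        """The ×10/×100 multipliers rescale coefficients only."""
        x = rng.uniform(0, 1, 120)
        y = (rng.random(120) < 0.3 + 0.4 * x).astype(int)
        f1 = fit_arm_specific_or(np.sqrt(x), y)
        f2 = fit_arm_specific_or(100 * np.sqrt(x), y)
        assert f1.p == pytest.approx(f2.p, rel=1e-6)
        assert f1.coef == pytest.approx(100 * f2.coef, rel=1e-5)


class TestArmSpecificOr:
    def test_2x2_contingency_oracle(self):
        """Saturated logistic OR equals the contingency cross-product:
        (15/5)/(5/15) = 9."""
        x = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(15), np.zeros(5), np.ones(5), np.zeros(15)]
        fit = fit_arm_specific_or(x, y)
        assert fit.odds_ratio == pytest.approx(9.0, rel=1e-6)

    def test_constant_predictor_flagged(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        assert fit_arm_specific_or(np.ones(10), y).separated

    def test_too_few_outcomes_raise(self):
        with pytest.raises(ValueError):
            fit_arm_specific_or(np.arange(5.0), np.array([1, 0, 0, 0, 0]))

    def test_ci_covers_one_for_null_predictor(self, rng):
        """Permuted predictors: the 95% CI should cover OR=1 ≈ 95% of the
        time."""
        n, reps, covered = 200, 200, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.integers(0, 2, n)
            fit = fit_arm_specific_or(x, y)
            lo, hi = fit.ci
            covered += lo <= 1.0 <= hi
        assert 0.91 <= covered / reps <= 0.99


class TestInteraction:
    def _binary_toy(self, or_c, or_i, n=40):
        def arm_block(or_):
            # exposed odds or_·(1/3), unexposed odds 1/3  (baseline 5/15)
            if or_ == 1.0:
                y1 = np.r_[np.ones(5), np.zeros(15)]
            else:  # OR 9: exposed 15/20 responders
                y1 = np.r_[np.ones(15), np.zeros(5)]
            y0 = np.r_[np.ones(5), np.zeros(15)]
            x = np.r_[np.ones(20), np.zeros(20)]
            return x, np.r_[y1, y0]

        xc, yc = arm_block(or_c)
        xi, yi = arm_block(or_i)
        x = np.r_[xc, xi]
        y = np.r_[yc, yi]
        arm = np.array(["C"] * 40 + ["C&I"] * 40)
        return x, y, arm

    def test_identical_arms_zero_interaction(self):
        x, y, arm = self._binary_toy(1.0, 1.0)
        fit = treatment_interaction_test(x, y, arm)
        assert abs(fit.coef) < 1e-6

    def test_interaction_equals_log_or_ratio(self):
        x, y, arm = self._binary_toy(1.0, 9.0)
        fit = treatment_interaction_test(x, y, arm)
        assert fit.coef == pytest.approx(np.log(9.0), rel=1e-6)

    def test_one_arm_raises(self):
        x = np.arange(10.0)
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError):
            treatment_interaction_test(x, y, np.array(["C"] * 10))

    def test_null_p_values_are_uniform(self, rng):
        """Interaction p-values under the null pass a KS uniformity check."""
        from scipy import stats

        ps = []
        for _ in range(400):
            n = 300
            x = rng.standard_normal(n)
            y = rng.integers(0, 2, n)
            arm = np.array(["C", "C&I"])[rng.integers(0, 2, n)]
            ps.append(treatment_interaction_test(x, y, arm).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFdr:
    def test_single_p(self):
        assert adjust_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computation(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough(self):
        out = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_order_invariant_and_at_least_raw_min(self, ps):
        p = np.asarray(ps)
        perm = np.random.default_rng(0).permutation(len(p))
        out = adjust_fdr(p)
        out_perm = adjust_fdr(p[perm])
        assert np.allclose(out[perm], out_perm)
        assert (out >= p - 1e-12).all() and (out <= 1.0 + 1e-12).all()


class TestAbundanceGlm:
    def test_identical_groups_zero_effect(self):
        r = differential_abundance_glm([0.2, 0.2], [100, 100], [0, 1])
        assert abs(r.log2_odds_ratio) < 1e-8

    def test_weighted_pooled_odds_oracle(self):
        """Pooled odds (0.25/0.75)/(0.1/0.9) = 3 → log2 OR = log2 3."""
        r = differential_abundance_glm(
            [0.2, 0.3, 0.1, 0.1], [100, 100, 100, 100], [1, 1, 0, 0]
        )
        assert r.log2_odds_ratio == pytest.approx(np.log2(3), rel=1e-6)

    def test_unequal_weights_shift_pooling(self):
        # weights matter: pooled A = (20+30)/200 with equal totals,
        # but (0.2*300 + 0.3*100)/400 = 0.225 with unequal totals
        r_eq = differential_abundance_glm([0.2, 0.3, 0.1, 0.1], [100] * 4, [1, 1, 0, 0])
        r_uneq = differential_abundance_glm(
            [0.2, 0.3, 0.1, 0.1], [300, 100, 100, 100], [1, 1, 0, 0]
        )
        assert r_eq.log2_odds_ratio != pytest.approx(r_uneq.log2_odds_ratio)

    def test_empty_proportion_group_separation_flag(self):
        r = differential_abundance_glm([0.0, 0.0, 0.2, 0.3], [50] * 4, [0, 0, 1, 1])
        assert r.separated

    def test_one_group_empty_raises(self):
        with pytest.raises(ValueError):
            differential_abundance_glm([0.2, 0.3], [100, 100], [1, 1])


class TestWilcoxon:
    def test_identical_samples_p_near_one(self):
        _, p = compare_groups_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_permutation_oracle(self):
        """{1,2,3} vs {10,11,12}: most extreme of C(6,3)=20 arrangements,
        two-sided exact p = 2/20 = 0.1."""
        _, p = compare_groups_wilcoxon([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups_wilcoxon([], [1.0])


class TestContactActivation:
    def _cohort_cells(self, shift, n_tumours=12, seed=0):
        reg = PhenotypeRegistry()
        cfg = SyntheticConfig(
            seed=0, contact_radius_um=25.0, contact_activation_shift=shift
        )
        comp = pd.Series(
            np.full(reg.n_phenotypes, 1.0 / reg.n_phenotypes),
            index=reg.all_phenotypes,
        )
        rng = np.random.default_rng(seed)
        frames = []
        for t in range(n_tumours):
            cells, _ = simulate_image(
                rng, 250, comp, cfg, {p: 0.2 for p in reg.all_phenotypes}
            )
            cells["tumour_id"] = f"T{t}"
            frames.append(cells)
        return pd.concat(frames, ignore_index=True), reg

    def test_shift_detected(self):
        cells, reg = self._cohort_cells(shift=0.8, n_tumours=20)
        res = compare_contact_activation(cells, ["TOX", "PD1"], reg)
        assert (res["p"] < 0.01).all()
        assert (res["mean_in_contact"] > res["mean_not_in_contact"]).all()

    def test_insufficient_tumours_raise(self):
        cells, reg = self._cohort_cells(shift=0.5, n_tumours=2)
        with pytest.raises(ValueError, match="≥ 3 tumours"):
            compare_contact_activation(cells, ["TOX"], reg)
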