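"""Correlations, VIF, FDR, adjusted regression, spin test and mediation."""

import numpy as np
import pytest

from connectoflex.inference import (
    adjusted_regression,
    bh_fdr,
    moderated_mediation,
    pearson,
    rescale_unit,
    serial_mediation,
    spin_test,
    vif,
)
from connectoflex.synthetic_data import gen_sphere_coords


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.standard_normal(20)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_closed_form_small_vector(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        # product-moment formula by hand
        want = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson(x, y)[0] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestVif:
    def test_orthogonal_predictors(self):
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0])
        np.testing.assert_allclose(vif([x1, x2]), [1.0, 1.0], atol=1e-12)

    def test_duplicated_predictor_flagged_infinite(self, rng):
        x = rng.standard_normal(30)
        out = vif([x, x.copy(), rng.standard_normal(30)])
        assert np.isinf(out[0]) and np.isinf(out[1])

    def test_r06_closed_form(self):
        # two standardized predictors with sample correlation exactly 0.6
        n = 50
        rng = np.random.default_rng(0)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        # Gram-Schmidt to exact r = 0.6
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a
        b /= b.std()
        x2 = 0.6 * a + np.sqrt(1 - 0.36) * b
        np.testing.assert_allclose(vif([a, x2]), [1.5625, 1.5625], atol=1e-9)


class TestBhFdr:
    def test_stepup_hand_example(self):
        reject, p_adj = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()  # thresholds 0.0125, 0.025, 0.0375, 0.05

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert bh_fdr([0.04], q=0.05)[0][0]
        assert not bh_fdr([0.06], q=0.05)[0][0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(25)
        _, p_adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-15)


class TestRescaleUnit:
    def test_affine(self):
        np.testing.assert_allclose(rescale_unit([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    def test_unit_range_unchanged(self):
        v = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(rescale_unit(v), v)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_unit([3.0, 3.0])


class TestAdjustedRegression:
    def test_exact_linear_relation(self, rng):
        x = rng.standard_normal(30)
        res = adjusted_regression(2 * x, x)
        assert res.coef == pytest.approx(2.0, abs=1e-10)
        assert abs(res.partial_r) == pytest.approx(1.0, abs=1e-6)

    def test_covariate_absorbs_effect(self, rng):
        n = 200
        age = rng.standard_normal(n)
        x = rng.standard_normal(n)  # independent of age
        res = adjusted_regression(y=age, x=x, covariates=[age])
        assert abs(res.partial_r) < 0.05
        assert res.p > 0.1

    def test_p_matches_reference_ols(self, rng):
        import statsmodels.api as sm

        n = 60
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = 0.4 * x + 0.2 * z + rng.standard_normal(n)
        res = adjusted_regression(y, x, covariates=[z])
        ref = sm.OLS(y, sm.add_constant(np.column_stack([x, z]))).fit()
        assert res.p == pytest.approx(ref.pvalues[1], abs=1e-8)
        assert res.coef == pytest.approx(ref.params[1], abs=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank"):
            adjusted_regression(rng.standard_normal(20), x, covariates=[x])


class TestSpinTest:
    def test_identical_maps_smallest_p(self, rng):
        coords = gen_sphere_coords(40, seed=2)
        smooth = coords.xyz @ np.array([0.7, -0.2, 0.4])
        res = spin_test(smooth, smooth, coords, n_perm=1000, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_spin <= 0.01

    def test_bit_reproducible(self, rng):
        coords = gen_sphere_coords(30, seed=5)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        r1 = spin_test(a, b, coords, n_perm=200, seed=9)
        r2 = spin_test(a, b, coords, n_perm=200, seed=9)
        assert r1.p_spin == r2.p_spin
        np.testing.assert_array_equal(r1.null_r, r2.null_r)

    def test_subcortical_nodes_excluded(self, rng):
        coords = gen_sphere_coords(30, n_subcortical=6, seed=1)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        res = spin_test(a, b, coords, n_perm=150, seed=3)
        assert res.n_cortical == 24

    def test_default_permutation_count_in_result(self, rng):
        import inspect

        from connectoflex.inference import spin_test as st_fn

        assert inspect.signature(st_fn).parameters["n_perm"].default == 100_000

    def test_too_few_permutations_rejected(self, rng):
        coords = gen_sphere_coords(10, seed=0)
        with pytest.raises(ValueError):
            spin_test(rng.random(10), rng.random(10), coords, n_perm=10)


def chain_data(rng, n, a1=0.5, d21=0.4, b2=0.6, eps=0.05):
    x = rng.standard_normal(n)
    m1 = a1 * x + eps * rng.standard_normal(n)
    m2 = d21 * m1 + eps * rng.standard_normal(n)
    y = b2 * m2 + eps * rng.standard_normal(n)
    return x, m1, m2, y


class TestSerialMediation:
    def test_effect_decomposition_identity(self, rng):
        # c = c' + total indirect holds exactly for nested OLS
        n = 80
        x, m1, m2, y = (rng.standard_normal(n) for _ in range(4))
        cov = rng.standard_normal((n, 2))
        for covariates in (None, cov):
            med = serial_mediation(x, m1, m2, y, covariates=covariates, n_boot=100, seed=0)
            assert med.c_total == pytest.approx(
                med.c_prime + med.indirect_total, abs=1e-8
            )

    def test_recovers_generative_chain(self, rng):
        x, m1, m2, y = chain_data(rng, 5000)
        med = serial_mediation(x, m1, m2, y, n_boot=400, seed=1)
        assert med.indirect_serial == pytest.approx(0.12, abs=0.02)
        lo, hi = med.ci["indirect_serial"]
        assert lo > 0
        dlo, dhi = med.ci["direct"]
        assert dlo < 0 < dhi  # no direct path planted

    def test_rescale_flag(self, rng):
        x, m1, m2, y = chain_data(rng, 300)
        med = serial_mediation(x, m1, m2, y, n_boot=150, seed=0, rescale=True)
        assert np.isfinite(med.indirect_serial)

    def test_small_bootstrap_rejected(self, rng):
        x, m1, m2, y = chain_data(rng, 50)
        with pytest.raises(ValueError, match="n_boot"):
            serial_mediation(x, m1, m2, y, n_boot=50, seed=0)


class TestModeratedMediation:
    def test_zero_variance_moderator_rejected(self, rng):
        x, m1, m2, y = chain_data(rng, 60)
        with pytest.raises(ValueError, match="moderator"):
            moderated_mediation(x, m1, m2, y, np.ones(60), n_boot=150, seed=0)

    def test_null_interaction_conditional_effects_agree(self, rng):
        x, m1, m2, y = chain_data(rng, 2000, eps=0.2)
        w = rng.standard_normal(2000)  # no interaction planted
        res = moderated_mediation(x, m1, m2, y, w, n_boot=300, seed=2)
        assert res.effect_low == pytest.approx(res.effect_high, abs=0.05)
        unmoderated = serial_mediation(x, m1, m2, y, n_boot=100, seed=2).indirect_serial
        for ci in (res.ci_low, res.ci_high):
            assert ci[0] < unmoderated < ci[1]

    def test_positive_interaction_orders_conditional_effects(self):
        wins = 0
        n_sims = 40
        for s in range(n_sims):
            rng = np.random.default_rng(500 + s)
            n = 400
            x = rng.standard_normal(n)
            w = rng.standard_normal(n)
            m1 = (0.4 + 0.4 * w) * x + 0.2 * rng.standard_normal(n)
            m2 = 0.5 * m1 + 0.2 * rng.standard_normal(n)
            y = 0.6 * m2 + 0.2 * rng.standard_normal(n)
            res = moderated_mediation(x, m1, m2, y, w, n_boot=120, seed=s)
            wins += res.effect_high > res.effect_low
        assert wins >= int(0.95 * n_sims)
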