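import numpy as np
import pytest
from conftest import (
    augmented_toy,
    dense_gls_oracle,
    dense_reml_loglik_oracle,
    random_mixed_instance,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from metsel.lmm import (
    ModelSpec,
    VarianceComponents,
    heritability,
    reml_fit,
    reml_loglik,
    solve_mme,
)


def balanced_oneway(rng, q=6, r=5, vu=2.0, ve=1.0):
    geno = np.repeat([f"g{i}" for i in range(q)], r)
    u = rng.normal(0, np.sqrt(vu), q)
    y = 5.0 + np.repeat(u, r) + rng.normal(0, np.sqrt(ve), q * r)
    return y, geno


class TestModelSpec:
    def test_rejects_nonfinite_response(self):
        with pytest.raises(ValueError, match="non-finite"):
            ModelSpec(response=np.array([1.0, np.nan]), fixed=np.array(["a", "b"]))

    def test_rejects_single_level_factor(self):
        with pytest.raises(ValueError, match="2 levels"):
            ModelSpec(response=np.ones(3), random=np.array(["a", "a", "a"]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ModelSpec(response=np.ones(3), fixed=np.array(["a", "b"]))


class TestRemlFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_balanced_oneway_matches_anova_estimators(self, seed):
        # closed-form oracle: sg2 = (MSB - MSW)/r, se2 = MSW when MSB > MSW
        rng = np.random.default_rng(seed)
        q, r = 8, 6
        y, geno = balanced_oneway(rng, q=q, r=r, vu=3.0, ve=1.0)
        means = y.reshape(q, r).mean(axis=1)
        msb = r * ((means - y.mean()) ** 2).sum() / (q - 1)
        msw = ((y.reshape(q, r) - means[:, None]) ** 2).sum() / (q * (r - 1))
        assert msb > msw, "seed produced MSB <= MSW; pick another"
        vc = reml_fit(ModelSpec(response=y, random=geno, genotype_term="random"))
        assert vc.converged
        assert vc.v_error == pytest.approx(msw, rel=1e-5)
        assert vc.v_random == pytest.approx((msb - msw) / r, rel=1e-5)

    def test_loglik_matches_dense_oracle_on_grid(self):
        # 30-observation instance: criterion value at arbitrary grid points
        rng = np.random.default_rng(7)
        y, fixed, random, *_ = random_mixed_instance(rng, max_obs=30)
        spec = ModelSpec(response=y, fixed=fixed, random=random)
        for vu in [0.05, 0.5, 2.0]:
            for ve in [0.3, 1.0, 4.0]:
                mine = reml_loglik(spec, vu, ve)
                oracle = dense_reml_loglik_oracle(y, fixed, random, vu, ve)
                assert mine == pytest.approx(oracle, abs=1e-6)

    def test_optimum_beats_grid(self):
        rng = np.random.default_rng(11)
        y, fixed, random, *_ = random_mixed_instance(rng, max_obs=30)
        spec = ModelSpec(response=y, fixed=fixed, random=random)
        vc = reml_fit(spec)
        grid = [
            reml_loglik(spec, lam * ve, ve)
            for lam in np.geomspace(1e-4, 1e4, 25)
            for ve in [vc.v_error * f for f in (0.5, 1.0, 2.0)]
        ]
        assert vc.reml_loglik >= max(grid) - 1e-6

    def test_constant_response_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            vc = reml_fit(ModelSpec(response=np.full(8, 3.0),
                                    random=np.array(list("aabbccdd"))))
        assert vc.boundary
        assert vc.v_error == 0.0

    def test_zero_within_level_variance_flagged(self):
        # exact level means, no noise -> v_error collapses to the boundary
        y = np.repeat([1.0, 5.0, 9.0], 4)
        geno = np.repeat(["a", "b", "c"], 4)
        with pytest.warns(UserWarning, match="collapsed"):
            vc = reml_fit(ModelSpec(response=y, random=geno))
        assert vc.boundary
        assert vc.v_error == pytest.approx(0.0, abs=1e-8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        y, fixed, random, *_ = random_mixed_instance(rng)
        a = reml_fit(ModelSpec(response=y, fixed=fixed, random=random))
        b = reml_fit(ModelSpec(response=y + 1234.5, fixed=fixed, random=random))
        assert a.v_random == pytest.approx(b.v_random, rel=1e-6, abs=1e-10)
        assert a.v_error == pytest.approx(b.v_error, rel=1e-6)

    def test_requires_random_factor(self):
        with pytest.raises(ValueError, match="random factor"):
            reml_fit(ModelSpec(response=np.arange(4.0), fixed=np.array(list("abab"))))

    def test_saturated_fixed_factor_rejected(self):
        y = np.arange(4.0)
        with pytest.raises(ValueError, match="degrees of freedom"):
            reml_fit(ModelSpec(response=y, fixed=np.array(list("abcd")),
                               random=np.array(list("xyxy"))))


class TestSolveMme:
    def test_balanced_oneway_shrinkage_closed_form(self):
        rng = np.random.default_rng(2)
        q, r = 5, 4
        y, geno = balanced_oneway(rng, q=q, r=r)
        vu, ve = 1.7, 0.9
        vc = VarianceComponents(vu, ve, 0.0, True, 1)
        est = solve_mme(ModelSpec(response=y, random=geno, genotype_term="random"), vc)
        means = np.array([y[geno == g].mean() for g in est.random_levels])
        shrink = r * vu / (r * vu + ve)
        np.testing.assert_allclose(
            est.random_predictions, shrink * (means - y.mean()), atol=1e-10
        )

    def test_infinite_variance_limit_no_shrinkage(self):
        rng = np.random.default_rng(3)
        y, geno = balanced_oneway(rng, q=4, r=3)
        vc = VarianceComponents(1e12, 1.0, 0.0, True, 1)
        est = solve_mme(ModelSpec(response=y, random=geno, genotype_term="random"), vc)
        means = np.array([y[geno == g].mean() for g in est.random_levels])
        np.testing.assert_allclose(est.random_predictions, means - y.mean(), atol=1e-6)

    def test_augmented_toy_matches_dense_gls(self):
        df = augmented_toy(seed=1)
        y = df["value"].to_numpy()
        vu, ve = 0.4, 0.25
        vc = VarianceComponents(vu, ve, 0.0, True, 1)
        spec = ModelSpec(response=y, fixed=df["genotype"].to_numpy(),
                         random=df["block"].to_numpy())
        est = solve_mme(spec, vc)
        flev, beta, se, rlev, u = dense_gls_oracle(
            y, df["genotype"].to_numpy(), df["block"].to_numpy(), vu, ve
        )
        assert list(est.fixed_levels) == list(flev)
        np.testing.assert_allclose(est.fixed_estimates, beta, atol=1e-9)
        np.testing.assert_allclose(est.random_predictions, u, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_dense_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        y, fixed, random, vu, ve = random_mixed_instance(rng)
        spec = ModelSpec(response=y, fixed=fixed, random=random)
        est = solve_mme(spec, VarianceComponents(vu, ve, 0.0, True, 1))
        _, beta, se, _, u = dense_gls_oracle(y, fixed, random, vu, ve)
        np.testing.assert_allclose(est.fixed_estimates, beta, atol=1e-8)
        np.testing.assert_allclose(est.random_predictions, u, atol=1e-8)
        np.testing.assert_allclose(est.fixed_se, se * np.sqrt(1.0), atol=1e-8)

    def test_random_predictions_sum_to_zero_balanced(self):
        rng = np.random.default_rng(9)
        y, geno = balanced_oneway(rng, q=6, r=4)
        vc = VarianceComponents(1.0, 1.0, 0.0, True, 1)
        est = solve_mme(ModelSpec(response=y, random=geno, genotype_term="random"), vc)
        assert abs(est.random_predictions.sum()) < 1e-8

    def test_shrinkage_monotone_in_v_error(self):
        rng = np.random.default_rng(4)
        y, geno = balanced_oneway(rng, q=5, r=3)
        spec = ModelSpec(response=y, random=geno, genotype_term="random")
        prev = None
        for ve in [0.1, 0.5, 1.0, 5.0, 25.0]:
            est = solve_mme(spec, VarianceComponents(1.0, ve, 0.0, True, 1))
            mags = np.abs(est.random_predictions)
            if prev is not None:
                assert np.all(mags <= prev + 1e-12)
            prev = mags

    def test_zero_random_variance_gives_ols(self):
        df = augmented_toy(seed=2)
        spec = ModelSpec(response=df["value"].to_numpy(),
                         fixed=df["genotype"].to_numpy(),
                         random=df["block"].to_numpy())
        est = solve_mme(spec, VarianceComponents(0.0, 1.0, 0.0, True, 1))
        assert np.all(est.random_predictions == 0)
        # cell means for genotypes observed once
        one = df.groupby("genotype")["value"].mean()
        np.testing.assert_allclose(
            est.fixed_estimates, one.loc[est.fixed_levels].to_numpy(), atol=1e-12
        )


@settings(max_examples=25, deadline=None)
@given(shift=st.floats(-1e4, 1e4, allow_nan=False), seed=st.integers(0, 50))
def test_property_reml_shift_invariance(shift, seed):
    rng = np.random.default_rng(seed)
    y, geno = (lambda q=4, r=3: (
        np.repeat(rng.normal(0, 1.2, q), r) + rng.normal(0, 0.8, q * r),
        np.repeat([f"g{i}" for i in range(q)], r),
    ))()
    a = reml_fit(ModelSpec(response=y, random=geno))
    b = reml_fit(ModelSpec(response=y + shift, random=geno))
    assert a.v_random == pytest.approx(b.v_random, rel=1e-5, abs=1e-8)
    assert a.v_error == pytest.approx(b.v_error, rel=1e-5, abs=1e-8)


class TestHeritability:
    def test_equal_components_half(self):
        assert heritability(VarianceComponents(2.0, 2.0, 0.0, True, 1)) == 0.5

    def test_zero_error_one(self):
        assert heritability(VarianceComponents(1.5, 0.0, 0.0, True, 1)) == 1.0

    def test_three_to_one(self):
        assert heritability(VarianceComponents(3.0, 1.0, 0.0, True, 1)) == 0.75

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability(VarianceComponents(0.0, 0.0, 0.0, True, 1))
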