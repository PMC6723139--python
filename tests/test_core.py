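"""Unit tests for the pure model mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varscale.core import (
    ScenarioConfig,
    derive_variance_components,
    environmental_breeding_values,
    gcv_from_v,
    pearson_correlation,
    rescale_trait_breeding_values,
    scale_deviations,
    simulate_base_records,
    simulate_population,
)


class TestVarianceComponents:
    @pytest.mark.parametrize(
        "mu, cv, h2, sp2, su2, se2",
        [
            (100.0, 0.15, 0.15, 225.0, 33.75, 191.25),
            (100.0, 0.05, 0.50, 25.0, 12.5, 12.5),
            (1.0, 1.0, 0.5, 1.0, 0.5, 0.5),
        ],
    )
    def test_reference_components(self, mu, cv, h2, sp2, su2, se2):
        vc = derive_variance_components(mu, cv, h2)
        assert vc.sigma_p2 == pytest.approx(sp2)
        assert vc.sigma_u2 == pytest.approx(su2)
        assert vc.sigma_e2 == pytest.approx(se2)
        assert vc.sigma_p == pytest.approx(np.sqrt(sp2))
        assert vc.sigma_u == pytest.approx(np.sqrt(su2))
        assert vc.sigma_e == pytest.approx(np.sqrt(se2))

    @given(
        mu=st.floats(0.01, 1e4),
        cv=st.floats(0.001, 2.0),
        h2=st.floats(0.001, 0.999),
    )
    @settings(max_examples=100, derandomize=True)
    def test_variance_conservation(self, mu, cv, h2):
        vc = derive_variance_components(mu, cv, h2)
        assert vc.sigma_u2 + vc.sigma_e2 == pytest.approx(vc.sigma_p2, rel=1e-12)
        assert vc.sigma_p2 > 0 and vc.sigma_u2 > 0 and vc.sigma_e2 > 0

    @pytest.mark.parametrize(
        "mu, cv, h2",
        [(-1.0, 0.1, 0.5), (100.0, 0.0, 0.5), (100.0, 0.1, 0.0), (100.0, 0.1, 1.0)],
    )
    def test_domain_errors(self, mu, cv, h2):
        with pytest.raises(ValueError):
            derive_variance_components(mu, cv, h2)


class TestBaseRecords:
    def test_zero_deviates_give_mu(self):
        vc = derive_variance_components(100.0, 0.1, 0.3)
        a, e, y = simulate_base_records(vc, 100.0, np.zeros(5), np.zeros(5))
        assert np.all(a == 0) and np.all(e == 0) and np.all(y == 100.0)

    def test_single_individual_arithmetic(self):
        vc = derive_variance_components(100.0, 0.05, 0.36)  # sigma_u=3, sigma_e=4
        a, e, y = simulate_base_records(vc, 100.0, np.array([1.0]), np.array([-1.0]))
        assert a == pytest.approx([3.0])
        assert e == pytest.approx([-4.0])
        assert y == pytest.approx([99.0])

    def test_additive_identity(self, rng):
        vc = derive_variance_components(100.0, 0.2, 0.4)
        a, e, y = simulate_base_records(
            vc, 100.0, rng.standard_normal(100), rng.standard_normal(100)
        )
        np.testing.assert_allclose(y, 100.0 + a + e)

    def test_length_mismatch(self):
        vc = derive_variance_components(100.0, 0.1, 0.3)
        with pytest.raises(ValueError, match="shape"):
            simulate_base_records(vc, 100.0, np.zeros(3), np.zeros(4))

    def test_negative_record_rate_at_high_cv(self, rng):
        # y ~ N(100, 50^2): P(y < 0) = Phi(-2) ~ 2.275%
        vc = derive_variance_components(100.0, 0.5, 0.3)
        _, _, y = simulate_base_records(
            vc, 100.0, rng.standard_normal(100_000), rng.standard_normal(100_000)
        )
        frac = np.mean(y < 0)
        assert frac == pytest.approx(0.02275, abs=0.003)


class TestScaleDeviations:
    def test_record_at_mean_reproduces_homogeneous_components(self):
        sp, se, su, n_neg = scale_deviations(np.array([100.0]), 0.15, 0.15)
        assert sp == pytest.approx([15.0])
        assert se == pytest.approx([15.0 * np.sqrt(0.85)])
        assert su == pytest.approx([15.0 * np.sqrt(0.15)])
        assert n_neg == 0

    def test_sign_flip_under_fold_convention(self):
        pos = scale_deviations(np.array([100.0]), 0.15, 0.15)
        neg = scale_deviations(np.array([-100.0]), 0.15, 0.15)
        for p, n in zip(pos[:3], neg[:3]):
            np.testing.assert_allclose(p, n)
        assert neg[3] == 1

    def test_proportionality_to_record(self):
        sp, se, _, _ = scale_deviations(np.array([50.0, 200.0]), 0.1, 0.25)
        np.testing.assert_allclose(sp, [5.0, 20.0])
        np.testing.assert_allclose(se, [5.0 * np.sqrt(0.75), 20.0 * np.sqrt(0.75)])

    def test_heritability_split_is_elementwise_exact(self, rng):
        y = rng.normal(100, 30, size=1000)
        y = y[y != 0]
        sp, se, su, _ = scale_deviations(y, 0.3, 0.4)
        np.testing.assert_allclose(se / sp, np.sqrt(0.6))
        np.testing.assert_allclose(su / sp, np.sqrt(0.4))
        assert np.all(sp > 0) and np.all(se > 0) and np.all(su > 0)

    def test_flip_residual_convention_keeps_signed_genetic_sd(self):
        sp, se, su, n_neg = scale_deviations(
            np.array([-100.0]), 0.15, 0.15, negative_handling="flip_residual"
        )
        assert sp[0] == pytest.approx(-15.0)
        assert se[0] == pytest.approx(15.0 * np.sqrt(0.85))
        assert su[0] == pytest.approx(-15.0 * np.sqrt(0.15))
        assert n_neg == 1

    def test_zero_record_is_an_error(self):
        with pytest.raises(ValueError, match="exactly 0"):
            scale_deviations(np.array([10.0, 0.0]), 0.1, 0.3)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            scale_deviations(np.array([1.0]), -0.1, 0.3)
        with pytest.raises(ValueError):
            scale_deviations(np.array([1.0]), 0.1, 1.5)
        with pytest.raises(ValueError):
            scale_deviations(np.array([]), 0.1, 0.3)


class TestBreedingValues:
    def test_identity_when_sd_matches_reference(self):
        v = environmental_breeding_values(np.full(4, 2.5), 2.5, r=0.7)
        np.testing.assert_array_equal(v, 0.0)

    def test_log_unit_case(self):
        v = environmental_breeding_values(np.array([2.0 * np.e]), 2.0, r=0.5)
        assert v == pytest.approx([1.0])

    def test_exact_linearity_in_r(self, rng):
        sigma_ei = rng.uniform(0.5, 5.0, size=200)
        base = environmental_breeding_values(sigma_ei, 2.0, r=1.0)
        for r in (0.05, 0.37, 0.5):
            np.testing.assert_array_equal(
                environmental_breeding_values(sigma_ei, 2.0, r=r), r * base
            )

    def test_rescale_identity_and_arithmetic(self):
        a = np.array([2.0, -1.0])
        assert rescale_trait_breeding_values(a, np.array([3.0, 3.0]), 3.0) == pytest.approx(a)
        assert rescale_trait_breeding_values(
            np.array([2.0]), np.array([6.0]), 3.0
        ) == pytest.approx([4.0])
        assert np.all(
            rescale_trait_breeding_values(np.zeros(3), np.ones(3), 2.0) == 0.0
        )

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            environmental_breeding_values(np.array([1.0, -1.0]), 2.0)
        with pytest.raises(ValueError):
            environmental_breeding_values(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            environmental_breeding_values(np.array([1.0]), 1.0, r=0.0)
        with pytest.raises(ValueError):
            rescale_trait_breeding_values(np.ones(2), np.ones(3), 1.0)
        with pytest.raises(ValueError):
            rescale_trait_breeding_values(np.ones(2), np.ones(2), -1.0)


class TestSummaryStatistics:
    def test_correlation_identity_cases(self, rng):
        x = rng.standard_normal(50)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_correlation_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(np.ones(10), np.arange(10.0))

    def test_gcv_zero_for_constant(self):
        assert gcv_from_v(np.full(10, 3.7)) == 0.0

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_gcv_scale_equivariance(self, c):
        w = np.array([0.3, -1.2, 0.8, 2.4, -0.5])
        assert gcv_from_v(c * w) == pytest.approx(c * gcv_from_v(w), rel=1e-12)

    def test_gcv_matches_sample_sd_definition(self, rng):
        v = rng.standard_normal(100)
        assert gcv_from_v(v) == pytest.approx(np.sqrt(np.var(v, ddof=1)))

    def test_too_short_inputs(self):
        with pytest.raises(ValueError):
            gcv_from_v(np.array([1.0]))
        with pytest.raises(ValueError):
            pearson_correlation(np.array([1.0]), np.array([2.0]))


class TestCompositionIdentity:
    def test_zero_deviates_collapse_to_homogeneous_model(self, small_config):
        n = 10
        draw = simulate_population(small_config, np.zeros(n), np.zeros(n))
        vc = derive_variance_components(
            small_config.mu, small_config.cv, small_config.h2
        )
        np.testing.assert_allclose(draw.y, small_config.mu)
        np.testing.assert_allclose(draw.sigma_ei, vc.sigma_e)
        np.testing.assert_array_equal(draw.v, 0.0)
        np.testing.assert_allclose(draw.u, draw.a)

    def test_v_vanishes_where_record_magnitude_equals_mu(self, small_config):
        # records exactly at mu arise when a + e = 0; force one
        vc = derive_variance_components(
            small_config.mu, small_config.cv, small_config.h2
        )
        z_a = np.array([0.0, 1.0])
        z_e = np.array([0.0, -vc.sigma_u / vc.sigma_e])
        draw = simulate_population(small_config, z_a, z_e)
        assert draw.y[0] == small_config.mu
        assert draw.v[0] == 0.0

    def test_vectors_share_length_and_model_identity(self, small_config, rng):
        n = small_config.n_individuals
        draw = simulate_population(
            small_config, rng.standard_normal(n), rng.standard_normal(n)
        )
        for name in ("a", "e", "y", "sigma_pi", "sigma_ei", "sigma_ui", "u", "v"):
            assert getattr(draw, name).shape == (n,)
        np.testing.assert_allclose(draw.y, small_config.mu + draw.a + draw.e)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(cv=0.1, h2=0.5, r=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(cv=0.1, h2=0.5, n_individuals=1)
        with pytest.raises(ValueError):
            ScenarioConfig(cv=0.1, h2=0.5, n_replicates=0)
        with pytest.raises(ValueError):
            ScenarioConfig(cv=0.1, h2=0.5, mu=-5.0)
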