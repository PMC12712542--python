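"""Exactness of the slope/correlation decomposition between aggregation orders."""

import numpy as np
import pytest

import traitagg as ta


class TestBiasVectors:
    def test_subtraction(self):
        theta, omega = ta.bias_vectors([1.0, 2.0], [0.9, 2.0], [3.0, 4.0], [3.0, 3.5])
        np.testing.assert_allclose(theta, [0.1, 0.0])
        np.testing.assert_allclose(omega, [0.0, 0.5])

    def test_equal_vectors_zero_bias(self):
        x = [1.0, 2.0, 3.0]
        theta, omega = ta.bias_vectors(x, x, x, x)
        assert not theta.any() and not omega.any()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ta.bias_vectors([1.0, 2.0], [1.0], [1.0, 2.0], [1.0, 2.0])


class TestSlopeDecomposition:
    def test_bias_free_case_reduces_to_plain_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 2.0 * x
        zero = np.zeros_like(x)
        dec = ta.slope_decomposition(x, y, zero, zero)
        assert dec.slope_direct == pytest.approx(2.0)
        assert dec.slope_reconstructed == pytest.approx(2.0)
        assert dec.slope_unbiased == pytest.approx(2.0)

    def test_four_point_example_against_hand_ols(self):
        """theta shifts x to x* = x - theta; the starred slope is
        cov(x*, y)/var(x*) = (9.8/3)/(4.85/3) computed by hand."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        theta = np.array([0.1, 0.0, -0.1, 0.2])
        omega = np.zeros(4)
        dec = ta.slope_decomposition(x, y, theta, omega)
        assert dec.slope_direct == pytest.approx(9.8 / 4.85, abs=1e-9)
        assert dec.slope_direct == pytest.approx(2.020619, abs=1e-6)
        assert dec.slope_reconstructed == pytest.approx(dec.slope_direct, abs=1e-10)
        # correlation: brute-force Pearson on x* = x - theta, y
        x_star = x - theta
        r = np.corrcoef(x_star, y)[0, 1]
        cdec = ta.correlation_decomposition(x, y, theta, omega)
        assert cdec.corr_direct == pytest.approx(r, abs=1e-12)
        assert cdec.corr_reconstructed == pytest.approx(r, abs=1e-10)

    @pytest.mark.parametrize("ddof", [0, 1])
    def test_identity_exact_on_200_random_quadruples(self, ddof):
        """The decomposition is algebra, not approximation: reconstructed and
        direct slope/correlation agree to 1e-10 relative for any data and
        either covariance divisor."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.normal(0.0, rng.uniform(0.5, 3.0), n)
            y = rng.normal(0.0, rng.uniform(0.5, 3.0), n)
            theta = rng.normal(rng.uniform(-1, 1), rng.uniform(0.01, 1.0), n)
            omega = rng.normal(rng.uniform(-1, 1), rng.uniform(0.01, 1.0), n)
            dec = ta.slope_decomposition(x, y, theta, omega, ddof=ddof)
            assert dec.slope_reconstructed == pytest.approx(
                dec.slope_direct, rel=1e-10, abs=1e-12
            )
            assert dec.corr_reconstructed == pytest.approx(
                dec.corr_direct, rel=1e-10, abs=1e-12
            )
            assert -1.0 <= dec.corr_direct <= 1.0

    def test_constant_bias_shift_leaves_slope_unchanged(self):
        """A mean (constant) bias cancels out of every covariance: only the
        between-species variation of the bias distorts the slope."""
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        theta, omega = rng.normal(0, 0.3, 20), rng.normal(0, 0.3, 20)
        base = ta.slope_decomposition(x, y, theta, omega)
        shifted = ta.slope_decomposition(x, y, theta + 5.0, omega - 3.0)
        assert shifted.slope_direct == pytest.approx(base.slope_direct, rel=1e-12)
        assert shifted.corr_direct == pytest.approx(base.corr_direct, rel=1e-12)

    def test_too_few_species(self):
        with pytest.raises(ValueError, match="3"):
            ta.slope_decomposition([1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [0.0, 0.0])

    def test_degenerate_regressor(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ZeroDivisionError, match="zero variance"):
            ta.slope_decomposition(x, x, np.zeros(4), np.zeros(4))


class TestCompareAggregationOrders:
    def test_single_individual_per_species_gives_zero_bias(self, log_t):
        table = ta.TraitMeasurementTable.from_records(
            [(f"sp{k}", f"i{k}", tr, v)
             for k, (d, r) in enumerate([(0.2, 0.3), (0.4, 0.2), (0.3, 0.25), (0.5, 0.1)])
             for tr, v in (("D", d), ("RTD", r))]
        )
        dec = ta.compare_aggregation_orders(table, "D", "RTD", log_t, log_t)
        assert dec.var_theta == pytest.approx(0.0, abs=1e-24)
        assert dec.var_omega == pytest.approx(0.0, abs=1e-24)
        assert dec.slope_direct == pytest.approx(dec.slope_unbiased, abs=1e-12)

    def test_zero_within_species_spread_gives_identical_slopes(self, log_t):
        table = ta.TraitMeasurementTable.from_records(
            [(f"sp{k}", f"sp{k}_i{j}", tr, v)
             for k, (d, r) in enumerate([(0.2, 0.3), (0.4, 0.2), (0.3, 0.25)])
             for j in range(3)
             for tr, v in (("D", d), ("RTD", r))]
        )
        dec = ta.compare_aggregation_orders(table, "D", "RTD", log_t, log_t)
        assert dec.slope_direct == pytest.approx(dec.slope_unbiased, abs=1e-12)
        assert dec.corr_direct == pytest.approx(dec.corr_unbiased, abs=1e-12)

    def test_heterogeneous_table_distorts_the_slope(self, log_t):
        """With within-species spread, aggregate-then-transform species values
        differ from transform-then-aggregate ones and the slope moves."""
        table = ta.simulate_trait_table(ta.default_config(seed=3, heterogeneous=True))
        dec = ta.compare_aggregation_orders(table, "D", "RTD", log_t, log_t)
        assert dec.var_theta > 0
        assert dec.slope_direct != pytest.approx(dec.slope_unbiased, abs=1e-6)
        assert dec.slope_reconstructed == pytest.approx(dec.slope_direct, rel=1e-10)

    def test_reference_flip_swaps_roles(self, default_table, log_t):
        fwd = ta.compare_aggregation_orders(default_table, "D", "RTD", log_t, log_t)
        rev = ta.compare_aggregation_orders(
            default_table, "D", "RTD", log_t, log_t, reference="aggregate_first"
        )
        assert rev.slope_unbiased == pytest.approx(fwd.slope_direct, rel=1e-12)
        assert rev.slope_direct == pytest.approx(fwd.slope_unbiased, rel=1e-12)

    def test_species_lacking_a_trait_are_excluded(self, log_t):
        records = [
            (f"sp{k}", f"sp{k}_i{j}", tr, v)
            for k, (d, r) in enumerate([(0.2, 0.3), (0.4, 0.2), (0.3, 0.25), (0.45, 0.15)])
            for j in range(2)
            for tr, v in (("D", d + 0.01 * j), ("RTD", r + 0.01 * j))
        ]
        records.append(("spOnlyD", "spOnlyD_i0", "D", 0.3))
        dec = ta.compare_aggregation_orders(
            ta.TraitMeasurementTable.from_records(records), "D", "RTD", log_t, log_t
        )
        assert dec.n_species == 4

    def test_too_few_overlapping_species(self, log_t):
        table = ta.TraitMeasurementTable.from_records(
            [("spA", "i1", "D", 0.2), ("spA", "i1", "RTD", 0.3),
             ("spB", "i2", "D", 0.4), ("spB", "i2", "RTD", 0.2),
             ("spC", "i3", "D", 0.3)]
        )
        with pytest.raises(ValueError, match=">= 3 species"):
            ta.compare_aggregation_orders(table, "D", "RTD", log_t, log_t)
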