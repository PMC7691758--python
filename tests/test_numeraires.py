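import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthnpv import (
    EffectStream,
    ParameterPath,
    ValidationError,
    consumption_value_columns,
    equivalent_consumption_effect,
    equivalent_health_effect,
    equivalent_resource_effect,
    equivalent_resources,
    extensive_table,
    health_opportunity_loss,
    net_consumption_cost,
    net_health_benefit,
    shadow_price_other_sector,
)
from healthnpv.numeraires import EXTENSIVE_COLUMNS


def make(delta_h, delta_c_h, delta_c_c, k_h, k_c, V_h):
    return (
        EffectStream("A", delta_h, delta_c_h, delta_c_c),
        ParameterPath(k_h, k_c, V_h),
    )


class TestPerPeriodFormulas:
    @pytest.mark.parametrize(
        "delta_c_h, k_h, expected",
        [([5000], [1000], [5.0]), ([0, 0], [800, 900], [0, 0]), ([-1000], [500], [-2.0])],
    )
    def test_health_opportunity_loss(self, delta_c_h, k_h, expected):
        np.testing.assert_allclose(
            health_opportunity_loss(delta_c_h, k_h), expected, rtol=1e-12
        )

    def test_health_opportunity_loss_rejects_nonpositive_threshold(self):
        with pytest.raises(ValidationError):
            health_opportunity_loss([100.0], [0.0])

    @pytest.mark.parametrize(
        "delta_h, delta_c_h, k_h, expected",
        [
            ([10], [5000], [1000], [5.0]),
            ([10], [10000], [1000], [0.0]),
            ([0, 0], [0, 0], [1, 1], [0, 0]),
        ],
    )
    def test_net_health_benefit(self, delta_h, delta_c_h, k_h, expected):
        stream, params = make(
            delta_h, delta_c_h, [0.0] * len(delta_h), k_h, [0.0] * len(k_h), [1.0] * len(k_h)
        )
        np.testing.assert_allclose(net_health_benefit(stream, params), expected, rtol=1e-12)

    @pytest.mark.parametrize(
        "delta_c_c, delta_c_h, k_c, expected",
        [
            ([200], [5000], [1], [5200]),
            ([200], [5000], [0], [200]),
            ([-300], [0], [1], [-300]),
        ],
    )
    def test_net_consumption_cost(self, delta_c_c, delta_c_h, k_c, expected):
        stream, params = make(
            [0.0] * len(delta_c_c), delta_c_h, delta_c_c, [1.0] * len(k_c), k_c, [1.0] * len(k_c)
        )
        np.testing.assert_allclose(
            net_consumption_cost(stream, params), expected, rtol=1e-12
        )

    @pytest.mark.parametrize(
        "delta_h, k_h, expected",
        [([10], [1000], [10000]), ([0], [1000], [0]), ([2, 3], [100, 102], [200, 306])],
    )
    def test_equivalent_resource_benefits(self, delta_h, k_h, expected):
        stream, params = make(
            delta_h, [0.0] * len(delta_h), [0.0] * len(delta_h), k_h, [0.0] * len(k_h), [1.0] * len(k_h)
        )
        benefits, costs = equivalent_resources(stream, params)
        np.testing.assert_allclose(benefits, expected, rtol=1e-12)
        np.testing.assert_allclose(costs, stream.delta_c_h)

    def test_consumption_value_columns(self):
        stream, params = make([10], [5000], [0], [1000], [0], [3000])
        benefits, costs = consumption_value_columns(stream, params)
        np.testing.assert_allclose(benefits, [30000])
        np.testing.assert_allclose(costs, [15000])

    def test_consumption_value_identity_parameters(self):
        stream, params = make([1], [1], [0], [1], [0], [1])
        benefits, costs = consumption_value_columns(stream, params)
        np.testing.assert_allclose(benefits, [1.0])
        np.testing.assert_allclose(costs, [1.0])

    def test_equivalent_consumption_effect_worked_example(self):
        # V_h * (10 - 5) - (200 + 5000) = 3000*5 - 5200 = 9800
        stream, params = make([10], [5000], [200], [1000], [1], [3000])
        np.testing.assert_allclose(
            equivalent_consumption_effect(stream, params), [9800.0], rtol=1e-12
        )

    def test_equivalent_consumption_effect_null_project(self):
        stream, params = make([0], [0], [0], [1000], [1], [3000])
        np.testing.assert_allclose(equivalent_consumption_effect(stream, params), [0.0])

    def test_equivalent_consumption_break_even_health_no_consumption_side(self):
        stream, params = make([10], [10000], [0], [1000], [0], [12345.0])
        np.testing.assert_allclose(equivalent_consumption_effect(stream, params), [0.0])

    def test_equivalent_health_effect_is_consumption_over_value(self):
        stream, params = make([10], [5000], [200], [1000], [1], [3000])
        np.testing.assert_allclose(
            equivalent_health_effect(stream, params), [9800.0 / 3000.0], rtol=1e-12
        )

    def test_equivalent_resource_effect_scales_by_threshold(self):
        stream, params = make([10], [5000], [200], [1000], [1], [3000])
        np.testing.assert_allclose(
            equivalent_resource_effect(stream, params),
            [1000 * 9800.0 / 3000.0],
            rtol=1e-12,
        )

    def test_resource_equals_consumption_when_k_equals_v(self):
        stream, params = make([3, 1], [500, 900], [0, 0], [700, 701], [0, 0], [700, 701])
        np.testing.assert_allclose(
            equivalent_resource_effect(stream, params),
            equivalent_consumption_effect(stream, params),
            rtol=1e-12,
        )

    @pytest.mark.parametrize(
        "delta_c_x, ratio, expected",
        [([100], [1.0], [100.0]), ([0.0], [2.5], [0.0])],
    )
    def test_shadow_price_other_sector(self, delta_c_x, ratio, expected):
        np.testing.assert_allclose(
            shadow_price_other_sector(delta_c_x, ratio), expected
        )

    def test_shadow_price_defaults_to_health_ratio(self):
        # V_h/k_h = 3 values a displaced 100 of sector-x spending at 300
        np.testing.assert_allclose(
            shadow_price_other_sector([100.0], np.array([3000.0]) / np.array([1000.0])),
            [300.0],
        )
        with pytest.raises(ValidationError):
            shadow_price_other_sector([100.0], [0.0])


small_streams = st.integers(1, 5).flatmap(
    lambda T: st.tuples(
        st.lists(st.floats(-50, 50), min_size=T, max_size=T),
        st.lists(st.floats(-1e4, 1e4), min_size=T, max_size=T),
        st.lists(st.floats(-1e3, 1e3), min_size=T, max_size=T),
        st.lists(st.floats(10, 1e4), min_size=T, max_size=T),
        st.lists(st.floats(0, 3), min_size=T, max_size=T),
        st.lists(st.floats(10, 1e4), min_size=T, max_size=T),
    )
)


class TestInvariants:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(data=small_streams)
    def test_numeraire_effects_share_sign_each_period(self, data):
        """Multiplying by positive V_h or k_h cannot flip a period's sign."""
        stream, params = make(*data)
        eq_c = equivalent_consumption_effect(stream, params)
        eq_h = equivalent_health_effect(stream, params)
        eq_r = equivalent_resource_effect(stream, params)
        assert np.array_equal(np.sign(eq_c), np.sign(eq_h))
        assert np.array_equal(np.sign(eq_h), np.sign(eq_r))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(data=small_streams)
    def test_no_consumption_side_reduces_to_net_health(self, data):
        """With no consumption costs and k_c = 0, the consumption value of
        health rescales but never flips the net health benefit."""
        delta_h, delta_c_h, _, k_h, _, V_h = data
        T = len(delta_h)
        stream, params = make(delta_h, delta_c_h, [0.0] * T, k_h, [0.0] * T, V_h)
        nhb = net_health_benefit(stream, params)
        np.testing.assert_allclose(
            equivalent_health_effect(stream, params), nhb, rtol=1e-12, atol=1e-12
        )
        # the V_h path does not influence the adopt/reject sign
        stream2, params2 = make(
            delta_h, delta_c_h, [0.0] * T, k_h, [0.0] * T, [v * 7.3 for v in V_h]
        )
        assert np.sign(equivalent_consumption_effect(stream, params).sum()) == np.sign(
            equivalent_consumption_effect(stream2, params2).sum()
        )

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(data=small_streams)
    def test_vectorised_matches_literal_transcription(self, data):
        """Term-by-term evaluation of the net-effect formulas agrees with the
        vectorised implementation to 1e-12."""
        stream, params = make(*data)
        eq_c = equivalent_consumption_effect(stream, params)
        eq_h = equivalent_health_effect(stream, params)
        eq_r = equivalent_resource_effect(stream, params)
        for i in range(stream.T):
            nhb = stream.delta_h[i] - stream.delta_c_h[i] / params.k_h[i]
            ncc = stream.delta_c_c[i] + params.k_c[i] * stream.delta_c_h[i]
            scale = max(1.0, abs(eq_c[i]))
            assert abs(eq_c[i] - (params.V_h[i] * nhb - ncc)) <= 1e-12 * scale
            assert abs(eq_h[i] - (nhb - ncc / params.V_h[i])) <= 1e-12 * max(1.0, abs(eq_h[i]))
            assert abs(eq_r[i] - params.k_h[i] * (nhb - ncc / params.V_h[i])) <= 1e-12 * max(
                1.0, abs(eq_r[i])
            )


class TestExtensiveTable:
    def test_columns_rederivable_from_inputs(self, rng):
        T = 6
        stream, params = make(
            rng.uniform(-5, 15, T),
            rng.uniform(-2000, 8000, T),
            rng.uniform(-500, 1500, T),
            rng.uniform(300, 4000, T),
            rng.uniform(0, 2, T),
            rng.uniform(500, 9000, T),
        )
        table = extensive_table(stream, params)
        assert list(table.columns) == EXTENSIVE_COLUMNS
        assert len(table) == T
        np.testing.assert_array_equal(
            table["health_opportunity_loss"],
            health_opportunity_loss(stream.delta_c_h, params.k_h),
        )
        np.testing.assert_array_equal(
            table["net_health_benefit"], net_health_benefit(stream, params)
        )
        np.testing.assert_array_equal(
            table["equivalent_consumption_effect"],
            equivalent_consumption_effect(stream, params),
        )
        # both consumption representations of health-care costs are present
        np.testing.assert_array_equal(
            table["consumption_value_health_lost"],
            params.V_h * (stream.delta_c_h / params.k_h),
        )
        np.testing.assert_array_equal(
            table["net_consumption_cost"],
            stream.delta_c_c + params.k_c * stream.delta_c_h,
        )
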