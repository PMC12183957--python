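"""Current-subtraction arithmetic, encoding round trips, and collisions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mramsim import (
    DeviceParams,
    MTJCell,
    MTJState,
    ThresholdBlock,
    WeightCode,
    code_current,
    collision_report,
    column_current,
    net_alpha_units,
    program_weights,
    threshold_units,
)

# Strategy: a random unit-ratio code paired cellwise as (gen_value, n_cells).
codes = st.integers(min_value=1, max_value=12).flatmap(
    lambda n: st.tuples(
        st.just(n),
        st.integers(min_value=0, max_value=n),
        st.integers(min_value=0, max_value=n),
    )
)


def _therm(value, n):
    return WeightCode.from_value(value, "thermometer", n)


def test_code_current_matches_term_by_term_sum(params):
    """7-cell code, six P one AP: 6×5 µA + 1×2.5 µA = 32.5 µA."""
    assert code_current(_therm(6, 7), params) == pytest.approx(32.5e-6)
    # all-AP code carries only the AP pedestal
    assert code_current(_therm(0, 7), params) == pytest.approx(7 * params.I_AP)


def test_binary_and_thermometer_codes_with_equal_value_match(params):
    binary = WeightCode.from_value(6, "binary")  # bits 110 on ratios 1,2,4
    therm = _therm(6, 7)
    assert binary.code_value == therm.code_value == 6
    assert binary.total_ratio == therm.total_ratio == 7
    assert code_current(binary, params) == pytest.approx(code_current(therm, params))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(codes)
def test_subtraction_identity_on_random_codes(spec):
    """I(gen) − I(ref) equals (gen − ref) × alpha, exactly, for matched totals."""
    n, v_gen, v_ref = spec
    params = DeviceParams(R_P=7e3, R_AP=25e3, V_READ_AMP=40e-3)
    gen, ref = _therm(v_gen, n), _therm(v_ref, n)
    diff = code_current(gen, params) - code_current(ref, params)
    assert diff == pytest.approx(net_alpha_units(gen, ref) * params.alpha, abs=1e-18)
    # pedestal identity: raw current = total×I_AP + value×alpha
    assert code_current(gen, params) == pytest.approx(
        n * params.I_AP + v_gen * params.alpha
    )


def test_worked_psp_examples():
    ref = _therm(2, 7)  # two P, five AP
    assert net_alpha_units(_therm(6, 7), ref) == 4    # EPSP of 4 alpha
    assert net_alpha_units(_therm(0, 7), ref) == -2   # IPSP of -2 alpha
    assert net_alpha_units(ref, ref) == 0
    with pytest.raises(ValueError, match="matched totals"):
        net_alpha_units(_therm(3, 6), ref)


def test_threshold_block_values_and_rejections():
    ref = _therm(2, 7)
    assert threshold_units(ThresholdBlock(_therm(7, 7), ref)) == 5
    assert threshold_units(ThresholdBlock(_therm(7, 7), _therm(0, 7))) == 7
    with pytest.raises(ValueError, match="positive threshold"):
        ThresholdBlock(ref, ref)


def test_column_current_spatial_summation(params):
    matrix = program_weights([[4], [-2], [1], [1], [1]])
    a = params.alpha
    # simultaneous EPSP +4 and IPSP -2 sum to +2 alpha
    assert column_current({0, 1}, 0, matrix, params) == pytest.approx(2 * a)
    assert column_current(set(), 0, matrix, params) == 0.0
    # linearity: three +1 stimuli give +3 alpha
    assert column_current({2, 3, 4}, 0, matrix, params) == pytest.approx(3 * a)
    with pytest.raises(IndexError):
        column_current({9}, 0, matrix, params)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 5), min_size=1, max_size=6),
    st.data(),
)
def test_column_superposition_over_random_subsets(col_weights, data):
    """Column current over a set equals the sum over singleton activations."""
    K = len(col_weights)
    W = np.array(col_weights).reshape(K, 1) - 2
    params = DeviceParams()
    matrix = program_weights(W)
    subset = data.draw(st.sets(st.integers(0, K - 1)))
    total = column_current(subset, 0, matrix, params)
    singles = sum(column_current({k}, 0, matrix, params) for k in subset)
    assert total == pytest.approx(singles, abs=1e-18)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(2, 8).flatmap(
        lambda n: st.lists(
            st.lists(st.integers(-2, 5), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        )
    ),
    st.sampled_from(["thermometer", "binary"]),
)
def test_program_weights_round_trip(table, shape):
    m = min(len(r) for r in table)
    W = np.array([row[:m] for row in table], dtype=int)
    matrix = program_weights(W, ref_value=2, code_shape=shape)
    assert (matrix.alpha_matrix() == W).all()


def test_program_weights_range_error_names_entry():
    with pytest.raises(ValueError, match=r"axon 1, dendrite 0.*-2\.\.5"):
        program_weights([[4], [-3]], ref_value=2, n_cells=7)


def test_three_bit_code_represents_exactly_eight_levels():
    """Reference 2 on a 7-total code spans −2..+5: eight distinct levels."""
    levels = [
        net_alpha_units(WeightCode.from_value(v, "binary"), WeightCode.from_value(2, "binary"))
        for v in range(8)
    ]
    assert levels == list(range(-2, 6))


def test_collision_report_flags_low_contrast_ambiguity(params):
    report = collision_report("thermometer", params)
    assert not report.empty
    # the canonical collision: one P cell vs. two AP cells
    patterns = set(report["pattern"])
    assert "1xP" in patterns and "1xAP+1xAP" in patterns
    one_p = report[report["pattern"] == "1xP"]
    two_ap = report[report["pattern"] == "1xAP+1xAP"]
    assert one_p["group"].iloc[0] == two_ap["group"].iloc[0]


def test_subtracted_levels_are_collision_free(params):
    assert collision_report("thermometer", params, subtract=True).empty


def test_full_length_codes_have_distinct_raw_currents():
    """Within one matched-total row, the 8 raw currents never collide."""
    params = DeviceParams(R_P=5e3, R_AP=30e3)  # I_P/I_AP = 6
    currents = [code_current(_therm(v, 7), params) for v in range(8)]
    assert len({round(c * 1e12) for c in currents}) == 8
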