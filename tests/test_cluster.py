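"""Cluster orchestration: summation, inhibition propagation, rasters."""

import dataclasses

import numpy as np
import pytest

from mramsim import (
    ArraySpec,
    SimulationConfig,
    SpikeRaster,
    StimulusSchedule,
    ThresholdSpec,
    TimingConfig,
    preset,
    simulate,
)


def _cluster(weights, theta=5, **timing_kw):
    W = np.atleast_2d(np.asarray(weights, dtype=int))
    sim = SimulationConfig(
        array=ArraySpec(K=W.shape[0], N=W.shape[1], weights=W.tolist()),
        threshold=ThresholdSpec(
            theta_units=theta, ref_value=2 if theta + 2 <= 7 else 0
        ),
        timing=TimingConfig(**timing_kw),
    )
    return sim.build_cluster()


def test_simultaneous_epsp_ipsp_below_threshold_is_silent():
    """+4 and −2 alpha stimuli sum to +2, under a threshold of 5: no spike."""
    cluster = _cluster([[4], [-2]])
    assert cluster.step({0, 1}) == set()


def test_spike_marks_neighbors_for_lateral_inhibition():
    cluster = _cluster([[4, 5, 4]], inhibition_radius=1)
    fired = cluster.step({0})
    assert fired == {1}
    assert cluster.states[0].baseline == cluster.analog.V_LAT
    assert cluster.states[2].baseline == cluster.analog.V_LAT
    assert cluster.states[1].baseline == cluster.analog.V_RFR


def test_idle_tick_changes_no_baselines():
    cluster = _cluster([[3]])
    before = cluster.states[0]
    cluster.step(set())
    assert cluster.states[0].baseline == before.baseline
    assert cluster.states[0].V_integ == before.V_integ


def test_axon_index_out_of_range_rejected():
    cluster = _cluster([[1]])
    with pytest.raises(IndexError):
        cluster.step({5})


def test_empty_schedule_yields_empty_raster():
    raster, _ = simulate(SimulationConfig(), StimulusSchedule([]), n_ticks=5)
    assert raster.spikes == []


def test_run_requires_ticks_to_cover_schedule():
    sim, schedule = preset("linear_sweep")
    with pytest.raises(ValueError, match="does not cover"):
        sim.build_cluster().run(StimulusSchedule([(4, 0)]), n_ticks=2)


def test_raster_determinism():
    sim, schedule = preset("refractory_lateral")
    r1, _ = simulate(sim, schedule)
    r2, _ = simulate(sim, schedule)
    assert r1 == r2 and r1.content_hash() == r2.content_hash()


def test_raster_invariant_across_clock_frequencies():
    """All analog windows are per-cycle: 1 kHz and 50 kHz rasters match."""
    rng = np.random.default_rng(7)
    W = rng.integers(-2, 6, size=(4, 4))
    events = [(int(t), int(a)) for t in range(15) for a in range(4)
              if rng.random() < 0.3]
    rasters = []
    for f in (1e3, 50e3):
        sim = SimulationConfig(
            array=ArraySpec(K=4, N=4, weights=W.tolist()),
            timing=TimingConfig(f_GCLK=f),
        )
        raster, _ = simulate(sim, StimulusSchedule(events))
        rasters.append(raster)
    assert rasters[0] == rasters[1]


def test_no_two_spikes_within_absolute_refractory_window():
    """Raster-level check over a random stream, for several gate lengths."""
    rng = np.random.default_rng(11)
    W = np.full((3, 3), 5)
    events = [(int(t), int(a)) for t in range(40) for a in range(3)
              if rng.random() < 0.6]
    for n_abs in (1, 2, 3):
        sim = SimulationConfig(
            array=ArraySpec(K=3, N=3, weights=W.tolist()),
            timing=TimingConfig(n_abs=n_abs, inhibition_radius=0),
        )
        raster, _ = simulate(sim, StimulusSchedule(events))
        assert raster.spikes  # the stream is strong enough to spike at all
        by_d: dict[int, list[int]] = {}
        for t, d in raster.spikes:
            by_d.setdefault(d, []).append(t)
        for ticks in by_d.values():
            gaps = np.diff(sorted(ticks))
            assert (gaps >= n_abs + 1).all()


def test_lateral_inhibition_never_raises_firing_rate():
    """Threshold-equal diagonal weights, interleaved axons: spikes on one
    dendrite suppress its neighbor's threshold-equal stimulus next tick."""
    rng = np.random.default_rng(23)
    W = (np.eye(4, dtype=int) * 5).tolist()  # axon k drives only dendrite k
    events = [(int(t), int(rng.integers(0, 4))) for t in range(40)
              if rng.random() < 0.7]
    counts = {}
    for radius in (0, 1):
        sim = SimulationConfig(
            array=ArraySpec(K=4, N=4, weights=W),
            timing=TimingConfig(inhibition_radius=radius),
        )
        raster, _ = simulate(sim, StimulusSchedule(events))
        counts[radius] = np.bincount(
            [d for _, d in raster.spikes], minlength=4
        )
    assert (counts[1] <= counts[0]).all()
    assert counts[1].sum() < counts[0].sum()


def test_unknown_preset_lists_available_names():
    with pytest.raises(ValueError, match="linear_sweep"):
        preset("does_not_exist")


@pytest.mark.parametrize("theta", [5, 7])
def test_refractory_preset_single_spike_then_silence(theta):
    """First stimulus fires only the middle dendrite; the second nothing."""
    sim, schedule = preset("refractory_lateral", theta_units=theta)
    raster, _ = simulate(sim, schedule)
    assert raster.spikes == [(0, 1)]


def test_lateral_inhibition_blocks_threshold_equal_neighbors():
    """A w = theta stimulus fails from V_LAT, then succeeds once it reverts."""
    cluster = _cluster([[0, 5, 0], [5, 0, 5]], inhibition_radius=1, n_abs=1)
    assert cluster.step({0}, tick=0) == {1}       # middle fires, 0/2 inhibited
    assert cluster.step({1}, tick=1) == set()     # w = theta from V_LAT: blocked
    assert cluster.step(set(), tick=2) == set()
    assert cluster.step({1}, tick=3) == {0, 2}    # inhibition reverted: fires


def test_traces_record_reset_integrate_compare_phases():
    sim, schedule = preset("linear_sweep")
    raster, traces = simulate(sim, schedule, record_traces=True)
    assert set(traces["phase"]) == {"reset", "integrate", "compare"}
    zero_col = 2  # weight 0 sits at index 2 of the -2..5 sweep
    sub = traces[traces["neuron"] == zero_col]
    assert (
        sub[sub.phase == "integrate"]["volts"].iloc[0]
        == sub[sub.phase == "reset"]["volts"].iloc[0]
    )
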