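"""Canonical experiment scenarios and parameter sweeps.

Four named scenarios cover the behaviors the architecture was built to
demonstrate:

``linear_sweep``
    One axon fans out to a column per weight level, sweeping the
    representable range upward from −2 alpha units.  A single stimulus
    shows IPSP dips, unchanged 0-weight columns, linearly growing EPSPs,
    and a spike exactly at the column whose weight equals the threshold.
``refractory_lateral``
    Three columns with weights (θ−1, θ, θ−1) receive two identical
    stimuli a couple of ticks apart.  The first fires only the middle
    dendrite; the second finds it in its relative refractory period
    (integrating from V_RFR) and its neighbors laterally inhibited
    (integrating from V_LAT), so nothing fires.
``leakage_control``
    A single subthreshold column, used with :func:`leakage_sweep` to show
    the per-window voltage drop scaling with the SW_LEAK pulse width and
    with I_LEAKAGE.
``time_window_sweep``
    A threshold-equal column, used with :func:`time_window_sweep` to map
    the integration window over a (theta, V_TH) grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cluster import Cluster, StimulusSchedule, TimingConfig
from .config import ArraySpec, SimulationConfig, ThresholdSpec
from .neuron import integration_window

PRESET_NAMES = (
    "linear_sweep",
    "refractory_lateral",
    "leakage_control",
    "time_window_sweep",
)


def _threshold_spec(theta_units: int) -> ThresholdSpec:
    # Thresholds above 5 are not representable against the usual
    # two-P/five-AP reference within seven cells, so they use the all-AP
    # reference (generation code alone carries the value).
    ref = 2 if theta_units + 2 <= 7 else 0
    return ThresholdSpec(theta_units=theta_units, ref_value=ref)


def preset(name: str, **overrides) -> tuple[SimulationConfig, StimulusSchedule]:
    """Build a named scenario; unknown names raise with the valid list.

    Overrides: ``theta_units`` (all), ``w_min``/``w_max`` (linear_sweep),
    ``gap`` (refractory_lateral), ``weight`` (leakage_control).
    """
    builders = {
        "linear_sweep": _linear_sweep,
        "refractory_lateral": _refractory_lateral,
        "leakage_control": _leakage_control,
        "time_window_sweep": _time_window_base,
    }
    if name not in builders:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    return builders[name](**overrides)


def _linear_sweep(
    theta_units: int = 5, w_min: int = -2, w_max: int | None = None
) -> tuple[SimulationConfig, StimulusSchedule]:
    if w_max is None:
        w_max = theta_units
    weights = [[w for w in range(w_min, w_max + 1)]]
    cfg = SimulationConfig(
        array=ArraySpec(K=1, N=len(weights[0]), weights=weights),
        threshold=_threshold_spec(theta_units),
    )
    return cfg, StimulusSchedule([(0, 0)])


def _refractory_lateral(
    theta_units: int = 5, gap: int = 2
) -> tuple[SimulationConfig, StimulusSchedule]:
    weights = [[theta_units - 1, theta_units, theta_units - 1]]
    cfg = SimulationConfig(
        array=ArraySpec(K=1, N=3, weights=weights),
        threshold=_threshold_spec(theta_units),
        timing=TimingConfig(n_abs=1, inhibition_radius=1),
    )
    return cfg, StimulusSchedule([(0, 0), (gap, 0)])


def _leakage_control(
    theta_units: int = 5, weight: int = 3, n_stimuli: int = 1
) -> tuple[SimulationConfig, StimulusSchedule]:
    cfg = SimulationConfig(
        array=ArraySpec(K=1, N=1, weights=[[weight]]),
        threshold=_threshold_spec(theta_units),
    )
    return cfg, StimulusSchedule([(t, 0) for t in range(n_stimuli)])


def _time_window_base(
    theta_units: int = 5,
) -> tuple[SimulationConfig, StimulusSchedule]:
    cfg = SimulationConfig(
        array=ArraySpec(K=1, N=1, weights=[[theta_units]]),
        threshold=_threshold_spec(theta_units),
    )
    return cfg, StimulusSchedule([(0, 0)])


def time_window_sweep(
    thetas: tuple[int, ...] = (5, 7),
    v_th_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integration window over a (theta, V_TH) grid.

    ``V_CM_TWG`` is held at its default value while ``V_TH`` sweeps the
    800–850 mV band, so the window grows strictly with ``V_TH`` and, at
    each ``V_TH``, scales as 1/theta (a higher stored threshold ramps the
    window generator faster).

    Returns a DataFrame with columns ``theta, V_TH, T_int_s``.
    """
    if v_th_grid is None:
        v_th_grid = np.arange(0.800, 0.851, 0.010)
    records = []
    for theta in thetas:
        sim, _ = preset("time_window_sweep", theta_units=theta)
        for v_th in v_th_grid:
            analog = dataclasses.replace(sim.analog, V_TH=float(v_th))
            records.append(
                {
                    "theta": theta,
                    "V_TH": float(v_th),
                    "T_int_s": integration_window(theta, analog, sim.device),
                }
            )
    return pd.DataFrame.from_records(records)


def leakage_sweep(
    t_leak_values: tuple[float, ...] = (5e-9, 10e-9, 20e-9, 40e-9),
    I_leak_values: tuple[float, ...] = (0.5e-6, 1e-6, 2e-6, 4e-6),
    weight: int = 3,
    theta_units: int = 5,
) -> pd.DataFrame:
    """Measured per-window leakage drop vs. pulse width and leak current.

    Runs the ``leakage_control`` scenario once per setting and measures
    the drop between the post-integration voltage (trace phase
    ``integrate``) and the settled membrane voltage after the SW_LEAK
    pulse.  Widening the pulse at fixed current, or raising the current at
    fixed pulse, both deepen the drop.

    Returns a DataFrame with columns ``t_leak_s, I_LEAKAGE_A, delta_V``.
    """
    records = []
    base, schedule = preset("leakage_control", theta_units=theta_units, weight=weight)
    for t_leak in t_leak_values:
        for i_leak in I_leak_values:
            analog = dataclasses.replace(
                base.analog, t_leak=float(t_leak), I_LEAKAGE=float(i_leak)
            )
            cluster = Cluster(
                base.matrix,
                base.threshold_block,
                analog=analog,
                timing=base.timing,
                params=base.device,
            )
            _, traces = cluster.run(schedule, record_traces=True)
            v_integrated = traces.loc[
                traces["phase"] == "integrate", "volts"
            ].iloc[-1]
            v_settled = cluster.states[0].V_integ
            records.append(
                {
                    "t_leak_s": t_leak,
                    "I_LEAKAGE_A": i_leak,
                    "delta_V": float(v_integrated - v_settled),
                }
            )
    return pd.DataFrame.from_records(records)
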