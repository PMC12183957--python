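"""Orchestration of a K-axon × N-dendrite cluster on the global-clock grid.

Axon spikes arrive synchronized to GCLK.  On every tick that carries at
least one spike, each dendrite column sums the subtracted currents of the
active rows (spatial summation) and runs the full switch sequence of
:func:`mramsim.neuron.step_neuron`; afterwards, lateral inhibition marks
the neighbors of every fired dendrite so that their next integration
starts from ``V_LAT``.  Ticks without spikes only advance the absolute
refractory counters — the switch generator produces no phases.

The clock frequency scales real time only; every analog window is defined
per cycle, so rasters are identical at 1 kHz and 50 kHz (real-time
emulation vs. accelerated operation).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .device import DeviceParams
from .neuron import (
    AnalogConfig,
    NeuronState,
    fire_decision,
    integrate,
    integration_window,
    select_baseline,
    step_neuron,
)
from .synapse import SynapseMatrix, ThresholdBlock, column_current, threshold_units

logger = logging.getLogger(__name__)

GCLK_BAND = (1e3, 50e3)  # supported global-clock range (Hz)


@dataclass(frozen=True)
class TimingConfig:
    """Clocking, absolute-refractory length, and inhibition topology.

    ``inhibition_radius`` gives radius-``r`` adjacency on the dendrite
    index line (non-wrapping); an explicit ``adjacency`` mapping overrides
    it for arbitrary topologies.  ``n_abs`` is the number of GCLK cycles a
    neuron's switch generator stays gated after its own spike.
    """

    f_GCLK: float = 10e3
    n_abs: int = 1
    inhibition_radius: int = 1
    adjacency: Mapping[int, Sequence[int]] | None = None

    def __post_init__(self) -> None:
        if self.f_GCLK <= 0:
            raise ValueError(f"f_GCLK must be positive, got {self.f_GCLK}")
        if not GCLK_BAND[0] <= self.f_GCLK <= GCLK_BAND[1]:
            logger.warning(
                "f_GCLK=%.4g Hz is outside the supported band %.4g-%.4g Hz",
                self.f_GCLK,
                *GCLK_BAND,
            )
        if self.n_abs < 0 or self.inhibition_radius < 0:
            raise ValueError("n_abs and inhibition_radius must be non-negative")

    def neighbors(self, dendrite: int, N: int) -> list[int]:
        """Dendrites laterally inhibited by a spike on ``dendrite``."""
        if self.adjacency is not None:
            return [n for n in self.adjacency.get(dendrite, []) if 0 <= n < N]
        r = self.inhibition_radius
        return [
            n
            for n in range(dendrite - r, dendrite + r + 1)
            if n != dendrite and 0 <= n < N
        ]


@dataclass
class StimulusSchedule:
    """Timestamped axon events on the GCLK grid: (tick, axon) pairs."""

    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = sorted({(int(t), int(a)) for t, a in self.events})
        if cleaned and cleaned[0][0] < 0:
            raise ValueError(f"negative tick in schedule: {cleaned[0]}")
        if any(a < 0 for _, a in cleaned):
            raise ValueError("negative axon index in schedule")
        self.events = cleaned

    @property
    def n_ticks(self) -> int:
        """Smallest run length that covers every event."""
        return self.events[-1][0] + 1 if self.events else 0

    def active_by_tick(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for t, a in self.events:
            out.setdefault(t, set()).add(a)
        return out


@dataclass
class SpikeRaster:
    """Output spikes: at most one (tick, dendrite) entry per pair."""

    spikes: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spikes = sorted(set(self.spikes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.spikes, columns=["tick", "dendrite"], dtype=int)

    def dendrites(self) -> set[int]:
        return {d for _, d in self.spikes}

    def content_hash(self) -> str:
        import hashlib

        payload = ";".join(f"{t},{d}" for t, d in self.spikes)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return self.spikes == other.spikes


class Cluster:
    """Stateful simulator of one local cluster.

    Parameters
    ----------
    matrix :
        Programmed synapse array (weights plus per-row PSP references).
    threshold :
        Shared threshold block; its net value sets the integration window
        for every neuron in the cluster.
    analog, timing, params :
        Analog levels, clocking/topology, and MTJ electrical parameters.
    offsets :
        Per-neuron comparator offset voltages (volts); zeros in the ideal
        chip, sampled by :mod:`mramsim.variation` otherwise.
    """

    def __init__(
        self,
        matrix: SynapseMatrix,
        threshold: ThresholdBlock,
        analog: AnalogConfig | None = None,
        timing: TimingConfig | None = None,
        params: DeviceParams | None = None,
        offsets: Sequence[float] | None = None,
    ) -> None:
        self.matrix = matrix
        self.threshold = threshold
        self.theta_units = threshold_units(threshold)
        self.analog = analog or AnalogConfig()
        self.timing = timing or TimingConfig()
        self.params = params or DeviceParams()
        self.offsets = np.zeros(matrix.N) if offsets is None else np.asarray(
            offsets, dtype=float
        )
        if self.offsets.shape != (matrix.N,):
            raise ValueError(
                f"need one offset per dendrite ({matrix.N}), got shape "
                f"{self.offsets.shape}"
            )
        T_int = integration_window(self.theta_units, self.analog, self.params)
        if T_int > 1.0 / self.timing.f_GCLK:
            logger.warning(
                "integration window %.3g s exceeds the GCLK period %.3g s",
                T_int,
                1.0 / self.timing.f_GCLK,
            )
        self.reset()

    def reset(self) -> None:
        self.states = [
            NeuronState.resting(self.analog) for _ in range(self.matrix.N)
        ]

    def step(
        self,
        active_axons: Iterable[int],
        tick: int = 0,
        trace: list[dict] | None = None,
        trace_neurons: Sequence[int] | None = None,
    ) -> set[int]:
        """Advance the cluster by one GCLK tick; return the fired dendrites.

        A tick with no active axons is idle: no switch phases run, only the
        absolute refractory counters advance.
        """
        active = set(active_axons)
        for a in active:
            if not 0 <= a < self.matrix.K:
                raise IndexError(f"axon index {a} outside 0..{self.matrix.K - 1}")

        if not active:
            self.states = [
                dataclasses.replace(
                    s,
                    abs_refractory_remaining=max(0, s.abs_refractory_remaining - 1),
                    fired_last=False,
                )
                for s in self.states
            ]
            return set()

        fired: set[int] = set()
        watched = set(
            range(self.matrix.N) if trace_neurons is None else trace_neurons
        )
        new_states: list[NeuronState] = []
        for n, state in enumerate(self.states):
            I_syn = column_current(active, n, self.matrix, self.params)
            if trace is not None and n in watched:
                self._record_trace(trace, tick, n, state, I_syn)
            new_state, did_fire = step_neuron(
                state,
                I_syn,
                self.theta_units,
                self.analog,
                self.params,
                n_abs=self.timing.n_abs,
                offset=float(self.offsets[n]),
            )
            new_states.append(new_state)
            if did_fire:
                fired.add(n)

        # Lateral inhibition: fired dendrites pull their (non-fired)
        # neighbors' next baseline down to V_LAT.  A neuron's own spike
        # outranks a neighbor's.
        inhibited: set[int] = set()
        for d in fired:
            inhibited.update(self.timing.neighbors(d, self.matrix.N))
        for n in inhibited - fired:
            s = new_states[n]
            new_states[n] = dataclasses.replace(
                s,
                baseline=select_baseline(
                    False, True, s.subthreshold_last, self.analog
                ),
            )
        self.states = new_states
        return fired

    def _record_trace(
        self, trace: list[dict], tick: int, n: int, state: NeuronState, I_syn: float
    ) -> None:
        cfg, params = self.analog, self.params
        if state.abs_refractory_remaining > 0:
            trace.append(
                {"tick": tick, "neuron": n, "phase": "gated", "volts": state.V_integ}
            )
            return
        T_int = integration_window(self.theta_units, cfg, params)
        v_int = integrate(state.baseline, I_syn, T_int, cfg.C_int)
        trace.append(
            {"tick": tick, "neuron": n, "phase": "reset", "volts": state.baseline}
        )
        trace.append(
            {"tick": tick, "neuron": n, "phase": "integrate", "volts": v_int}
        )
        fired = fire_decision(v_int, cfg, float(self.offsets[n]))
        end = cfg.V_REST if fired else v_int  # leak applied after comparison
        trace.append({"tick": tick, "neuron": n, "phase": "compare", "volts": end})

    def run(
        self,
        schedule: StimulusSchedule,
        n_ticks: int | None = None,
        record_traces: bool = False,
        trace_neurons: Sequence[int] | None = None,
    ) -> tuple[SpikeRaster, pd.DataFrame | None]:
        """Simulate ``n_ticks`` GCLK cycles from a fresh resting state.

        Deterministic for a given configuration; returns the spike raster
        and, when requested, a per-phase voltage trace table with columns
        ``tick, neuron, phase, volts``.
        """
        if n_ticks is None:
            n_ticks = schedule.n_ticks
        if n_ticks < schedule.n_ticks:
            raise ValueError(
                f"n_ticks={n_ticks} does not cover the last scheduled event "
                f"at tick {schedule.n_ticks - 1}"
            )
        self.reset()
        by_tick = schedule.active_by_tick()
        spikes: list[tuple[int, int]] = []
        trace: list[dict] | None = [] if record_traces else None
        for t in range(n_ticks):
            fired = self.step(by_tick.get(t, set()), t, trace, trace_neurons)
            spikes.extend((t, d) for d in sorted(fired))
        traces = (
            pd.DataFrame(trace, columns=["tick", "neuron", "phase", "volts"])
            if record_traces
            else None
        )
        return SpikeRaster(spikes), traces
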