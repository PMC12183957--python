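"""Per-cycle analog behavior of one dendrite's leaky integrate-and-fire path.

Each global-clock (GCLK) cycle that carries a stimulus runs a fixed switch
sequence: reset the integrator to the baseline voltage, integrate the net
synaptic current for the threshold-derived time window, compare against
``V_TH``, then apply one discrete leakage pulse toward ``V_REST``.

The time-window generator is the normalization trick at the heart of the
design.  The stored threshold ``theta`` (in alpha units) drives a ramp from
``V_CM_TWG`` to ``V_TH``; the crossing time

    T_int = C_int * (V_TH - V_CM_TWG) / (theta * alpha)

bounds the integration window, so a weight of ``w`` alpha units deflects
the membrane by ``(w / theta) * (V_TH - V_CM_TWG)`` — independent of
``alpha``, the capacitance, and the clock frequency.  Because the ramp
starts a margin ``delta = V_CM_COL - V_CM_TWG`` below the integrator's own
reset level, a weight exactly equal to the threshold overshoots ``V_TH``
and fires, while ``delta`` is kept small enough that ``theta - 1`` never
does.

Refractory and lateral-inhibition states are encoded purely as the
baseline the next integration starts from: ``V_RFR`` after a neuron's own
spike (relative refractory), ``V_LAT`` after a neighbor's spike (lateral
inhibition), ``V_GEN`` after a subthreshold deflection, ``V_REST``
otherwise, with ``V_LAT < V_RFR < V_REST``.  The absolute refractory
period is a digital gate: for ``n_abs`` cycles after a spike the switch
generator is inactive and input is ignored entirely.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

from .device import DeviceParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalogConfig:
    """Voltage levels, integrator capacitance and leakage settings.

    All voltages in volts, capacitance in farads, current in amperes,
    time in seconds.  ``theta_max`` is the largest threshold the margin
    ``delta`` must stay safe for.
    """

    C_int: float = 1e-12
    V_TH: float = 0.850
    V_CM_COL: float = 0.600
    V_CM_TWG: float | None = None  # default: V_CM_COL - (V_TH-V_CM_COL)/(2*theta_max)
    V_REST: float = 0.600
    V_GEN: float | None = None     # default: V_REST
    V_RFR: float = 0.540
    V_LAT: float = 0.480
    I_LEAKAGE: float = 1e-6
    t_leak: float = 10e-9
    theta_max: int = 7

    def __post_init__(self) -> None:
        if self.V_CM_TWG is None:
            object.__setattr__(
                self,
                "V_CM_TWG",
                self.V_CM_COL - (self.V_TH - self.V_CM_COL) / (2 * self.theta_max),
            )
        if self.V_GEN is None:
            object.__setattr__(self, "V_GEN", self.V_REST)
        self.validate()

    @property
    def delta(self) -> float:
        """Firing margin ``V_CM_COL - V_CM_TWG`` (volts)."""
        return self.V_CM_COL - self.V_CM_TWG

    def validate(self) -> None:
        if self.C_int <= 0:
            raise ValueError(f"C_int must be positive, got {self.C_int}")
        if self.I_LEAKAGE < 0 or self.t_leak < 0:
            raise ValueError("I_LEAKAGE and t_leak must be non-negative")
        if not self.V_LAT < self.V_RFR < self.V_REST:
            raise ValueError(
                "baseline ordering V_LAT < V_RFR < V_REST violated: "
                f"V_LAT={self.V_LAT}, V_RFR={self.V_RFR}, V_REST={self.V_REST}"
            )
        if self.V_TH <= self.V_REST:
            raise ValueError(
                f"V_TH={self.V_TH} must exceed V_REST={self.V_REST}"
            )
        if self.delta <= 0:
            raise ValueError(
                f"V_CM_TWG={self.V_CM_TWG} must lie below V_CM_COL="
                f"{self.V_CM_COL} (margin delta must be positive)"
            )
        if self.theta_max > 1 and self.delta * (self.theta_max - 1) >= (
            self.V_TH - self.V_CM_COL
        ):
            raise ValueError(
                f"margin delta={self.delta:.4g} V too large: requires "
                f"delta < (V_TH - V_CM_COL)/(theta_max - 1) = "
                f"{(self.V_TH - self.V_CM_COL) / (self.theta_max - 1):.4g} V "
                "so that a weight one unit below threshold never fires"
            )
        if not self.refractory_blocks_threshold():
            logger.warning(
                "V_RFR=%.4g V is not below V_CM_TWG=%.4g V: a threshold-equal "
                "stimulus can fire through the relative refractory period",
                self.V_RFR,
                self.V_CM_TWG,
            )

    def refractory_blocks_threshold(self) -> bool:
        """True when a w = theta stimulus cannot fire from V_RFR (or V_LAT).

        Starting from baseline B the deflection at w = theta is exactly
        ``V_TH - V_CM_TWG``, so the spike is blocked iff B < V_CM_TWG.
        """
        return self.V_RFR < self.V_CM_TWG


@dataclass(frozen=True)
class NeuronState:
    """Discrete state of one dendrite between GCLK cycles."""

    V_integ: float = 0.600
    baseline: float = 0.600
    abs_refractory_remaining: int = 0
    fired_last: bool = False
    subthreshold_last: bool = False

    @classmethod
    def resting(cls, cfg: AnalogConfig) -> "NeuronState":
        return cls(V_integ=cfg.V_REST, baseline=cfg.V_REST)


def integration_window(
    theta_units: int, cfg: AnalogConfig, params: DeviceParams
) -> float:
    """Threshold-derived integration time ``T_int`` in seconds.

    The ramp from ``V_CM_TWG`` to ``V_TH`` is driven by the net threshold
    current ``theta * alpha``; larger thresholds ramp faster and shorten
    the window, higher ``V_TH`` extends it.
    """
    if theta_units <= 0:
        raise ValueError(f"theta_units must be positive, got {theta_units}")
    return cfg.C_int * (cfg.V_TH - cfg.V_CM_TWG) / (theta_units * params.alpha)


def integrate(V_start: float, I_syn: float, T_int: float, C_int: float) -> float:
    """Capacitive integration: ``V_start + I_syn * T_int / C_int``."""
    if T_int <= 0:
        raise ValueError(f"T_int must be positive, got {T_int}")
    return V_start + I_syn * T_int / C_int


def fire_decision(V_integ: float, cfg: AnalogConfig, offset: float = 0.0) -> bool:
    """Comparator output: fire iff ``V_integ >= V_TH + offset``.

    ``offset`` is the comparator's input-referred offset voltage; zero in
    the ideal chip, sampled by the variation model otherwise.
    """
    return V_integ >= cfg.V_TH + offset


def leak(V: float, cfg: AnalogConfig) -> float:
    """One discrete leakage pulse toward ``V_REST``, never overshooting.

    The step magnitude ``I_LEAKAGE * t_leak / C_int`` is applied in the
    direction of ``V_REST`` and clamped at it, so ``V_REST`` is a fixed
    point and iterated leaking converges in finitely many pulses.
    """
    step = cfg.I_LEAKAGE * cfg.t_leak / cfg.C_int
    diff = cfg.V_REST - V
    if abs(diff) <= step:
        return cfg.V_REST
    return V + math.copysign(step, diff)


def select_baseline(
    fired_self: bool,
    fired_neighbor: bool,
    subthreshold: bool,
    cfg: AnalogConfig,
) -> float:
    """Baseline for the next stimulus cycle, by event priority.

    A neuron's own spike (relative refractory, ``V_RFR``) outranks a
    neighbor's spike (lateral inhibition, ``V_LAT``), which outranks a
    subthreshold deflection (``V_GEN``); otherwise the resting level.
    """
    if fired_self:
        return cfg.V_RFR
    if fired_neighbor:
        return cfg.V_LAT
    if subthreshold:
        return cfg.V_GEN
    return cfg.V_REST


def step_neuron(
    state: NeuronState,
    I_syn: float,
    theta_units: int,
    cfg: AnalogConfig,
    params: DeviceParams,
    n_abs: int = 1,
    offset: float = 0.0,
) -> tuple[NeuronState, bool]:
    """Run one stimulus-carrying GCLK cycle for a single dendrite.

    Phase order: absolute-refractory gate, reset to baseline, integrate
    over the threshold window, compare (fire and reset on success), leak
    (skipped on fire cycles), then choose the next baseline.  Lateral
    inhibition is not visible at this level — the cluster overrides the
    baseline of a fired neuron's neighbors afterwards.

    Returns the post-cycle state and whether the neuron fired.
    """
    if state.abs_refractory_remaining > 0:
        # Switch generator inactive: input ignored entirely, no reset,
        # no integration, no fire.  Baseline is left untouched.
        return (
            dataclasses.replace(
                state,
                abs_refractory_remaining=state.abs_refractory_remaining - 1,
                fired_last=False,
                subthreshold_last=False,
            ),
            False,
        )

    T_int = integration_window(theta_units, cfg, params)
    V = integrate(state.baseline, I_syn, T_int, cfg.C_int)
    fired = fire_decision(V, cfg, offset)
    subthreshold = (not fired) and V != state.baseline

    if fired:
        V = cfg.V_REST  # immediate repolarization; waveform not traced
    else:
        V = leak(V, cfg)

    return (
        NeuronState(
            V_integ=V,
            baseline=select_baseline(fired, False, subthreshold, cfg),
            abs_refractory_remaining=n_abs if fired else 0,
            fired_last=fired,
            subthreshold_last=subthreshold,
        ),
        fired,
    )
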