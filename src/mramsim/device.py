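"""Magnetic-tunnel-junction cell model and the dual-mode read circuit.

An MTJ stores one bit as its resistance: the parallel (P) configuration is
the low-resistance state, the anti-parallel (AP) configuration the
high-resistance state.  During synapse operation the bit line is clamped at
``V_READ_AMP`` by a regulation amplifier, so each cell sources an Ohm's-law
current ``I_P = V_READ_AMP / R_P`` or ``I_AP = V_READ_AMP / R_AP``.  The
difference ``alpha = I_P - I_AP`` is the quantum of synaptic weight used by
the current-subtraction architecture.

Writes are modeled as instantaneous, error-free state assignment; reads
never disturb the stored state.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Read-disturb guideline for the clamped bit-line voltage (volts).
READ_DISTURB_LIMIT = 50e-3


class MTJState(enum.Enum):
    """The two storable MTJ resistance states."""

    P = "P"    # parallel, low resistance
    AP = "AP"  # anti-parallel, high resistance


@dataclass(frozen=True)
class MTJCell:
    """A single one-transistor/one-MTJ memory cell."""

    state: MTJState = MTJState.AP

    def __post_init__(self) -> None:
        if not isinstance(self.state, MTJState):
            object.__setattr__(self, "state", MTJState(self.state))


@dataclass(frozen=True)
class DeviceParams:
    """Electrical parameters of the MTJ array read path.

    Parameters
    ----------
    R_P, R_AP :
        Parallel / anti-parallel resistances in ohms.  The fabricated
        devices span the envelope 10 kΩ:20 kΩ ... 5 kΩ:30 kΩ; the default
        pair sits at the low-contrast end of that envelope, where the
        single-P vs. double-AP current ambiguity is worst.
    V_READ_AMP :
        Clamped bit-line voltage in volts during synapse operation.
    """

    R_P: float = 10e3
    R_AP: float = 20e3
    V_READ_AMP: float = 50e-3

    def __post_init__(self) -> None:
        if self.V_READ_AMP <= 0:
            raise ValueError(f"V_READ_AMP must be positive, got {self.V_READ_AMP}")
        if self.R_P <= 0 or self.R_AP <= 0:
            raise ValueError(
                f"resistances must be positive, got R_P={self.R_P}, R_AP={self.R_AP}"
            )
        if self.R_P >= self.R_AP:
            raise ValueError(
                f"AP must be the high-resistance state: need R_P < R_AP, "
                f"got R_P={self.R_P} Ω, R_AP={self.R_AP} Ω"
            )

    @property
    def I_P(self) -> float:
        """Current through one P-state cell at the clamped voltage (A)."""
        return self.V_READ_AMP / self.R_P

    @property
    def I_AP(self) -> float:
        """Current through one AP-state cell at the clamped voltage (A)."""
        return self.V_READ_AMP / self.R_AP

    @property
    def alpha(self) -> float:
        """The weight quantum ``I_P - I_AP`` (A); positive by construction."""
        return self.I_P - self.I_AP


@dataclass(frozen=True)
class ReadReferencePair:
    """One P and one AP reference cell used for memory-read sensing."""

    cell_p: MTJCell = field(default_factory=lambda: MTJCell(MTJState.P))
    cell_ap: MTJCell = field(default_factory=lambda: MTJCell(MTJState.AP))

    def __post_init__(self) -> None:
        if self.cell_p.state is not MTJState.P or self.cell_ap.state is not MTJState.AP:
            raise ValueError("reference pair must hold one P and one AP cell")


def unit_currents(params: DeviceParams) -> tuple[float, float, float]:
    """Return ``(I_P, I_AP, alpha)`` for the given device parameters."""
    return params.I_P, params.I_AP, params.alpha


def cell_current(
    cell: MTJCell, mirror_ratio: int = 1, params: DeviceParams | None = None
) -> float:
    """Current contributed by one cell through a ``mirror_ratio``-scaled mirror.

    The current-generation circuit applies integer mirror ratios (x1, x2,
    x4, ...) to weight each bit of a multi-bit code.
    """
    if params is None:
        params = DeviceParams()
    if mirror_ratio < 1:
        raise ValueError(f"mirror_ratio must be >= 1, got {mirror_ratio}")
    base = params.I_P if cell.state is MTJState.P else params.I_AP
    return mirror_ratio * base


def read_cell(
    cell: MTJCell,
    refs: ReadReferencePair | None = None,
    params: DeviceParams | None = None,
    offset: float = 0.0,
) -> MTJState:
    """Memory-read discrimination of one cell against the reference pair.

    The sense threshold is the arithmetic mean of the P and AP reference
    currents; a cell current strictly above it reads as P, otherwise AP
    (midpoint ties resolve to the conservative high-resistance state).
    ``offset`` (amperes) models a sense-path error current; the stored
    state is never altered by a read.
    """
    if params is None:
        params = DeviceParams()
    if refs is None:
        refs = ReadReferencePair()
    i_ref = 0.5 * (
        cell_current(refs.cell_p, 1, params) + cell_current(refs.cell_ap, 1, params)
    )
    i_data = cell_current(cell, 1, params) + offset
    return MTJState.P if i_data > i_ref else MTJState.AP


def check_read_disturb(params: DeviceParams) -> bool:
    """Warn when the clamp voltage exceeds the read-disturb guideline.

    Returns True when the voltage is within the safe band.  A violation is
    logged, not raised: the bound is an ideal operating guideline and the
    simulation proceeds either way.
    """
    if params.V_READ_AMP > READ_DISTURB_LIMIT:
        logger.warning(
            "V_READ_AMP=%.4g V exceeds the read-disturb guideline of %.4g V",
            params.V_READ_AMP,
            READ_DISTURB_LIMIT,
        )
        return False
    return True
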