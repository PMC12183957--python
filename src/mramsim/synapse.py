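"""Crossbar weight storage and the current-subtraction synapse arithmetic.

A synaptic weight is a short multi-bit MTJ code read out through mirrored
current sources.  Because the P/AP resistance contrast is low (down to
1:2), raw code currents are ambiguous — one P cell can equal two AP cells.
The architecture resolves this by pairing every generation block with a
reference block of the same total mirror ratio and using only the
*difference* of their currents.  For matched totals the difference is an
exact integer multiple of the weight quantum ``alpha = I_P - I_AP``:

    I(gen) - I(ref) = (code_value(gen) - code_value(ref)) * alpha

where ``code_value`` is the mirror-ratio-weighted count of P cells.  A
positive net value is an excitatory postsynaptic potential (EPSP), a
negative one inhibitory (IPSP).  Simultaneously active axons sum on the
shared dendrite column, each row subtracting its own reference (spatial
summation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .device import DeviceParams, MTJCell, MTJState, cell_current

CodeShape = Literal["thermometer", "binary"]

#: Mirror ratios of the 3-bit binary code used on the chip.
BINARY_RATIOS = (1, 2, 4)
#: Unit-ratio thermometer code used in the worked examples (7 cells).
THERMOMETER_CELLS = 7
#: Reference code value shared by every worked example (two P, five AP).
DEFAULT_REF_VALUE = 2


@dataclass(frozen=True)
class WeightCode:
    """An ordered list of MTJ cells with per-cell mirror ratios.

    ``code_value`` (the ratio-weighted P count) is the digital value the
    code represents; ``total_ratio`` bounds it and must match between a
    generation code and its reference for subtraction to be defined.
    """

    cells: tuple[MTJCell, ...]
    ratios: tuple[int, ...]

    def __post_init__(self) -> None:
        cells = tuple(
            c if isinstance(c, MTJCell) else MTJCell(MTJState(c)) for c in self.cells
        )
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "ratios", tuple(int(r) for r in self.ratios))
        if len(self.cells) != len(self.ratios) or len(self.cells) < 1:
            raise ValueError(
                f"cells ({len(self.cells)}) and ratios ({len(self.ratios)}) must "
                "have equal, nonzero length"
            )
        if any(r < 1 for r in self.ratios):
            raise ValueError(f"mirror ratios must be >= 1, got {self.ratios}")

    @property
    def total_ratio(self) -> int:
        return sum(self.ratios)

    @property
    def code_value(self) -> int:
        return sum(
            r for c, r in zip(self.cells, self.ratios) if c.state is MTJState.P
        )

    @classmethod
    def from_value(
        cls, value: int, shape: CodeShape = "thermometer", n_cells: int | None = None
    ) -> "WeightCode":
        """Encode an unsigned code value into cell states of a given shape.

        Thermometer codes set the first ``value`` unit-ratio cells to P;
        binary codes use mirror ratios 1, 2, 4, ... and the binary digits
        of ``value``.
        """
        if shape == "thermometer":
            n = THERMOMETER_CELLS if n_cells is None else n_cells
            if not 0 <= value <= n:
                raise ValueError(f"value {value} outside 0..{n} for {n}-cell code")
            states = [MTJState.P] * value + [MTJState.AP] * (n - value)
            ratios = [1] * n
        elif shape == "binary":
            n = len(BINARY_RATIOS) if n_cells is None else n_cells
            ratios = [1 << i for i in range(n)]
            if not 0 <= value <= sum(ratios):
                raise ValueError(
                    f"value {value} outside 0..{sum(ratios)} for {n}-bit code"
                )
            states = [
                MTJState.P if value >> i & 1 else MTJState.AP for i in range(n)
            ]
        else:
            raise ValueError(f"unknown code shape {shape!r}")
        return cls(tuple(MTJCell(s) for s in states), tuple(ratios))


def code_current(code: WeightCode, params: DeviceParams | None = None) -> float:
    """Raw (un-subtracted) current of a code: Σ ratio_i × I(state_i)."""
    if params is None:
        params = DeviceParams()
    return sum(
        cell_current(c, r, params) for c, r in zip(code.cells, code.ratios)
    )


def net_alpha_units(gen: WeightCode, ref: WeightCode) -> int:
    """Signed weight, in alpha units, of a generation/reference code pair.

    Defined only for matched total mirror ratios; the returned integer
    satisfies ``code_current(gen) - code_current(ref) == result * alpha``
    exactly (up to floating rounding).
    """
    if gen.total_ratio != ref.total_ratio:
        raise ValueError(
            f"subtraction requires matched totals: generation total "
            f"{gen.total_ratio} != reference total {ref.total_ratio}"
        )
    return gen.code_value - ref.code_value


@dataclass(frozen=True)
class ThresholdBlock:
    """Per-cluster threshold storage: a generation and a reference code.

    The net value ``theta_units`` = gen − ref (in alpha units) is shared by
    all neurons of the cluster and sets the integration time window.
    """

    gen: WeightCode
    ref: WeightCode

    def __post_init__(self) -> None:
        if self.gen.total_ratio != self.ref.total_ratio:
            raise ValueError("threshold gen/ref codes must have matched totals")
        if self.gen.code_value - self.ref.code_value < 1:
            raise ValueError(
                "a neuron must have a positive threshold: gen code value "
                f"{self.gen.code_value} - ref {self.ref.code_value} < 1"
            )

    @classmethod
    def from_units(
        cls,
        theta_units: int,
        ref_value: int = DEFAULT_REF_VALUE,
        shape: CodeShape = "thermometer",
        n_cells: int | None = None,
    ) -> "ThresholdBlock":
        n = n_cells
        if shape == "thermometer" and n is None:
            n = max(THERMOMETER_CELLS, theta_units + ref_value)
        return cls(
            WeightCode.from_value(theta_units + ref_value, shape, n),
            WeightCode.from_value(ref_value, shape, n),
        )


def threshold_units(block: ThresholdBlock) -> int:
    """Net cluster threshold in alpha units (validated positive)."""
    return net_alpha_units(block.gen, block.ref)


@dataclass
class SynapseMatrix:
    """K axons × N dendrites of weight codes plus per-axon-row references.

    Each axon row carries one PSP reference block; when several axons are
    active in the same tick, each active row subtracts its own reference
    before the column sums, which is what makes simultaneous EPSP/IPSP
    arithmetic come out in alpha units.
    """

    weights: list[list[WeightCode]]
    psp_refs: list[WeightCode]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.psp_refs):
            raise ValueError(
                f"{len(self.weights)} weight rows but {len(self.psp_refs)} "
                "PSP reference rows"
            )
        n_cols = {len(row) for row in self.weights}
        if len(n_cols) > 1:
            raise ValueError(f"ragged weight matrix: row lengths {sorted(n_cols)}")
        for k, (row, ref) in enumerate(zip(self.weights, self.psp_refs)):
            for n, code in enumerate(row):
                if code.total_ratio != ref.total_ratio:
                    raise ValueError(
                        f"weight ({k},{n}) total {code.total_ratio} != row "
                        f"reference total {ref.total_ratio}"
                    )

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def N(self) -> int:
        return len(self.weights[0]) if self.weights else 0

    def alpha_matrix(self) -> np.ndarray:
        """Decode back to the K×N signed integer weight table."""
        return np.array(
            [
                [net_alpha_units(code, ref) for code in row]
                for row, ref in zip(self.weights, self.psp_refs)
            ],
            dtype=int,
        )


def program_weights(
    alpha_matrix: Sequence[Sequence[int]] | np.ndarray,
    ref_value: int = DEFAULT_REF_VALUE,
    code_shape: CodeShape = "thermometer",
    n_cells: int | None = None,
) -> SynapseMatrix:
    """Encode a signed weight table (alpha units) into a programmed array.

    Each weight ``w`` becomes a code with value ``w + ref_value``; the
    per-row reference holds ``ref_value``.  The representable range is
    ``-ref_value .. total_ratio - ref_value``.
    """
    W = np.asarray(alpha_matrix, dtype=int)
    if W.ndim != 2:
        raise ValueError(f"weight table must be 2-D, got shape {W.shape}")
    if code_shape == "thermometer" and n_cells is None:
        n_cells = max(THERMOMETER_CELLS, int(W.max(initial=0)) + ref_value)
    probe = WeightCode.from_value(ref_value, code_shape, n_cells)
    total = probe.total_ratio
    lo, hi = -ref_value, total - ref_value
    for (k, n), w in np.ndenumerate(W):
        if not lo <= w <= hi:
            raise ValueError(
                f"weight {w} at (axon {k}, dendrite {n}) outside the "
                f"representable range {lo}..{hi} for total ratio {total} "
                f"and reference value {ref_value}"
            )
    weights = [
        [WeightCode.from_value(int(w) + ref_value, code_shape, n_cells) for w in row]
        for row in W
    ]
    refs = [
        WeightCode.from_value(ref_value, code_shape, n_cells) for _ in range(W.shape[0])
    ]
    return SynapseMatrix(weights, refs)


def column_current(
    active_axons: Iterable[int],
    dendrite: int,
    matrix: SynapseMatrix,
    params: DeviceParams | None = None,
) -> float:
    """Net synaptic current on one dendrite for a set of active axons (A).

    Spatial summation: every active row contributes
    ``code_current(weight) - code_current(psp_ref)``; an empty active set
    yields 0 A.
    """
    if params is None:
        params = DeviceParams()
    total = 0.0
    for k in set(active_axons):
        if not 0 <= k < matrix.K:
            raise IndexError(f"axon index {k} outside 0..{matrix.K - 1}")
        total += code_current(matrix.weights[k][dendrite], params) - code_current(
            matrix.psp_refs[k], params
        )
    return total


def collision_report(
    shape: CodeShape = "thermometer",
    params: DeviceParams | None = None,
    max_cells: int | None = None,
    rel_tol: float = 1e-9,
    subtract: bool = False,
    ref_value: int = DEFAULT_REF_VALUE,
) -> pd.DataFrame:
    """Enumerate current-level collisions caused by the low on/off contrast.

    Without subtraction (``subtract=False``) the report enumerates every
    distinct access pattern — any subset of cells of the shape, each in
    either state — computes its raw current, and groups patterns whose
    currents agree within ``rel_tol`` but whose code values differ.  With
    the 10 kΩ:20 kΩ devices (I_P/I_AP = 2) this flags the classic
    ambiguity of one P cell against two AP cells.

    With ``subtract=True`` the net levels ``w × alpha`` for all codes of
    the full shape against a ``ref_value`` reference are grouped instead;
    the subtraction architecture makes them all distinct, so the report is
    empty.

    Returns a DataFrame with columns ``group``, ``current_A``,
    ``code_value``, ``pattern`` (one row per colliding pattern).
    """
    if params is None:
        params = DeviceParams()
    if shape == "thermometer":
        ratios = [1] * (THERMOMETER_CELLS if max_cells is None else max_cells)
    elif shape == "binary":
        n = len(BINARY_RATIOS) if max_cells is None else max_cells
        ratios = [1 << i for i in range(n)]
    else:
        raise ValueError(f"unknown code shape {shape!r}")

    entries: dict[tuple, tuple[float, int, str]] = {}
    if subtract:
        total = sum(ratios)
        n_cells = len(ratios)
        for value in range(total + 1):
            w = value - ref_value
            entries[("net", w)] = (
                w * params.alpha,
                w,
                f"code {value} - ref {ref_value}",
            )
    else:
        # Every access pattern: a subset of cells, each P or AP.  Patterns
        # are canonicalized by the multiset of (ratio, state) so thermometer
        # duplicates collapse.
        for r_subset in _ratio_subsets(ratios):
            for states in itertools.product((MTJState.P, MTJState.AP), repeat=len(r_subset)):
                key = ("raw",) + tuple(sorted(zip(r_subset, (s.value for s in states))))
                if key in entries:
                    continue
                current = sum(
                    r * (params.I_P if s is MTJState.P else params.I_AP)
                    for r, s in zip(r_subset, states)
                )
                value = sum(r for r, s in zip(r_subset, states) if s is MTJState.P)
                label = "+".join(
                    f"{r}x{s.value}" for r, s in zip(r_subset, states)
                )
                entries[key] = (current, value, label)

    rows = sorted(entries.values())
    scale = max(params.I_P, 1e-30)
    groups: list[list[tuple[float, int, str]]] = []
    for row in rows:
        if groups and abs(row[0] - groups[-1][-1][0]) <= rel_tol * scale:
            groups[-1].append(row)
        else:
            groups.append([row])

    records = []
    for gi, group in enumerate(groups):
        if len(group) < 2 or len({v for _, v, _ in group}) < 2:
            continue
        for current, value, label in group:
            records.append(
                {"group": gi, "current_A": current, "code_value": value, "pattern": label}
            )
    return pd.DataFrame.from_records(
        records, columns=["group", "current_A", "code_value", "pattern"]
    )


def _ratio_subsets(ratios: Sequence[int]) -> list[tuple[int, ...]]:
    """Nonempty subsets of mirror ratios, deduplicated as multisets."""
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for r in range(1, len(ratios) + 1):
        for combo in itertools.combinations(ratios, r):
            key = tuple(sorted(combo))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out
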