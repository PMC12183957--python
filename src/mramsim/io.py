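"""CSV readers/writers and the random fixture generator.

File formats (all RFC-4180-style CSV with a header row):

* stimulus:  ``tick,axon`` — one axon event per row, GCLK-grid aligned
* raster:    ``tick,dendrite`` — one output spike per row
* traces:    ``tick,neuron,phase,volts``
* weights:   signed alpha-unit integers, one row per axon, header row of
  dendrite indices
* bit dump:  ``axon,dendrite,bit,ratio,state`` — one MTJ cell per row;
  ``dendrite = -1`` rows hold the per-axon PSP reference cells

Readers reject ragged or malformed rows with the file line number.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cluster import SpikeRaster, StimulusSchedule
from .config import ArraySpec, SimulationConfig, ThresholdSpec
from .device import MTJCell, MTJState
from .synapse import SynapseMatrix, WeightCode


class InputFileError(ValueError):
    """A malformed input file; the message carries the line number."""


def _read_rows(path: str | Path, expected_header: list[str]) -> Iterable[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFileError(f"{path}: empty file, expected header "
                                 f"{','.join(expected_header)}") from None
        if [h.strip() for h in header] != expected_header:
            raise InputFileError(
                f"{path}:1: expected header {','.join(expected_header)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise InputFileError(
                    f"{path}:{lineno}: expected {len(expected_header)} fields, "
                    f"got {len(row)}"
                )
            yield lineno, row


def read_stimulus(path: str | Path) -> StimulusSchedule:
    events = []
    for lineno, row in _read_rows(path, ["tick", "axon"]):
        try:
            events.append((int(row[0]), int(row[1])))
        except ValueError:
            raise InputFileError(
                f"{path}:{lineno}: non-integer field in {row}"
            ) from None
    return StimulusSchedule(events)


def write_stimulus(schedule: StimulusSchedule, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tick", "axon"])
        w.writerows(schedule.events)


def read_raster(path: str | Path) -> SpikeRaster:
    spikes = []
    for lineno, row in _read_rows(path, ["tick", "dendrite"]):
        try:
            spikes.append((int(row[0]), int(row[1])))
        except ValueError:
            raise InputFileError(
                f"{path}:{lineno}: non-integer field in {row}"
            ) from None
    return SpikeRaster(spikes)


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tick", "dendrite"])
        w.writerows(raster.spikes)


def write_traces(traces: pd.DataFrame, path: str | Path) -> None:
    traces.to_csv(path, index=False)


def read_weights(path: str | Path) -> np.ndarray:
    """Signed alpha-unit weight table with a dendrite-index header row."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InputFileError(f"{path}: empty weight file") from None
        n = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n:
                raise InputFileError(
                    f"{path}:{lineno}: expected {n} fields, got {len(row)}"
                )
            try:
                rows.append([int(v) for v in row])
            except ValueError:
                raise InputFileError(
                    f"{path}:{lineno}: non-integer weight in {row}"
                ) from None
    return np.array(rows, dtype=int)


def write_weights(alpha_matrix: np.ndarray, path: str | Path) -> None:
    W = np.asarray(alpha_matrix, dtype=int)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(range(W.shape[1])))
        w.writerows(W.tolist())


def write_bit_dump(matrix: SynapseMatrix, path: str | Path) -> None:
    """Raw per-cell dump: every weight cell plus the per-row references."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["axon", "dendrite", "bit", "ratio", "state"])
        for k, (row, ref) in enumerate(zip(matrix.weights, matrix.psp_refs)):
            for b, (cell, ratio) in enumerate(zip(ref.cells, ref.ratios)):
                w.writerow([k, -1, b, ratio, cell.state.value])
            for n, code in enumerate(row):
                for b, (cell, ratio) in enumerate(zip(code.cells, code.ratios)):
                    w.writerow([k, n, b, ratio, cell.state.value])


def read_bit_dump(path: str | Path) -> SynapseMatrix:
    cells: dict[tuple[int, int], dict[int, tuple[int, str]]] = {}
    for lineno, row in _read_rows(path, ["axon", "dendrite", "bit", "ratio", "state"]):
        try:
            k, n, b, r = int(row[0]), int(row[1]), int(row[2]), int(row[3])
            state = row[4].strip()
        except ValueError:
            raise InputFileError(
                f"{path}:{lineno}: malformed cell row {row}"
            ) from None
        if state not in ("P", "AP"):
            raise InputFileError(
                f"{path}:{lineno}: state must be P or AP, got {state!r}"
            )
        cells.setdefault((k, n), {})[b] = (r, state)

    def build(code_cells: dict[int, tuple[int, str]]) -> WeightCode:
        bits = sorted(code_cells)
        return WeightCode(
            tuple(MTJCell(MTJState(code_cells[b][1])) for b in bits),
            tuple(code_cells[b][0] for b in bits),
        )

    K = 1 + max(k for k, _ in cells)
    N = 1 + max(n for _, n in cells)
    refs = [build(cells[(k, -1)]) for k in range(K)]
    weights = [[build(cells[(k, n)]) for n in range(N)] for k in range(K)]
    return SynapseMatrix(weights, refs)


def generate_fixtures(
    seed: int = 0,
    n_random: int = 3,
    K: int = 8,
    N: int = 8,
    n_ticks: int = 20,
    rate: float = 0.15,
) -> tuple[list[SimulationConfig], list[StimulusSchedule]]:
    """Random-but-valid configurations and stimulus streams for testing.

    Produces ``n_random`` uniform-random weight matrices over the
    representable range with Poisson-like event streams, plus adversarial
    edge cases: an all-IPSP array, a threshold-boundary array holding
    every representable weight in {theta-1, theta, theta+1}, and a
    full-row simultaneous-activation schedule.
    """
    rng = np.random.default_rng(seed)
    configs: list[SimulationConfig] = []
    schedules: list[StimulusSchedule] = []
    theta = 5
    lo, hi = -2, 5

    for _ in range(n_random):
        W = rng.integers(lo, hi + 1, size=(K, N))
        configs.append(
            SimulationConfig(
                array=ArraySpec(K=K, N=N, weights=W.tolist()),
                threshold=ThresholdSpec(theta_units=theta),
            )
        )
        events = [
            (t, a)
            for t in range(n_ticks)
            for a in range(K)
            if rng.random() < rate
        ]
        schedules.append(StimulusSchedule(events))

    # All-IPSP columns: nothing may ever fire.
    configs.append(
        SimulationConfig(
            array=ArraySpec(K=K, N=N, weights=(-np.ones((K, N), dtype=int) * 2).tolist()),
            threshold=ThresholdSpec(theta_units=theta),
        )
    )
    schedules.append(StimulusSchedule([(t, int(a)) for t in range(n_ticks)
                                       for a in rng.integers(0, K, 2)]))

    # Threshold-boundary weights theta-1, theta (theta+1 not representable
    # for theta = 5 with 7-unit codes).
    boundary = [w for w in (theta - 1, theta, theta + 1) if lo <= w <= hi]
    Wb = np.tile(boundary, (1, N))[:, :N]
    configs.append(
        SimulationConfig(
            array=ArraySpec(K=1, N=N, weights=Wb.tolist()),
            threshold=ThresholdSpec(theta_units=theta),
        )
    )
    schedules.append(StimulusSchedule([(0, 0), (3, 0)]))

    # Simultaneous full-row activation.
    Wf = rng.integers(lo, hi + 1, size=(K, N))
    configs.append(
        SimulationConfig(
            array=ArraySpec(K=K, N=N, weights=Wf.tolist()),
            threshold=ThresholdSpec(theta_units=theta),
        )
    )
    schedules.append(StimulusSchedule([(0, a) for a in range(K)]))

    return configs, schedules
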