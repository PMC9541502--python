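"""Stepped wedge schematics and batched designs.

A *schematic* is a sequences-by-periods matrix of treatment indicators
(0 = control, 1 = intervention) with optional unobserved cells.  A
*batched design* is an ordered series of self-contained schematics whose
clusters commence trial participation at (possibly) different calendar
times; consecutive batches may share calendar periods ("overlap").

Period indices are 1-based *within a batch* (time-on-trial).  Calendar
indices are derived and used only for layout and reporting: with
batch-specific period effects in the analysis model, the calendar
alignment of batches has no effect on the precision of the treatment
effect estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Cell codes for the schematic matrix.
CONTROL = 0
INTERVENTION = 1
UNOBSERVED = -1


class InvalidDesignError(ValueError):
    """A schematic or batched design violates a structural requirement."""


class ConfigError(ValueError):
    """Inconsistent configuration arguments (lengths, ranges, types)."""


@dataclass(frozen=True)
class TreatmentSchematic:
    """Treatment-indicator matrix for one stepped wedge component.

    Parameters
    ----------
    cells
        Integer matrix of shape (n_sequences, n_periods) with entries in
        {0, 1, -1}; -1 marks a cell in which no data are collected.
    sequence_labels, period_labels
        Optional row/column names, used for reporting only.
    """

    cells: np.ndarray
    sequence_labels: tuple[str, ...] | None = None
    period_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells, dtype=int)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InvalidDesignError("schematic must be a non-empty 2-D matrix")
        bad = ~np.isin(arr, (CONTROL, INTERVENTION, UNOBSERVED))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise InvalidDesignError(
                f"illegal cell value {arr[r, c]} at sequence {r + 1}, period {c + 1}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "cells", arr)

    @property
    def n_sequences(self) -> int:
        return self.cells.shape[0]

    @property
    def n_periods(self) -> int:
        return self.cells.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean matrix marking cells in which data are collected."""
        return self.cells != UNOBSERVED

    def violations(self) -> list[str]:
        """Check the structural invariants; empty list means valid.

        A schematic is valid when every sequence switches at most once
        from control to intervention (unidirectional rollout) and when
        both conditions are observed somewhere (otherwise the treatment
        effect is inestimable).
        """
        out: list[str] = []
        for k, row in enumerate(self.cells):
            obs = row[row != UNOBSERVED]
            if np.any(np.diff(obs) < 0):
                out.append(
                    f"sequence {k + 1}: treatment indicator decreases across "
                    "observed periods (intervention removed after rollout)"
                )
        obs_cells = self.cells[self.cells != UNOBSERVED]
        if obs_cells.size == 0:
            out.append("schematic has no observed cells")
        else:
            if not np.any(obs_cells == CONTROL):
                out.append("no observed control cell: treatment effect inestimable")
            if not np.any(obs_cells == INTERVENTION):
                out.append("no observed intervention cell: treatment effect inestimable")
        return out


@dataclass(frozen=True)
class Batch:
    """One component of a batched design."""

    schematic: TreatmentSchematic
    clusters_per_sequence: int
    calendar_start: int  # 1-based calendar period of the batch's first period

    def __post_init__(self) -> None:
        if self.clusters_per_sequence < 1:
            raise ConfigError("clusters_per_sequence must be a positive integer")
        if self.calendar_start < 1:
            raise ConfigError("calendar_start must be a positive (1-based) index")

    @property
    def calendar_end(self) -> int:
        return self.calendar_start + self.schematic.n_periods - 1


@dataclass(frozen=True)
class BatchedDesign:
    """An ordered series of stepped wedge components.

    Batches are ordered by calendar start.  The overlap between
    consecutive batches is the number of calendar periods during which
    both collect data; it affects only the calendar layout, never the
    per-batch schematics that the variance computations consume.
    """

    batches: tuple[Batch, ...]

    def __post_init__(self) -> None:
        if len(self.batches) == 0:
            raise ConfigError("a batched design needs at least one batch")
        starts = [b.calendar_start for b in self.batches]
        if any(s2 < s1 for s1, s2 in zip(starts, starts[1:])):
            raise InvalidDesignError("calendar_start must be non-decreasing over batches")

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    @property
    def overlaps(self) -> tuple[int, ...]:
        """Shared-calendar-period counts between consecutive batches."""
        out = []
        for a, b in zip(self.batches, self.batches[1:]):
            shared = min(a.calendar_end, b.calendar_end) - max(
                a.calendar_start, b.calendar_start
            ) + 1
            out.append(max(shared, 0))
        return tuple(out)

    @property
    def total_calendar_periods(self) -> int:
        return max(b.calendar_end for b in self.batches)

    def violations(self) -> list[str]:
        out: list[str] = []
        for i, b in enumerate(self.batches):
            out.extend(f"batch {i + 1}: {v}" for v in b.schematic.violations())
        return out


def build_standard_sw(n_periods: int) -> TreatmentSchematic:
    """Standard stepped wedge staircase with T periods and T-1 sequences.

    Sequence k (1-based) is in the control condition for periods 1..k
    and in the intervention condition for periods k+1..T; every cell is
    observed.

    >>> build_standard_sw(4).cells.tolist()
    [[0, 1, 1, 1], [0, 0, 1, 1], [0, 0, 0, 1]]
    """
    if n_periods < 2:
        raise InvalidDesignError("a stepped wedge needs at least 2 periods")
    t = np.arange(1, n_periods + 1)
    k = np.arange(1, n_periods)[:, None]
    return TreatmentSchematic((t[None, :] > k).astype(int))


def _as_list(value, n: int, name: str) -> list:
    if isinstance(value, (list, tuple, np.ndarray)):
        vals = list(value)
        if len(vals) != n:
            raise ConfigError(f"{name}: expected {n} values, got {len(vals)}")
        return vals
    return [value] * n


def make_batched(
    component: TreatmentSchematic | Sequence[TreatmentSchematic],
    n_batches: int | None = None,
    overlap: int | Sequence[int] = 0,
    clusters_per_sequence: int | Sequence[int] = 1,
) -> BatchedDesign:
    """Assemble a batched design from one or more component schematics.

    ``overlap`` gives, for each pair of consecutive batches, the number
    of shared calendar periods (0 = the next batch starts right after
    the previous one ends; T = fully aligned starts for equal-length
    batches).  Equivalently the start offset of batch b+1 relative to
    batch b is ``T_b - overlap_b``.
    """
    if isinstance(component, TreatmentSchematic):
        if n_batches is None or n_batches < 1:
            raise ConfigError("n_batches must be a positive integer")
        components = [component] * n_batches
    else:
        components = list(component)
        if n_batches is not None and n_batches != len(components):
            raise ConfigError(
                f"n_batches={n_batches} inconsistent with {len(components)} components"
            )
    n = len(components)
    if n == 0:
        raise ConfigError("at least one component schematic is required")
    overlaps = _as_list(overlap, max(n - 1, 0), "overlap")
    clusters = _as_list(clusters_per_sequence, n, "clusters_per_sequence")

    batches = []
    start = 1
    for b, comp in enumerate(components):
        batches.append(Batch(comp, int(clusters[b]), start))
        if b < n - 1:
            ov = int(overlaps[b])
            if ov < 0 or ov > min(comp.n_periods, components[b + 1].n_periods):
                raise InvalidDesignError(
                    f"overlap {ov} between batches {b + 1} and {b + 2} outside "
                    f"[0, {min(comp.n_periods, components[b + 1].n_periods)}]"
                )
            start = start + comp.n_periods - ov
    return BatchedDesign(tuple(batches))


def validate(design: BatchedDesign | TreatmentSchematic) -> list[str]:
    """Report all invariant violations (empty list = valid).

    Content problems are reported, never raised, so a front end can show
    every defect of a hand-written design CSV at once.
    """
    return design.violations()
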