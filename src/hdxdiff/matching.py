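"""Align peptides across protein states, timepoints and replicates.

Differential analysis only makes sense on peptides observed in every state
at every shared exposure time, so matching is an intersection: the matched
table contains exactly the peptides present in all states at all shared
timepoints, with replicate uptake values aligned per cell.  The first state
in the table is the reference that every other state is compared against;
it can be changed with :func:`reorder_reference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .io_formats import PeptideRecord


class MatchingError(ValueError):
    """Peptide intersection across states is empty or reference unknown."""


@dataclass(frozen=True, order=True)
class PeptideKey:
    """Biological identity of a peptide: sequence plus 1-based residue span.

    Charge state and retention time are deliberately excluded — charge-state
    rows are averaged upstream.
    """

    sequence: str = field(compare=False)
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MatchedTable:
    """Peptides common to all states with aligned replicate measurements.

    ``uptake[(key, state, timepoint)]`` is an array of replicate uptake
    values in Da; ``percent`` mirrors it for percent deuteration (possibly
    empty when the export lacked %D).  ``states[0]`` is the reference.
    """

    peptides: list[PeptideKey]
    states: list[str]
    timepoints_s: list[float]
    uptake: dict[tuple[PeptideKey, str, float], np.ndarray]
    percent: dict[tuple[PeptideKey, str, float], np.ndarray]
    n_replicates: dict[str, int]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def reference(self) -> str:
        return self.states[0]

    def uptake_values(self, key: PeptideKey, state: str, tp: float) -> np.ndarray:
        return self.uptake[(key, state, tp)]

    def percent_values(self, key: PeptideKey, state: str, tp: float) -> np.ndarray:
        return self.percent.get((key, state, tp), np.array([]))

    def comparisons(self) -> list[tuple[str, str]]:
        """Default comparisons: every non-reference state vs the reference."""
        return [(self.reference, s) for s in self.states[1:]]


def _aggregate_charges(
    records: Iterable[PeptideRecord],
) -> dict[tuple[str, PeptideKey, float, int], tuple[float | None, float | None]]:
    """Average multiple charge-state rows of the same observation."""
    acc: dict[tuple, list[PeptideRecord]] = {}
    for r in records:
        key = PeptideKey(r.sequence, r.start, r.end)
        acc.setdefault((r.protein_state, key, r.exposure_s, r.replicate), []).append(r)
    out = {}
    for k, rows in acc.items():
        up = [r.uptake_da for r in rows if r.uptake_da is not None]
        pc = [r.percent_d for r in rows if r.percent_d is not None]
        out[k] = (
            float(np.mean(up)) if up else None,
            float(np.mean(pc)) if pc else None,
        )
    return out


def match_peptides(
    records: Iterable[PeptideRecord],
    reference: str | None = None,
    timepoint_tolerance: float = 0.0,
) -> MatchedTable:
    """Build the matched table from parsed records.

    Fully-deuterated control rows and the undeuterated (0 s) timepoint are
    excluded from the test set.  Timepoints are the intersection of exposure
    times across states (exact equality after unit normalisation, or within
    ``timepoint_tolerance`` seconds when nonzero).  Peptides are the
    intersection over states of peptides observed at every shared timepoint.
    The per-state count of dropped peptides is recorded on the table.
    """
    records = [r for r in records if not r.is_fd_control and r.exposure_s > 0]
    if not records:
        raise MatchingError("no testable records (all FD or undeuterated)")

    states: list[str] = []
    for r in records:
        if r.protein_state not in states:
            states.append(r.protein_state)
    if reference is not None:
        if reference not in states:
            raise MatchingError(f"reference state {reference!r} not in data")
        states = [reference] + [s for s in states if s != reference]

    # shared timepoints
    times_by_state = {
        s: sorted({r.exposure_s for r in records if r.protein_state == s})
        for s in states
    }
    shared = _intersect_times(times_by_state, states, timepoint_tolerance)
    if not shared:
        raise MatchingError("states share no exposure times")

    cells = _aggregate_charges(records)

    # per state: peptides observed at every shared timepoint
    observed: dict[str, dict[PeptideKey, set[float]]] = {s: {} for s in states}
    for (state, key, tp, _rep) in cells:
        tp_canon = _canon_time(tp, shared, timepoint_tolerance)
        if tp_canon is not None:
            observed[state].setdefault(key, set()).add(tp_canon)
    full_sets = {
        s: {k for k, tps in observed[s].items() if tps == set(shared)}
        for s in states
    }
    matched = set.intersection(*(full_sets[s] for s in states))
    if not matched:
        worst = min(states, key=lambda s: len(full_sets[s]))
        raise MatchingError(
            f"no peptides common to all states at all timepoints; "
            f"state {worst!r} has least overlap ({len(full_sets[worst])} complete peptides)"
        )
    dropped = {s: len(observed[s]) - len(matched) for s in states}

    # collect replicate arrays per cell
    uptake: dict[tuple, list[tuple[int, float]]] = {}
    percent: dict[tuple, list[tuple[int, float]]] = {}
    for (state, key, tp, rep), (up, pc) in cells.items():
        if key not in matched:
            continue
        tp_canon = _canon_time(tp, shared, timepoint_tolerance)
        if tp_canon is None:
            continue
        if up is not None:
            uptake.setdefault((key, state, tp_canon), []).append((rep, up))
        if pc is not None:
            percent.setdefault((key, state, tp_canon), []).append((rep, pc))

    def _to_arrays(d: dict) -> dict:
        return {
            k: np.array([v for _, v in sorted(vals)], dtype=float)
            for k, vals in d.items()
        }

    uptake_a = _to_arrays(uptake)
    percent_a = _to_arrays(percent)
    peptides = sorted(matched, key=lambda k: (k.start, k.end, k.sequence))
    n_replicates = {
        s: min(
            len(uptake_a.get((k, s, t), percent_a.get((k, s, t), ())))
            for k in peptides
            for t in shared
        )
        for s in states
    }
    return MatchedTable(
        peptides=peptides,
        states=states,
        timepoints_s=list(shared),
        uptake=uptake_a,
        percent=percent_a,
        n_replicates=n_replicates,
        dropped=dropped,
    )


def _intersect_times(
    times_by_state: Mapping[str, list[float]], states: list[str], tol: float
) -> list[float]:
    ref_times = times_by_state[states[0]]
    if tol <= 0:
        shared = set(ref_times)
        for s in states[1:]:
            shared &= set(times_by_state[s])
        return sorted(shared)
    out = []
    for t in ref_times:
        if all(
            any(abs(t - u) <= tol for u in times_by_state[s]) for s in states[1:]
        ):
            out.append(t)
    return out


def _canon_time(t: float, shared: list[float], tol: float) -> float | None:
    if tol <= 0:
        return t if t in shared else None
    for s in shared:
        if abs(t - s) <= tol:
            return s
    return None


def reorder_reference(table: MatchedTable, new_reference: str) -> MatchedTable:
    """Return the same table with ``new_reference`` rotated to the front.

    Values are untouched; the relative order of the remaining states is
    preserved.  Applying the operation twice restores the original order
    only when the displaced state is re-selected, but re-selecting the
    current reference is a no-op.
    """
    if new_reference not in table.states:
        raise MatchingError(f"state {new_reference!r} not in table")
    if new_reference == table.reference:
        return replace(table, states=list(table.states))
    states = [new_reference] + [s for s in table.states if s != new_reference]
    return replace(table, states=states)
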