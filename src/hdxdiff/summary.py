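"""Per-state publication summary statistics.

Community reporting guidelines for HDX-MS ask every publication to state,
per protein state: the exposure times, replicate count, peptide count,
sequence coverage, average peptide length, redundancy, the pooled replicate
SD and the critical interval of the differential test, and back-exchange
statistics from a fully-deuterated (FD) control.  This module computes all
of them from the matched table and raw records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import PeptideRecord
from .matching import MatchedTable, PeptideKey
from .stats import DEFAULT_ALPHA, critical_interval, _pooled_sd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Publication summary for one protein state.

    Back-exchange fields are ``None`` (rendered "n.d.") when the state has
    no FD control; the reference state's ``critical_interval_da`` is ``None``
    because the interval is a property of a comparison, not a single state.
    """

    state: str
    timepoints_s: Sequence[float]
    n_replicates: int
    n_peptides: int
    coverage_pct: float
    avg_peptide_length: float
    avg_redundancy: float
    pooled_sd_da: float
    critical_interval_da: float | None
    avg_back_exchange_pct: float | None
    back_exchange_range_pct: tuple[float, float] | None


def coverage_and_redundancy(
    peptides: Iterable[PeptideKey], protein_length: int
) -> tuple[float, float]:
    """Sequence coverage (%) and mean per-residue peptide depth.

    Coverage counts residues touched by at least one peptide; redundancy is
    the mean depth over *covered* residues only (so it is >= 1 whenever
    coverage is nonzero).
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide list")
    depth = np.zeros(protein_length, dtype=int)
    for p in peptides:
        if p.end > protein_length:
            raise ValueError(
                f"peptide {p.sequence} ({p.start}-{p.end}) exceeds protein "
                f"length {protein_length}"
            )
        depth[p.start - 1 : p.end] += 1
    covered = depth > 0
    coverage_pct = 100.0 * covered.sum() / protein_length
    avg_redundancy = float(depth[covered].mean())
    return coverage_pct, avg_redundancy


def exchangeable_amides(sequence: str, convention: str = "first_two_excluded") -> int:
    """Number of backbone amides that can retain deuterium.

    ``first_two_excluded`` (default): length - 2 - prolines at position > 2
    (the N-terminal residue has no amide hydrogen and the second backbone
    amide back-exchanges too fast to measure).  ``first_excluded``:
    length - 1 - prolines at position >= 2.
    """
    L = len(sequence)
    if convention == "first_two_excluded":
        return max(L - 2 - sequence[2:].count("P"), 0)
    if convention == "first_excluded":
        return max(L - 1 - sequence[1:].count("P"), 0)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class BackExchange:
    """Per-peptide back exchange and its aggregate statistics (percent)."""

    per_peptide: dict[PeptideKey, float]
    mean_pct: float
    min_pct: float
    max_pct: float
    n_skipped: int


def back_exchange(
    records: Iterable[PeptideRecord],
    d_fraction: float = 1.0,
    convention: str = "first_two_excluded",
) -> BackExchange | None:
    """Back exchange from fully-deuterated control rows.

    BE% = 100 * (1 - uptake_fd / (max_uptake * d_fraction)) per peptide,
    where ``max_uptake`` is the exchangeable-amide count and ``d_fraction``
    the deuterium fraction of the labeling buffer.  FD replicates (and
    charge states) are averaged first.  Peptides with zero exchangeable
    amides are skipped with a warning.  Returns ``None`` when no FD rows
    exist.
    """
    fd: dict[PeptideKey, list[float]] = {}
    for r in records:
        if r.is_fd_control and r.uptake_da is not None:
            fd.setdefault(PeptideKey(r.sequence, r.start, r.end), []).append(
                r.uptake_da
            )
    if not fd:
        return None
    per_peptide: dict[PeptideKey, float] = {}
    n_skipped = 0
    for key, vals in fd.items():
        max_up = exchangeable_amides(key.sequence, convention)
        if max_up == 0:
            n_skipped += 1
            logger.warning("peptide %s has no exchangeable amides; skipped", key)
            continue
        be = 100.0 * (1.0 - float(np.mean(vals)) / (max_up * d_fraction))
        per_peptide[key] = be
    if not per_peptide:
        return None
    values = np.array(list(per_peptide.values()))
    return BackExchange(
        per_peptide=per_peptide,
        mean_pct=float(values.mean()),
        min_pct=float(values.min()),
        max_pct=float(values.max()),
        n_skipped=n_skipped,
    )


def build_summary(
    table: MatchedTable,
    raw_records: Iterable[PeptideRecord],
    protein_length: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    d_fraction: float = 1.0,
) -> list[SummaryStats]:
    """One :class:`SummaryStats` per state in the matched table.

    ``protein_length`` defaults to the maximal peptide end observed across
    all raw records.  The critical interval reported for a non-reference
    state is that of its default comparison against the reference; the
    reference row reports its own pooled SD with the interval marked n.d.
    """
    raw_records = list(raw_records)
    if protein_length is None:
        protein_length = max(r.end for r in raw_records)
    lengths = [k.length for k in table.peptides]
    coverage_pct, avg_red = coverage_and_redundancy(table.peptides, protein_length)
    out: list[SummaryStats] = []
    for state in table.states:
        pooled_sd, _ = _pooled_sd(table, state)
        if state == table.reference:
            ci = None
        else:
            ci = critical_interval(table, (table.reference, state), alpha).ci_da
        be = back_exchange(
            (r for r in raw_records if r.protein_state == state), d_fraction
        )
        out.append(
            SummaryStats(
                state=state,
                timepoints_s=list(table.timepoints_s),
                n_replicates=table.n_replicates[state],
                n_peptides=len(table.peptides),
                coverage_pct=coverage_pct,
                avg_peptide_length=float(np.mean(lengths)),
                avg_redundancy=avg_red,
                pooled_sd_da=pooled_sd,
                critical_interval_da=ci,
                avg_back_exchange_pct=be.mean_pct if be else None,
                back_exchange_range_pct=(be.min_pct, be.max_pct) if be else None,
            )
        )
    return out
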