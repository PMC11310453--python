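"""Plot suite for differential HDX-MS results.

All builders are pure functions of (results, color scheme, options) and
return a matplotlib Figure of fixed size, so identical inputs render
identical artifacts.  One :class:`ColorScheme` instance is shared by every
plot and by the PyMOL export: blue marks protection (significant dD < 0),
red marks deprotection (significant dD > 0), grey marks non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.figure import Figure

from .matching import MatchedTable, PeptideKey
from .stats import ComparisonResult, GlobalCriticalInterval

Mode = Literal["all", "significant_only"]


@dataclass(frozen=True)
class ColorScheme:
    """Shared colors: protection blue, deprotection red, n.s. grey."""

    protect_color: str = "#2166ac"
    deprotect_color: str = "#b2182b"
    ns_color: str = "#9b9b9b"
    timepoint_palette: tuple[str, ...] = (
        "#fdd49e", "#fc8d59", "#d7301f", "#7f0000",
        "#54278f", "#2171b5", "#238b45", "#525252",
    )
    gradient: str = "RdBu_r"

    def point_color(self, delta_d: float, significant: bool) -> str:
        if not significant:
            return self.ns_color
        return self.deprotect_color if delta_d > 0 else self.protect_color


DEFAULT_SCHEME = ColorScheme()

_FIGSIZE = (7.0, 4.5)


@dataclass
class ResidueMatrix:
    """Residue x column matrix of mean dD; NaN marks uncovered residues.

    Columns are timepoints (time-course mode) or test states (multi-state
    mode).  NaN keeps uncovered residues distinguishable from dD = 0.
    """

    residues: np.ndarray  # 1..L
    columns: list
    values: np.ndarray  # shape (L, n_cols), NaN = uncovered

    @property
    def protein_length(self) -> int:
        return len(self.residues)


def residue_matrix(
    results: Iterable[ComparisonResult],
    mode: Mode = "all",
    protein_length: int | None = None,
    axis: Literal["timepoints", "comparisons"] = "timepoints",
) -> ResidueMatrix:
    """Aggregate peptide-level dD onto residues by unweighted mean.

    ``mode="significant_only"`` restricts to peptides flagged by the hybrid
    test; residues covered by no qualifying peptide are NaN.
    """
    results = list(results)
    if protein_length is None:
        protein_length = max((r.peptide.end for r in results), default=0)
    if axis == "timepoints":
        columns = sorted({r.timepoint_s for r in results})
        col_of = lambda r: r.timepoint_s
    else:
        columns = sorted({r.comparison[1] for r in results})
        col_of = lambda r: r.comparison[1]
    sums = np.zeros((protein_length, len(columns)))
    counts = np.zeros((protein_length, len(columns)), dtype=int)
    col_idx = {c: j for j, c in enumerate(columns)}
    for r in results:
        if mode == "significant_only" and not r.significant:
            continue
        j = col_idx[col_of(r)]
        sums[r.peptide.start - 1 : r.peptide.end, j] += r.delta_d
        counts[r.peptide.start - 1 : r.peptide.end, j] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ResidueMatrix(
        residues=np.arange(1, protein_length + 1), columns=columns, values=values
    )


def volcano_plot(
    results: Iterable[ComparisonResult],
    ci: GlobalCriticalInterval,
    alpha: float,
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> Figure:
    """dD vs -log10(p) with the hybrid-test guides at +-ci and alpha."""
    results = list(results)
    if not results:
        raise ValueError("no results to plot")
    tiny = np.finfo(float).tiny
    x = np.array([r.delta_d for r in results])
    y = -np.log10(np.maximum([r.p_value for r in results], tiny))
    colors = [scheme.point_color(r.delta_d, r.significant) for r in results]
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ax.scatter(x, y, c=colors, s=18, edgecolors="none", zorder=3)
    for guide in (-ci.ci_da, ci.ci_da):
        ax.axvline(guide, color="0.3", ls="--", lw=0.8)
    ax.axhline(-np.log10(alpha), color="0.3", ls="--", lw=0.8)
    ax.set_xlabel(r"$\Delta$D (Da), test $-$ reference")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{ci.comparison[1]} vs {ci.comparison[0]}")
    return fig


def woods_plot(
    results: Iterable[ComparisonResult],
    timepoint: float,
    mode: Mode = "all",
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> Figure:
    """Horizontal peptide segments at height dD over residue coordinates."""
    results = [r for r in results if r.timepoint_s == timepoint]
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ci = results[0].ci_da if results else 0.0
    ax.axhspan(-ci, ci, color="0.92", zorder=0)
    ax.axhline(0.0, color="0.4", lw=0.6)
    for r in results:
        if mode == "significant_only" and not r.significant:
            continue
        ax.hlines(
            r.delta_d,
            r.peptide.start,
            r.peptide.end,
            colors=scheme.point_color(r.delta_d, r.significant),
            lw=2.0,
        )
    ax.set_xlabel("Residue")
    ax.set_ylabel(r"$\Delta$D (Da)")
    ax.set_title(f"t = {timepoint:g} s")
    return fig


def robot_plot(
    results: Iterable[ComparisonResult],
    table: MatchedTable,
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> Figure:
    """Mirrored percent-deuteration plot for one two-state comparison.

    The x-axis is residue number; the reference state is drawn on the
    positive y-axis and the test state mirrored below.  A peptide appears
    only if the hybrid test flags it at >= 1 timepoint.  Each included
    peptide contributes, per timepoint, a horizontal bar over its residue
    span at its mean %D, a vertical bar of +-SD at the midpoint, and a
    midpoint dot colored by the timepoint palette when that timepoint is
    significant, grey otherwise.
    """
    results = list(results)
    comparisons = {r.comparison for r in results}
    if len(comparisons) != 1:
        raise ValueError(
            "robot_plot draws one comparison (two states); call it once per "
            "comparison"
        )
    (ref, test) = comparisons.pop()
    sig_any = {r.peptide for r in results if r.significant}
    by_pep: dict[PeptideKey, dict[float, ComparisonResult]] = {}
    for r in results:
        by_pep.setdefault(r.peptide, {})[r.timepoint_s] = r
    timepoints = sorted(table.timepoints_s)
    tp_color = {
        tp: scheme.timepoint_palette[i % len(scheme.timepoint_palette)]
        for i, tp in enumerate(timepoints)
    }
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    for pep in sorted(sig_any, key=lambda k: (k.start, k.end)):
        mid = 0.5 * (pep.start + pep.end)
        for tp in timepoints:
            r = by_pep.get(pep, {}).get(tp)
            if r is None:
                continue
            for state, sign in ((ref, +1.0), (test, -1.0)):
                pc = table.percent_values(pep, state, tp)
                if len(pc) == 0:
                    continue
                mean_pc = float(np.mean(pc)) * sign
                sd_pc = float(np.std(pc, ddof=1)) if len(pc) > 1 else 0.0
                ax.hlines(mean_pc, pep.start, pep.end,
                          colors=tp_color[tp], lw=1.4)
                ax.vlines(mid, mean_pc - sd_pc, mean_pc + sd_pc,
                          colors=tp_color[tp], lw=0.9)
                dot = tp_color[tp] if r.significant else scheme.ns_color
                ax.plot(mid, mean_pc, "o", color=dot, ms=4, zorder=3)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("Residue")
    ax.set_ylabel(f"% deuteration  ({test} below, {ref} above)")
    ax.set_title(f"{test} vs {ref}")
    return fig


def pack_intervals(spans: Sequence[tuple[int, int]]) -> list[int]:
    """First-fit greedy packing of [start, end] spans into non-overlapping
    rows, scanning spans ordered by start.  Returns a row index per span (in
    the order given)."""
    order = sorted(range(len(spans)), key=lambda i: (spans[i][0], spans[i][1]))
    row_ends: list[int] = []
    assignment = [0] * len(spans)
    for i in order:
        s, e = spans[i]
        for j, end in enumerate(row_ends):
            if s > end:
                row_ends[j] = e
                assignment[i] = j
                break
        else:
            row_ends.append(e)
            assignment[i] = len(row_ends) - 1
    return assignment


def significant_peptide_map(
    results: Iterable[ComparisonResult],
    timepoint: float,
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> Figure:
    """Stacked coverage map at one timepoint, colored by significance."""
    results = [r for r in results if r.timepoint_s == timepoint]
    spans = [(r.peptide.start, r.peptide.end) for r in results]
    rows = pack_intervals(spans)
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    for r, row in zip(results, rows):
        ax.hlines(
            -row,
            r.peptide.start,
            r.peptide.end,
            colors=scheme.point_color(r.delta_d, r.significant),
            lw=4.0,
        )
    ax.set_yticks([])
    ax.set_xlabel("Residue")
    ax.set_title(f"Peptide map, t = {timepoint:g} s")
    return fig


def heatmap(
    matrix: ResidueMatrix, scheme: ColorScheme = DEFAULT_SCHEME
) -> Figure:
    """Residue-level dD heatmap; uncovered residues hatched out."""
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    vmax = np.nanmax(np.abs(matrix.values)) if np.isfinite(matrix.values).any() else 1.0
    vmax = vmax or 1.0
    cmap = plt.get_cmap(scheme.gradient).copy()
    cmap.set_bad("0.85")
    im = ax.imshow(
        matrix.values.T,
        aspect="auto",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        extent=(0.5, matrix.protein_length + 0.5, len(matrix.columns) - 0.5, -0.5),
        interpolation="nearest",
    )
    ax.set_yticks(range(len(matrix.columns)))
    ax.set_yticklabels([str(c) for c in matrix.columns])
    ax.set_xlabel("Residue")
    fig.colorbar(im, ax=ax, label=r"mean $\Delta$D (Da)")
    return fig


def uptake_plot(
    table: MatchedTable,
    peptide: PeptideKey,
    scheme: ColorScheme = DEFAULT_SCHEME,
) -> Figure:
    """Mean uptake vs log exposure per state, error bars = replicate SD."""
    if peptide not in table.peptides:
        raise ValueError(f"peptide {peptide} not in matched table")
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    for state in table.states:
        means, sds = [], []
        for tp in table.timepoints_s:
            vals = table.uptake_values(peptide, state, tp)
            means.append(float(np.mean(vals)))
            sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        ax.errorbar(
            table.timepoints_s, means, yerr=sds, marker="o", ms=4,
            capsize=2, label=state,
        )
    ax.set_xscale("log")
    ax.set_xlabel("Exposure (s)")
    ax.set_ylabel("Uptake (Da)")
    ax.set_title(f"{peptide.sequence} ({peptide.start}-{peptide.end})")
    ax.legend(fontsize=8)
    return fig
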