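"""PyMOL command-script generation.

Residue-level coloring scripts let the differential results be painted onto
an already-loaded structure.  Scripts are self-contained (custom colors are
defined with ``set_color`` before use), contain only ASCII, and include no
``load`` line or absolute paths — the user applies them to their open
session.  Coloring is per residue via a :class:`~hdxdiff.plots.ResidueMatrix`
so overlapping peptides resolve deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import matplotlib

from .plots import ColorScheme, DEFAULT_SCHEME, ResidueMatrix

Mode = Literal["significant_only", "gradient"]

NEUTRAL_RGB = (0.82, 0.82, 0.82)


@dataclass(frozen=True)
class PymolScript:
    lines: tuple[str, ...]
    comparison: tuple[str, str] | None
    timepoint_s: float | None
    mode: Mode

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.text)


def merge_ranges(residues: Iterable[int]) -> list[tuple[int, int]]:
    """Collapse residue indices into maximal runs of consecutive integers."""
    out: list[tuple[int, int]] = []
    for r in sorted(set(residues)):
        if out and r == out[-1][1] + 1:
            out[-1] = (out[-1][0], r)
        else:
            out.append((r, r))
    return out


def _resi_selection(ranges: Sequence[tuple[int, int]], chain: str | None) -> str:
    parts = [f"{a}-{b}" if a != b else f"{a}" for a, b in ranges]
    sel = f"resi {'+'.join(parts)}"
    if chain:
        sel = f"chain {chain} and {sel}"
    return sel


def parse_resi_ranges(selection: str) -> set[int]:
    """Inverse of :func:`_resi_selection`: residue set from a resi token."""
    body = selection.split("resi", 1)[1].strip()
    out: set[int] = set()
    for part in body.split("+"):
        if "-" in part[1:]:
            a, b = part.rsplit("-", 1)
            out.update(range(int(a), int(b) + 1))
        else:
            out.add(int(part))
    return out


def _rgb(color: str) -> tuple[float, float, float]:
    return matplotlib.colors.to_rgb(color)


def _set_color(name: str, rgb: tuple[float, float, float]) -> str:
    return f"set_color {name}, [{rgb[0]:.4f}, {rgb[1]:.4f}, {rgb[2]:.4f}]"


def pymol_script(
    matrix: ResidueMatrix,
    scheme: ColorScheme = DEFAULT_SCHEME,
    mode: Mode = "significant_only",
    column: int = 0,
    chain: str | None = None,
    residue_offset: int = 0,
) -> PymolScript:
    """Build a coloring script from one column of a residue matrix.

    ``significant_only``: residues with dD < 0 get the protection color,
    dD > 0 the deprotection color, everything else neutral (build the matrix
    with ``mode="significant_only"`` so only flagged peptides contribute).
    ``gradient``: every covered residue gets its own color from the
    diverging map, scaled symmetrically to the largest |dD|.
    ``residue_offset`` shifts indices to match the structure's numbering.
    """
    values = matrix.values[:, column]
    residues = matrix.residues + residue_offset
    lines = [
        "# hdxdiff PyMOL coloring script",
        f"# mode: {mode}",
        _set_color("hdx_neutral", NEUTRAL_RGB),
        f"color hdx_neutral, {'chain ' + chain if chain else 'polymer'}",
    ]
    covered = ~np.isnan(values)
    if mode == "significant_only":
        lines.append(_set_color("hdx_protect", _rgb(scheme.protect_color)))
        lines.append(_set_color("hdx_deprotect", _rgb(scheme.deprotect_color)))
        protect = residues[covered & (values < 0)]
        deprotect = residues[covered & (values > 0)]
        if len(protect) == 0 and len(deprotect) == 0:
            lines.append("# zero significant residues")
        for name, resis in (("hdx_protect", protect), ("hdx_deprotect", deprotect)):
            if len(resis):
                sel = _resi_selection(merge_ranges(resis), chain)
                lines.append(f"color {name}, {sel}")
    elif mode == "gradient":
        vmax = float(np.nanmax(np.abs(values))) if covered.any() else 1.0
        vmax = vmax or 1.0
        cmap = matplotlib.pyplot.get_cmap(scheme.gradient)
        if not covered.any():
            lines.append("# zero covered residues")
        for resi, v in zip(residues[covered], values[covered]):
            rgb = cmap(0.5 + 0.5 * v / vmax)[:3]
            name = f"hdx_r{resi}"
            lines.append(_set_color(name, rgb))
            lines.append(f"color {name}, {_resi_selection([(resi, resi)], chain)}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    text = "\n".join(lines)
    if not text.isascii():
        raise AssertionError("script must be ASCII")
    return PymolScript(lines=tuple(lines), comparison=None, timepoint_s=None, mode=mode)
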