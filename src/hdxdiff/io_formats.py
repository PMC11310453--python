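"""Reading and writing HDExaminer-style peptide-level deuterium-uptake tables.

Bottom-up HDX-MS pipelines export one row per peptide x charge state x
exposure time x replicate x protein state, carrying the peptide sequence,
its residue span, and the measured deuterium uptake (Da and/or percent
deuteration).  This module turns such long-format delimited text into
validated :class:`PeptideRecord` objects and writes every tabular output of
the pipeline: the matched-peptide CSV, the verbose per-peptide statistics
CSV, and the publication summary table.

Header spellings drift between software versions, so parsing goes through an
:class:`ExportDialect` that maps canonical field names onto the headers
actually present in the file.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: tokens in the exposure column that mark a fully-deuterated control row
_FD_TIME_TOKENS = {"fd", "full-d", "fulld", "max", "maxd"}

_TIME_UNIT_S = {"seconds": 1.0, "minutes": 60.0, "hours": 3600.0}


class FormatError(ValueError):
    """Input file header could not be resolved against the dialect."""


class EmptyInputError(ValueError):
    """No valid data rows were found in the input."""


@dataclass(frozen=True)
class PeptideRecord:
    """One measured peptide observation.

    Residue coordinates are 1-based and inclusive on both ends.  ``uptake_da``
    is deuterium uptake in Daltons; ``percent_d`` is percent deuteration.  At
    least one of the two must be present.  ``exposure_s`` is the deuterium
    exposure time in seconds (0 for the undeuterated control, ``inf`` for a
    fully-deuterated control row).
    """

    protein_state: str
    sequence: str
    start: int
    end: int
    exposure_s: float
    replicate: int
    uptake_da: float | None = None
    percent_d: float | None = None
    charge: int | None = None
    is_fd_control: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end}"
            )
        if self.uptake_da is None and self.percent_d is None:
            raise ValueError("need at least one of uptake_da / percent_d")
        if self.uptake_da is not None and self.uptake_da < 0:
            raise ValueError("uptake_da must be non-negative")
        if self.exposure_s < 0:
            raise ValueError("exposure_s must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based")


@dataclass(frozen=True)
class ExportDialect:
    """How to read a particular flavour of export file.

    ``column_name_map`` maps canonical field names (``protein_state``,
    ``sequence``, ``start``, ``end``, ``charge``, ``exposure``, ``replicate``,
    ``uptake_da``, ``percent_d``) to the header strings found in the file.
    Bare numeric exposure values are interpreted in ``time_unit``; suffixed
    tokens ("30s", "5m", "1h") always win.  State labels in
    ``fd_state_labels`` are treated as fully-deuterated controls, as are rows
    whose exposure field is an FD token ("FD", "MAX").
    """

    column_name_map: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_COLUMNS)
    )
    time_unit: str = "seconds"
    decimal_separator: str = "."
    fd_state_labels: frozenset[str] = frozenset({"FD", "Full-D", "MAX"})

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_UNIT_S:
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        headers = list(self.column_name_map.values())
        if len(set(h.lower() for h in headers)) != len(headers):
            raise ValueError("two canonical fields map to the same header")


_DEFAULT_COLUMNS = {
    "protein_state": "Protein State",
    "sequence": "Sequence",
    "start": "Start",
    "end": "End",
    "charge": "Charge",
    "exposure": "Deut Time",
    "replicate": "File",
    "uptake_da": "#D",
    "percent_d": "%D",
}

#: dialect matching HDExaminer v3 "all results" exports
DEFAULT_DIALECT = ExportDialect()

_REQUIRED = ("protein_state", "sequence", "start", "end", "exposure")

_TIME_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(s|sec|m|min|h|hr)?\s*$")
_UNIT_TO_S = {"s": 1.0, "sec": 1.0, "m": 60.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}


@dataclass
class ParseResult:
    """Parsed records plus row accounting for the skip rule."""

    records: list[PeptideRecord]
    n_rows: int
    n_skipped: int


def _parse_time(token: str, dialect: ExportDialect) -> float | None:
    """Exposure token to seconds; ``None`` marks a fully-deuterated row."""
    if token.strip().lower() in _FD_TIME_TOKENS:
        return None
    m = _TIME_RE.match(token.replace(dialect.decimal_separator, "."))
    if not m:
        raise ValueError(f"unparseable exposure {token!r}")
    value = float(m.group(1))
    unit = m.group(2)
    scale = _UNIT_TO_S[unit] if unit else _TIME_UNIT_S[dialect.time_unit]
    return value * scale


def _parse_float(token: str, dialect: ExportDialect) -> float | None:
    token = token.strip()
    if not token:
        return None
    return float(token.replace(dialect.decimal_separator, "."))


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get)  # type: ignore[arg-type]


def parse_export(
    path: str | Path, dialect: ExportDialect = DEFAULT_DIALECT
) -> ParseResult:
    """Read a long-format peptide export into validated records.

    Rows with unparseable numeric fields (or inconsistent sequence/span) are
    skipped and counted; the skip count is logged and returned in the
    :class:`ParseResult`.  Missing canonical columns raise
    :class:`FormatError`; zero valid rows raise :class:`EmptyInputError`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise EmptyInputError(f"{path}: empty file")
        fh.seek(0)
        reader = csv.reader(fh, delimiter=_sniff_delimiter(first))
        header = next(reader)
        col_idx = _resolve_header(header, dialect, path)
        records: list[PeptideRecord] = []
        n_rows = 0
        n_skipped = 0
        # fallback replicate enumeration when no replicate column resolves,
        # and label->index mapping when the column holds raw-file names
        counters: dict[tuple, int] = {}
        label_maps: dict[str, dict[str, int]] = {}
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            n_rows += 1
            try:
                records.append(
                    _row_to_record(row, col_idx, dialect, counters, label_maps)
                )
            except (ValueError, IndexError) as exc:
                n_skipped += 1
                logger.debug("skipping row %d: %s", n_rows, exc)
    if not records:
        raise EmptyInputError(f"{path}: no valid data rows ({n_skipped} skipped)")
    if n_skipped:
        logger.warning("%s: skipped %d of %d rows", path, n_skipped, n_rows)
    return ParseResult(records=records, n_rows=n_rows, n_skipped=n_skipped)


def _resolve_header(
    header: Sequence[str], dialect: ExportDialect, path: Path
) -> dict[str, int]:
    lower = {h.strip().lower(): i for i, h in enumerate(header)}
    col_idx: dict[str, int] = {}
    for canon, name in dialect.column_name_map.items():
        i = lower.get(name.strip().lower())
        if i is not None:
            col_idx[canon] = i
    missing = [c for c in _REQUIRED if c not in col_idx]
    if "uptake_da" not in col_idx and "percent_d" not in col_idx:
        missing.append("uptake_da|percent_d")
    if missing:
        raise FormatError(
            f"{path}: cannot resolve canonical columns {missing} "
            f"against header {list(header)}"
        )
    return col_idx


def _row_to_record(
    row: Sequence[str],
    col_idx: Mapping[str, int],
    dialect: ExportDialect,
    counters: dict[tuple, int],
    label_maps: dict[str, dict[str, int]],
) -> PeptideRecord:
    get = lambda c: row[col_idx[c]].strip() if c in col_idx else ""
    state = get("protein_state")
    sequence = get("sequence").upper()
    start = int(get("start"))
    end = int(get("end"))
    exposure = _parse_time(get("exposure"), dialect)
    is_fd = exposure is None or state in dialect.fd_state_labels
    exposure_s = math.inf if exposure is None else exposure

    charge_tok = get("charge")
    charge = int(float(charge_tok)) if charge_tok else None

    uptake = _parse_float(get("uptake_da"), dialect) if "uptake_da" in col_idx else None
    percent = _parse_float(get("percent_d"), dialect) if "percent_d" in col_idx else None
    if uptake is None and percent is None:
        raise ValueError("no uptake value")

    rep_tok = get("replicate")
    if rep_tok:
        try:
            replicate = int(rep_tok)
        except ValueError:
            # raw-file names: enumerate distinct labels per state in order seen
            labels = label_maps.setdefault(state, {})
            replicate = labels.setdefault(rep_tok, len(labels) + 1)
    else:
        key = (state, sequence, start, end, exposure_s, charge)
        counters[key] = counters.get(key, 0) + 1
        replicate = counters[key]

    return PeptideRecord(
        protein_state=state,
        sequence=sequence,
        start=start,
        end=end,
        exposure_s=exposure_s,
        replicate=replicate,
        uptake_da=uptake,
        percent_d=percent,
        charge=charge,
        is_fd_control=is_fd,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_matched_csv(table, path: str | Path, include_exposure: bool | None = None) -> None:
    """Write the matched-peptide table: one row per (peptide, timepoint).

    Columns are sequence, start, end, then per state x replicate the uptake
    values (states in comparison order, replicates ascending).  An
    ``Exposure (s)`` column is added when the table holds more than one
    timepoint so the file round-trips losslessly; for a single timepoint it
    is omitted by default.
    """
    if not table.peptides:
        raise ValueError("matched table is empty")
    path = Path(path)
    if include_exposure is None:
        include_exposure = len(table.timepoints_s) > 1
    header = ["Sequence", "Start", "End"]
    if include_exposure:
        header.append("Exposure (s)")
    for state in table.states:
        for r in range(1, table.n_replicates[state] + 1):
            header.append(f"{state}_rep{r}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for tp in table.timepoints_s:
            for key in table.peptides:
                row: list = [key.sequence, key.start, key.end]
                if include_exposure:
                    row.append(repr(tp))
                for state in table.states:
                    vals = table.uptake_values(key, state, tp)
                    n = table.n_replicates[state]
                    for r in range(n):
                        row.append(repr(float(vals[r])) if r < len(vals) else "")
                w.writerow(row)


def read_matched_csv(path: str | Path):
    """Inverse of :func:`write_matched_csv` (uptake values only)."""
    from .matching import MatchedTable, PeptideKey
    import numpy as np

    df = pd.read_csv(path)
    state_cols = [c for c in df.columns if "_rep" in c]
    states: list[str] = []
    reps: dict[str, int] = {}
    for c in state_cols:
        s, r = c.rsplit("_rep", 1)
        if s not in states:
            states.append(s)
        reps[s] = max(reps.get(s, 0), int(r))
    has_exp = "Exposure (s)" in df.columns
    uptake: dict = {}
    keys: list[PeptideKey] = []
    timepoints: set[float] = set()
    for _, row in df.iterrows():
        key = PeptideKey(str(row["Sequence"]), int(row["Start"]), int(row["End"]))
        tp = float(row["Exposure (s)"]) if has_exp else 0.0
        timepoints.add(tp)
        if key not in keys:
            keys.append(key)
        for s in states:
            vals = [
                float(row[f"{s}_rep{r}"])
                for r in range(1, reps[s] + 1)
                if not pd.isna(row.get(f"{s}_rep{r}"))
            ]
            uptake[(key, s, tp)] = np.asarray(vals)
    keys.sort(key=lambda k: (k.start, k.end, k.sequence))
    return MatchedTable(
        peptides=keys,
        states=states,
        timepoints_s=sorted(timepoints),
        uptake=uptake,
        percent={},
        n_replicates=reps,
    )


_VERBOSE_HEADER = [
    "Reference State",
    "Test State",
    "Sequence",
    "Start",
    "End",
    "Exposure (s)",
    "Mean Ref (Da)",
    "Mean Test (Da)",
    "Delta D (Da)",
    "SD Ref (Da)",
    "SD Test (Da)",
    "n Ref",
    "n Test",
    "t",
    "df",
    "p-value",
    "Critical Interval (Da)",
    "Significant",
]


def write_verbose_csv(results, path: str | Path) -> None:
    """Write per-peptide differential statistics, one row per
    (peptide, comparison, timepoint).  p-values keep >= 9 significant digits.
    """
    results = list(results)
    if not results:
        raise ValueError("no comparison results to write")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_VERBOSE_HEADER)
        for r in results:
            w.writerow(
                [
                    r.comparison[0],
                    r.comparison[1],
                    r.peptide.sequence,
                    r.peptide.start,
                    r.peptide.end,
                    repr(r.timepoint_s),
                    f"{r.mean_ref:.6f}",
                    f"{r.mean_test:.6f}",
                    f"{r.delta_d:.6f}",
                    f"{r.sd_ref:.6f}",
                    f"{r.sd_test:.6f}",
                    r.n_ref,
                    r.n_test,
                    f"{r.t_stat:.12g}",
                    f"{r.df:.12g}",
                    f"{r.p_value:.12g}",
                    f"{r.ci_da:.6f}",
                    r.significant,
                ]
            )


def read_verbose_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


_SUMMARY_ROWS = [
    ("Deuterium exposure times (s)", "timepoints"),
    ("Number of replicates", "n_replicates"),
    ("Number of peptides", "n_peptides"),
    ("Sequence coverage (%)", "coverage_pct"),
    ("Average peptide length", "avg_peptide_length"),
    ("Average redundancy", "avg_redundancy"),
    ("Pooled SD (Da)", "pooled_sd_da"),
    ("Critical interval (Da)", "critical_interval_da"),
    ("Average back exchange (%)", "avg_back_exchange_pct"),
    ("Back exchange range (%)", "back_exchange_range_pct"),
]


def publication_frame(summaries) -> pd.DataFrame:
    """Publication summary as a DataFrame: one column per state, one row per
    reported field; unavailable values rendered as ``n.d.``.
    """
    if not summaries:
        raise ValueError("no state summaries")
    cols: dict[str, list[str]] = {}
    for s in summaries:
        col = []
        for _, attr in _SUMMARY_ROWS:
            col.append(_fmt_summary_value(s, attr))
        cols[s.state] = col
    return pd.DataFrame(cols, index=[name for name, _ in _SUMMARY_ROWS])


def _fmt_summary_value(s, attr: str) -> str:
    if attr == "timepoints":
        return "; ".join(_fmt_num(t) for t in s.timepoints_s)
    v = getattr(s, attr)
    if v is None:
        return "n.d."
    if attr == "back_exchange_range_pct":
        return f"{v[0]:.1f}-{v[1]:.1f}"
    if isinstance(v, float):
        return f"{v:.3f}".rstrip("0").rstrip(".")
    return str(v)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def write_publication_table(summaries, path: str | Path, fmt: str = "csv") -> None:
    """Write the per-state publication summary table as CSV or XLSX."""
    df = publication_frame(summaries)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index_label="Parameter")
    elif fmt == "xlsx":
        df.to_excel(path, index_label="Parameter")
    else:
        raise ValueError(f"unknown format {fmt!r}")
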