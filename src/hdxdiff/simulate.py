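"""Synthetic HDX-MS exports with known ground truth.

The generator writes files in the same long format the parser reads, so
every stage of the pipeline can be exercised without any real instrument
data.  It emulates the standard differential experiment: several protein
states measured at a few exposure times in replicate, peptides tiling the
protein with overlapping 8-20-residue spans, saturating-exponential uptake
kinetics D(t) = max_uptake * (1 - exp(-k t)) with per-peptide rates, a
global back-exchange loss, optional fully-deuterated control rows, and
i.i.d. Gaussian replicate noise.  State effects are injected as additive
uptake shifts on chosen peptides, and the exact injected truth is returned
for assertions.

What it does not emulate: heteroscedastic or peptide-length-dependent
noise, EX1 bimodality, carry-over, or missing measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .matching import PeptideKey
from .summary import exchangeable_amides

_AA = "ACDEFGHIKLMNQRSTVWY"  # proline added separately

#: default exposure series (seconds); extended geometrically if more needed
_BASE_TIMEPOINTS = (30.0, 300.0, 3600.0, 14400.0)


@dataclass(frozen=True)
class Effect:
    """An injected uptake shift: +delta_da on one peptide in one state.

    ``timepoints_s=None`` applies the shift at every exposure time.
    """

    peptide_index: int
    state: str
    delta_da: float
    timepoints_s: tuple[float, ...] | None = None


@dataclass
class GeneratorConfig:
    """Study design for one synthetic export; the seed fixes everything."""

    n_states: int = 2
    n_timepoints: int = 4
    n_replicates: int = 3
    n_peptides: int = 100
    protein_length: int = 200
    effects: tuple[Effect, ...] = ()
    noise_sd_da: float = 0.05
    back_exchange_pct: float = 15.0
    d_fraction: float = 1.0
    include_fd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_states", "n_timepoints", "n_replicates", "n_peptides"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def states(self) -> list[str]:
        return [f"State{i + 1}" for i in range(self.n_states)]

    @property
    def timepoints_s(self) -> list[float]:
        tps = list(_BASE_TIMEPOINTS)
        while len(tps) < self.n_timepoints:
            tps.append(tps[-1] * 4.0)
        return tps[: self.n_timepoints]


@dataclass
class GroundTruth:
    """Noise-free truth behind a generated export."""

    peptides: list[PeptideKey]
    states: list[str]
    timepoints_s: list[float]
    true_mean_da: dict[tuple[PeptideKey, str, float], float]
    effects: tuple[Effect, ...]
    effect_peptides: dict[str, set[PeptideKey]]  # per state, peptides with an effect
    max_uptake: dict[PeptideKey, int]


def _make_protein(rng: np.random.Generator, length: int) -> str:
    aas = rng.choice(list(_AA), size=length)
    # sprinkle prolines at ~5% so exchangeable-amide counts vary
    pro = rng.random(length) < 0.05
    return "".join("P" if p else a for a, p in zip(aas, pro))


def _make_peptides(
    rng: np.random.Generator, protein: str, n_peptides: int
) -> list[PeptideKey]:
    length = len(protein)
    keys: list[PeptideKey] = []
    seen: set[tuple[int, int]] = set()
    start = 1
    while len(keys) < n_peptides:
        span = int(rng.integers(8, 21))
        if start + span - 1 > length:
            start = int(rng.integers(1, 6))
        end = start + span - 1
        if (start, end) not in seen:
            seen.add((start, end))
            keys.append(PeptideKey(protein[start - 1 : end], start, end))
        start += int(rng.integers(3, 9))
    return keys


def generate_truth(config: GeneratorConfig) -> GroundTruth:
    """Peptide map, kinetics and injected effects, without noise."""
    rng = np.random.default_rng(config.seed)
    protein = _make_protein(rng, config.protein_length)
    peptides = _make_peptides(rng, protein, config.n_peptides)
    states = config.states
    timepoints = config.timepoints_s
    for e in config.effects:
        if not 0 <= e.peptide_index < len(peptides):
            raise ValueError(f"effect references absent peptide {e.peptide_index}")
        if e.state not in states:
            raise ValueError(f"effect references absent state {e.state!r}")

    max_up = {k: exchangeable_amides(k.sequence) for k in peptides}
    # per-peptide exchange rate, log-uniform over slow..fast
    log_k = rng.uniform(math.log(1e-4), math.log(1e-1), size=len(peptides))
    retain = 1.0 - config.back_exchange_pct / 100.0

    true_mean: dict[tuple[PeptideKey, str, float], float] = {}
    effect_peptides: dict[str, set[PeptideKey]] = {s: set() for s in states}
    for i, key in enumerate(peptides):
        k_rate = math.exp(log_k[i])
        for tp in timepoints:
            base = max_up[key] * config.d_fraction * (1.0 - math.exp(-k_rate * tp))
            base *= retain
            for state in states:
                true_mean[(key, state, tp)] = base
    for e in config.effects:
        key = peptides[e.peptide_index]
        tps = e.timepoints_s if e.timepoints_s is not None else tuple(timepoints)
        for tp in tps:
            true_mean[(key, e.state, tp)] += e.delta_da
        effect_peptides[e.state].add(key)
    return GroundTruth(
        peptides=peptides,
        states=states,
        timepoints_s=timepoints,
        true_mean_da=true_mean,
        effects=config.effects,
        effect_peptides=effect_peptides,
        max_uptake=max_up,
    )


def generate_rows(config: GeneratorConfig) -> tuple[list[list[str]], GroundTruth]:
    """Export rows (default dialect column order) plus the ground truth."""
    truth = generate_truth(config)
    rng = np.random.default_rng(config.seed + 1)  # noise stream, independent of map
    retain = 1.0 - config.back_exchange_pct / 100.0
    rows: list[list[str]] = []
    charges = {
        k: int(rng.integers(1, 5)) for k in truth.peptides
    }
    for state in truth.states:
        for key in truth.peptides:
            max_d = truth.max_uptake[key] * config.d_fraction
            for tp in truth.timepoints_s:
                mean = truth.true_mean_da[(key, state, tp)]
                for rep in range(1, config.n_replicates + 1):
                    up = mean + rng.normal(0.0, config.noise_sd_da)
                    up = max(up, 0.0)
                    pct = 100.0 * up / max_d if max_d > 0 else 0.0
                    rows.append(
                        _row(state, tp, rep, key, charges[key], up, pct)
                    )
            if config.include_fd:
                for rep in range(1, config.n_replicates + 1):
                    up = max_d * retain + rng.normal(0.0, config.noise_sd_da)
                    up = max(up, 0.0)
                    pct = 100.0 * up / max_d if max_d > 0 else 0.0
                    rows.append(
                        _row(state, None, rep, key, charges[key], up, pct)
                    )
    return rows, truth


def generate_records(config: GeneratorConfig):
    """Like :func:`generate_export` but return records directly.

    Values go through the same text formatting as the file writer, so the
    records are identical to parsing a written export.
    """
    from .io_formats import PeptideRecord

    rows, truth = generate_rows(config)
    records = []
    for state, tp_tok, rep_tok, start, end, seq, charge, up, pct in rows:
        is_fd = tp_tok == "FD"
        records.append(
            PeptideRecord(
                protein_state=state,
                sequence=seq,
                start=int(start),
                end=int(end),
                exposure_s=math.inf if is_fd else float(tp_tok[:-1]),
                replicate=int(rep_tok[3:5]),
                uptake_da=float(up),
                percent_d=float(pct),
                charge=int(charge),
                is_fd_control=is_fd,
            )
        )
    return records, truth


def _fmt_time(tp: float | None) -> str:
    if tp is None:
        return "FD"
    if tp == int(tp):
        return f"{int(tp)}s"
    return f"{tp:g}s"


def _row(state, tp, rep, key: PeptideKey, charge, up, pct) -> list[str]:
    return [
        state,
        _fmt_time(tp),
        f"rep{rep:02d}.raw",
        str(key.start),
        str(key.end),
        key.sequence,
        str(charge),
        f"{up:.5f}",
        f"{pct:.5f}",
    ]


_HEADER = [
    "Protein State",
    "Deut Time",
    "File",
    "Start",
    "End",
    "Sequence",
    "Charge",
    "#D",
    "%D",
]


def generate_export(
    config: GeneratorConfig, path: str | Path
) -> GroundTruth:
    """Write a synthetic export file; returns the ground truth.

    The same config (same seed) always produces a byte-identical file.
    """
    rows, truth = generate_rows(config)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(_HEADER) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    return truth
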