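# hdxdiff

Differential analysis of hydrogen–deuterium exchange mass spectrometry
(HDX-MS) experiments. `hdxdiff` ingests peptide-level deuterium-uptake
exports (HDExaminer-style long-format tables: one row per peptide × charge
state × exposure time × replicate × protein state), matches peptides across
protein states, flags statistically significant uptake differences, and
produces publication-ready tables, plots, and PyMOL coloring scripts.

It is aimed at structural biologists running comparative HDX-MS — apo vs
ligand-bound, wild-type vs mutant, or many states at once — who need to go
from a raw export to "which peptides changed, where, and by how much"
without hand-rolled spreadsheets.

## The statistical model

For each non-reference state *s*, every matched peptide *i* at every
exposure time *t* is tested against the reference state with a **hybrid
criterion**: the peptide is significant only if it passes **both**

1. **Welch's t-test** on the replicate uptake values (Daltons):

   t = (x̄ₛ − x̄ᵣ) / √(s²ᵣ/nᵣ + s²ₛ/nₛ),

   with Welch–Satterthwaite degrees of freedom and a two-sided p-value;
   require p < α (default α = 0.01); and

2. the **global critical interval**: |ΔD| must exceed

   CI = t₁₋α/₂, nᵣ+nₛ−2 · √(σ²ᵣ/nᵣ + σ²ₛ/nₛ),

   where σ²ᵣ, σ²ₛ are the per-cell replicate variances pooled (averaged)
   over *all* peptides and timepoints of the comparison.

The t-test guards against large-but-noisy differences; the dataset-wide
interval guards against tiny-variance flukes and acts as the framework's
multiplicity control (no additional p-value correction is applied). ΔD is
signed test − reference: positive means more exchange (deprotection) in the
test state. With *k* states the pipeline runs *k* − 1 comparisons against
the first (or user-chosen) reference state.

The package also computes the standard per-state summary for publication —
timepoints, replicates, peptide count, sequence coverage, average peptide
length, redundancy, pooled SD, critical interval, and back exchange
(mean and range) from a fully-deuterated control — and renders volcano
plots, Woods plots, residue-level heatmaps, significant-peptide coverage
maps, per-peptide uptake curves, and mirrored "robot" plots of percent
deuteration, all with one shared color scheme that carries over to the
generated PyMOL scripts.

## Worked example

Generate a synthetic two-state export with a known +1.0 Da deprotection on
peptide 4, then analyze it:

```bash
hdxdiff fixtures --out demo.csv --n-states 2 --n-peptides 25 \
    --seed 11 --effect 4:State2:1.0
hdxdiff analyze --input demo.csv --output-dir demo_out
```

The analyze step logs:

```
INFO state State1: 0 peptides dropped in matching
INFO state State2: 0 peptides dropped in matching
INFO 1 comparisons, 100 tested cells, 4 significant
```

25 peptides × 4 timepoints = 100 tested cells; the 4 significant cells are
the injected peptide at each of its 4 timepoints — exactly the planted
ground truth. `demo_out/` then contains `matched.csv` (aligned replicate
uptake values), `verbose_State2.csv` (per-peptide means, SDs, ΔD, t, df, p,
critical interval, significance flag), `summary.csv` (the per-state
publication table), the plot suite as PNG, and `pymol_State2_*.pml`
scripts that color significant residues blue (protection) or red
(deprotection) on an open structure.

The same workflow is available as a library:

```python
from hdxdiff import parse_export, match_peptides, compare_states

records = parse_export("demo.csv").records
table = match_peptides(records)            # reference = first state
results, intervals = compare_states(table, alpha=0.01)
```

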