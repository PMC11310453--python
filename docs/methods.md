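# Methods

## Data model and input handling

The unit of observation is one peptide measured in one protein state at one
deuterium exposure time in one replicate (optionally per charge state).
Residue coordinates are 1-based and inclusive on both ends. Input files are
delimited text (comma or tab, auto-sniffed); header spellings are resolved
through an `ExportDialect` that maps canonical field names onto the headers
actually present, with a default map matching common HDExaminer v3
"all results" exports (`Protein State`, `Sequence`, `Start`, `End`,
`Charge`, `Deut Time`, `File`, `#D`, `%D`). Exposure tokens accept `30s`,
`5m`, `1h` suffixes; bare numbers are interpreted in the dialect's time
unit (default seconds). Rows whose numeric fields fail to parse, or whose
sequence length contradicts the residue span, are skipped and counted; the
skip count is logged and returned so a corrupt export cannot silently
shrink.

Three normalisations happen before matching:

- **Charge states.** Multiple charge-state rows of the same
  (state, peptide, exposure, replicate) observation are averaged into one
  value. Averaging rather than best-charge selection keeps the operation
  symmetric and order-free; it is confined to one helper if a different
  policy is ever needed.
- **Replicate identity.** An integer replicate column is used as-is; a
  raw-file-name column is enumerated to indices in order of first
  appearance per state; with no column at all, replicates are enumerated in
  file order within each (state, peptide, exposure, charge) group. The
  charge is included in that grouping key so charge-state rows of one
  replicate are not miscounted as extra replicates.
- **Controls.** Undeuterated (0 s) rows and fully-deuterated (FD) rows —
  marked by an `FD`/`MAX` exposure token or an FD state label — are kept
  for plotting and back-exchange calculation but excluded from the
  differential test set.

## Matching

Peptides are identified by (sequence, start, end); charge and retention
time are not part of the identity. The matched table is a strict
intersection: the shared timepoints are the exposure times present in every
state (exact equality after unit normalisation; an optional tolerance in
seconds exists for sloppy exports, default 0), and the matched peptides are
those observed in every state at every shared timepoint. Dropped-peptide
counts are reported per state, and an empty intersection raises an error
naming the state with the least overlap. The first state is the reference;
`reorder_reference` rotates any state to the front without touching
values. Unequal replicate counts across states are allowed — Welch's test
tolerates n₁ ≠ n₂ — but any cell with fewer than two replicates is excluded
from testing (variance needs n ≥ 2) while remaining available for plots.

## Hybrid significance test

Testing operates on uptake in Daltons (a single physical unit keeps the
variance pooling meaningful); percent deuteration is display-only. For each
comparison (reference, test):

1. Per state, the per-cell replicate variances (ddof = 1) are averaged over
   all (peptide, timepoint) cells and square-rooted to a pooled SD.
2. The critical interval is
   CI = t₁₋α/₂,df · sqrt(sd²_ref/n_ref + sd²_test/n_test) with
   df = n_ref + n_test − 2, where n are the per-state replicate counts.
3. Per (peptide, timepoint), Welch's t, the Welch–Satterthwaite df and the
   two-sided p-value are computed from the replicate means and SDs.
4. The cell is significant iff p < α **and** |ΔD| > CI.

Default α = 0.01 — a conservative level customary in differential HDX
work — and it is user-configurable everywhere. No multiple-testing
correction is applied on top: the global interval is the hybrid framework's
guard against multiplicity, and this is stated in the API documentation
rather than hidden. The degenerate case of zero variance in both groups is
defined by convention (p = 1 for equal means, p = 0 otherwise) and flagged
with a warning, so constant synthetic data does not crash the pipeline.
ΔD = mean_test − mean_ref throughout; swapping reference and test negates
ΔD and t and preserves p and the significance call (a tested invariant).

## Summary statistics

Coverage is the percentage of protein residues touched by ≥ 1 matched
peptide; redundancy is the mean per-residue peptide depth over *covered*
residues only (the conventional definition in HDX summary tables, hence
≥ 1 whenever coverage is nonzero). The protein length defaults to the
maximum peptide end observed, overridable in configuration. Back exchange
per peptide is BE% = 100·(1 − uptake_FD/(max_uptake·d_fraction)), where
d_fraction is the deuterium fraction of the labeling buffer (default 1.0)
and max_uptake counts exchangeable backbone amides as
L − 2 − (prolines at position > 2): the N-terminal residue has no backbone
amide and the second amide back-exchanges too fast to retain label. The
alternative L − 1 − P convention is available behind a flag. Peptides with
zero exchangeable amides are skipped with a warning. States without FD rows
report back exchange as "n.d." (absent, never zero); the reference state
reports "n.d." for the critical interval because the interval is a property
of a comparison.

## Visualization and structure export

All plot builders are pure functions of (results, scheme, options) with
fixed figure sizes, so identical inputs render identical files. One
`ColorScheme` is shared: blue = protection (significant ΔD < 0),
red = deprotection (ΔD > 0), grey = non-significant, a diverging
blue–white–red gradient for heatmaps, and an ordered per-timepoint palette.
Residue-level displays aggregate overlapping peptides by unweighted mean
ΔD; uncovered residues are NaN, which keeps them distinguishable from
ΔD = 0 (rendered as a neutral "uncovered" tone). The robot plot draws, for
every peptide significant at ≥ 1 timepoint, mirrored percent-deuteration
bars (reference above the axis, test below) spanning the peptide's
residues, ±SD whiskers, and a midpoint dot per timepoint — colored by the
timepoint palette when that timepoint is significant, grey otherwise. Each
dot sits on its own timepoint trace; the vertical placement was a genuinely
open choice and per-trace placement preserves per-timepoint readability.
The significant-peptide map stacks segments by greedy first-fit interval
packing ordered by start. PyMOL scripts color by residue (via the residue
matrix, so peptide overlaps resolve deterministically), merge consecutive
residues into minimal `resi a-b` ranges, define every custom color before
use, are pure ASCII, and contain no `load` line or paths — the user applies
them to an open session. A chain selector and an integer residue-number
offset are the only structure-mapping knobs.

## Synthetic data generator

The generator emulates the standard differential experiment at the scale
the pipeline is designed for (it is exercised up to eight states × four
timepoints × four replicates). Defaults model a routine two-state
comparison: 100 peptides of 8–20 residues tiling a 200-residue random
protein (~5% proline), exposure times 30/300/3600/14400 s, three
replicates, Gaussian i.i.d. replicate noise with SD 0.05 Da (a typical
replicate repeatability for peptide-level uptake), 15% uniform back
exchange, and FD control rows. Uptake follows saturating-exponential
kinetics D(t) = max_uptake·(1 − e^(−kt)) with per-peptide rate k
log-uniform in [10⁻⁴, 10⁻¹] s⁻¹, spanning fast-exchanging loops to
well-protected cores across the measured window. State effects are
injected as additive Da shifts on chosen peptides (optionally restricted to
chosen timepoints) and the exact noise-free truth is returned for
assertions. The seed fully determines the output down to the byte.

Deliberately not modelled: heteroscedastic or length-dependent noise, EX1
bimodality, missing cells, retention-time drift, and inter-day batch
effects. Passing tests therefore demonstrate correctness of the statistics
and bookkeeping under the stated noise model, not robustness to every
pathology of real instrument data.

## Numerical and testing choices

Problem sizes in the test suite and the acceptance script are chosen to
exercise the full tested capacity while keeping runs quick: the capacity
run uses 50 peptides across 8 states; type-I calibration uses 50 seeds of
200 null peptides × 4 timepoints (40 000 tested cells); recovery uses 20
seeds of 100 peptides with five +1.0 Da effects. The type-I check bounds
the flagged fraction by α + 3·sqrt(α(1−α)/N); the hybrid AND of two
criteria is strongly conservative relative to α, and the observed rate is
near zero. Effect estimates are checked against the injected shift within
3·noise_SD·sqrt(2/n). Welch's statistics are verified to 10⁻¹⁰ relative
against an independently coded textbook evaluation and scipy's
summary-statistics test. CSV writers serialize test statistics with 12
significant digits so re-parsed p-values agree to better than 10⁻⁹
relative; matched-table uptake values are written with full `repr`
precision and round-trip bitwise.

## Known limitations

- The critical interval uses the per-state replicate counts with
  df = n_ref + n_test − 2; with grossly unbalanced designs a
  Welch-style df for the interval might be preferable.
- Timepoint matching is exact by default; exports that label the same
  exposure inconsistently need the tolerance knob.
- Back exchange assumes a single global d_fraction; per-timepoint buffer
  differences are out of scope.
- The publication table fixes states as columns; transposed layouts are a
  rendering concern left to the caller.
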