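# Methods

This note documents the models and procedures implemented in `loopdiff`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-data generator does and does not
establish.

## Coordinate and matrix conventions

All coordinates are 0-based half-open, in base pairs, everywhere
(internally and in BED-style I/O).  A genomic position maps to bin
`floor(start / bin_size)`; the default bin size is 40 kb.  Contact
matrices are intra-chromosomal only — inter-chromosomal triplets are
dropped on read with a logged count, since every downstream analysis
(TADs, promoter–distal loops) is intra-chromosomal — and only the upper
triangle is stored.  Counts may be real-valued (balanced/ICE matrices)
for normalization and diagnostics; down-sampling demands raw integer
counts and rejects anything else.  The library-wide total valid-pair
count rides along with the matrix (sidecar stats key
`valid_interaction_rmdup`, else the sum of counts) because it is the
denominator of the VPPM statistic.

## LOWESS inter-sample normalization

When one of the two compared libraries comes from a different study or
batch, its contact decay can differ systematically.  The correction
models the bias as a smooth function of genomic distance only: for every
position stored in either matrix, M = log2((target + c)/(reference + c))
with pseudocount c (default 1.0) is regressed on log10(distance) by
LOWESS (statsmodels), pooled across chromosomes.  Distance is the
dominant covariate of Hi-C signal and pooling stabilizes the sparse
far-diagonal strata; both the smoothing fraction (default 0.3) and the
pseudocount are exposed in the config.  Correction divides each count by
2^curve(d) with linear interpolation between grid points and constant
extrapolation beyond (diagonal entries, distance 0, take the near-end
value; they are excluded from the fit).  The totals are left untouched —
the correction reshapes the distance profile, it does not re-estimate
library size.

Verified properties: self-comparison is flat to 1e-6; an injected
constant 0.5-log2 bias is recovered within ±0.02; after one correction a
refit is flat to 0.05; for smooth biases bounded by 1 log2 unit the
median absolute curve error stays within 0.05.  A LOWESS `delta`
parameter (0.5% of the x-range) keeps the fit linear-time without
changing the pooled-fit semantics.

Down-sampling retains each valid pair independently with probability f
(binomial thinning per entry, plus a thinned draw of the library pairs
not present in the matrix), so depth-robustness checks — e.g. that TAD
structure and the decay profile survive 50% thinning — are one function
call.

## Eight-type TAD-change classification

Inputs are two three-state tilings (`tad`/`boundary`/`gap`); uncovered
space counts as gap.  TADs of the two conditions are joined by ≥1 bp
overlap (configurable) into bipartite components; the component is the
unit of counting, and every TAD of either condition lands in exactly one
event.

* Unmatched B-TAD → **neo**; unmatched A-TAD → **del**.
* 1-to-many → **split**; many-to-1 → **fuse**.
* Many-to-many components are decomposed greedily into stars: edges by
  decreasing overlap (leftmost tie-break, invariant under swapping the
  conditions), a new sub-event per edge with two free ends, a free end
  joining an existing sub-event only while the joined side is still a
  singleton.  TADs left over become singleton neo/del sub-events.
* 1-to-1: **no change** if both boundary displacements are within the
  identity tolerance (default one bin, 40 kb — TopDom boundaries are
  bin-quantized, so exact equality would be an accident of rounding);
  otherwise **conserve-expand**/**conserve-shrink** if the length change
  is nonzero and both |Δlength| and the maximum boundary displacement
  are ≤ 300 kb; otherwise **shift**.

Two taxonomy gaps had to be closed by decision.  A 1-1 match moving by
more than 300 kb in length is classified shift (the conserve types are
explicitly bounded).  A pure translation — zero length change but
displacement beyond tolerance — is also classified shift regardless of
magnitude: it is literally a position shift, and assigning it to either
conserve type would break the A/B-swap anti-symmetry (swap maps
neo↔del, split↔fuse, expand↔shrink, and fixes no-change/shift), which
the suite verifies on random instances alongside exact equivalence with
a brute-force reference classifier.

RC = no change + conserve-expand + conserve-shrink; DC = the rest.
Summaries report counts, fractions (over events) and the RC/DC split.

## P1D1 loops and VPPM

Promoter window: 4 kb upstream to 1 kb downstream of the 5'TSS,
following transcription direction ("upstream" is strand-aware — the
standard reading, though conventions differ); distal windows: 10–100 kb
up- and downstream, likewise strand-aware; all windows clipped to
chromosome bounds.  An anchor takes every (gene, role) with ≥1 bp window
overlap, and promoter priority then discards **all** distal roles of an
anchor that touches any promoter — including competing promoter roles of
other genes, which are kept.  A SIF becomes one loop per gene for which
one anchor is promoter and the other distal of that same gene.  SIFs are
pre-filtered at FDR ≤ 0.1 (inclusive).

VPPM = valid pairs in the loop / library total valid pairs × 10⁶;
per-gene strength is the sum over the gene's loops.  Loop identity
across samples, used for the unique/common partition, is (gene id, ≥1 bp
distal-anchor overlap) — restriction-fragment identity is not assumed
available.  Strength comparisons between partition classes use
two-sided Wilcoxon rank-sum tests on gene-level VPPM sums.

## Strengthened looping genes

Over the union of looping genes (absent gene → VPPM 0), diff = VPPM_B −
VPPM_A.  The published recipe — z-score, then "normalize into [0, 1]" —
is internally inconsistent (z-scores are unbounded), so the
implementation z-scores the diffs and min–max scales within the
positive-diff subset, thresholding the scaled score at 0.15 (default)
for condition-B SLGs; condition-A SLGs run the identical procedure on
the negated diffs, so swapping the input tables swaps the two sets
exactly and no gene can be strengthened in both conditions.  Because
min–max scaling within a sign subset is invariant to affine transforms,
z-scoring jointly versus per sign yields identical scores; both policy
names are accepted and share one code path, and the z-step survives as
the degenerate-input guard (zero variance of diffs → error, no SLGs
definable).  Note the consequence of a relative cutoff: when one
condition carries no true signal, the top of its noise tail still
scores above 0.15, so SLG counts in a null condition are not a false
-positive rate on any absolute scale.

DEGs are genes with |log2FC| ≥ 0.58 and p ≤ 0.05, both inclusive, on the
supplied table (raw p by default; the model is never refit here).  DELGs
are the per-condition intersection SLG ∩ DEG.

## Synthetic scenarios

The generator emits every input dialect with an answer key
(`truth.json`).  The stated world: one 20 Mb chromosome, 40 kb bins,
TADs of median 800 kb (log-normal, σ = 0.4, clipped to 0.48–2 Mb)
separated by 400 kb spacers, 60 genes at ≥250 kb spacing on both
strands, depth 2×10⁶ valid pairs, decay exponent α = 1 with 3× within-TAD
enrichment and Poisson counts, one planted event of each non-trivial
change type, 5% of genes loop-strengthened 5× in condition B, 30% of
genes differentially expressed.  Poisson (not negative-binomial) noise
is deliberate: it suffices to exercise the downstream logic, and the
noise model is localized for replacement.

Design points worth knowing:

* **Spacers are 400 kb** so every planted change stays within its own
  TAD-plus-spacer envelope: expansion/shrinkage moves a boundary 80 kb,
  shifts move 360 kb, neo TADs sit one bin inside a spacer following an
  untouched TAD.  Events are therefore unambiguous under the 300 kb
  rules, and the classifier must recover the planted multiset exactly —
  at 20 Mb this yields ~13–16 TADs; scenarios planting more events scale
  `chrom_length` up rather than packing events closer.
* **Loop strength is a per-gene budget.**  The log-normal draw (median
  100 pairs, σ = 0.35) is the gene's total, divided over its 1 + Poisson(0.8)
  loops, so the planted 5× effect acts on the gene-level VPPM
  regardless of loop count and the planted SLG set is recoverable at the
  0.15 cutoff with zero false positives.
* **Decoy SIFs** (distal–distal, cross-gene promoter–promoter, and
  anchors in the window-free zone ≥100 kb from any TSS, guaranteed to
  exist by the 250 kb gene spacing) carry FDR ~ U[0, 1] and must never
  produce loops; planted loops carry FDR ~ U[0, 0.1] and all survive the
  filter.
* **DEG truth is exact by construction**: null genes fail at least one
  criterion (|lfc| truncated below 0.58, or p strictly above 0.05), so
  the filter must return exactly the planted set.
* `frac_condition_unique` (default 0) moves a fraction of
  non-strengthened loops into a single condition for unique/common
  partition studies; it is off by default so the strengthened-gene truth
  set stays exact.

What a green closed-loop test does **not** establish: robustness to real
Hi-C artifacts (fragment-level bias, trans contacts, copy-number
effects), to TAD callers' disagreements, or to interaction callers'
FDR calibration — those tools are upstream of this package and consumed
as given.  The generator's FDR values are labels, not outputs of a
fitted model.

## Determinism

Every stochastic operation takes an explicit seed; the generator derives
independent child streams per module from the scenario seed.  Identical
configs produce byte-identical emitted files and reports (no timestamps
in data outputs), which the suite checks end to end.
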