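# loopdiff

Differential analysis of chromatin architecture between two conditions
from processed Hi-C data — e.g. the same cancer cell line grown as a 2D
monolayer versus a 3D spheroid, or a parental versus a drug-resistant
line.

Starting from binned contact matrices (HiC-Pro dialect), three-state
TAD calls (TopDom-style `domain`/`boundary`/`gap` tilings), significant
interaction fragments (SIFs) and a differential-expression table, the
package answers three questions:

1. **How did the domain landscape change?**  TADs of the two conditions
   are matched by overlap and every matched component is classified into
   one of eight change types — no change, conserve-expand,
   conserve-shrink (together "relatively conserved", RC), and shift,
   split, fuse, neo, del ("drastically changed", DC) — using a 300 kb
   bound on conserved length change and boundary displacement.
2. **Which genes changed their promoter–distal looping?**  A SIF whose
   anchors fall in a gene's promoter window (−4 kb/+1 kb of the 5'TSS)
   and a distal window (10–100 kb from the 5'TSS) of the *same* gene is a
   P1D1 loop.  Loop strength is Valid Pairs Per Million,

   VPPM = (valid pairs in loop) / (library total valid pairs) × 10⁶,

   summed per gene.  Per-gene VPPM differences between conditions are
   z-scored, min–max scaled to [0, 1] within each sign, and thresholded
   at 0.15 to call strengthened looping genes (SLGs) per condition.
3. **Which of those are also differentially expressed?**  SLGs
   intersected with genes passing |log2FC| ≥ 0.58 and p ≤ 0.05 give
   differentially expressed looping genes (DELGs).

Two supporting tools make cross-library comparison sound: a LOWESS
normalization that removes a smooth distance-dependent log2 bias of one
matrix relative to another, and binomial down-sampling to check that
library depth does not drive the domain calls.

A first-class synthetic-data module generates every input with known
ground truth (planted TAD-change events, planted loops of controlled
strength, planted expression effects), so the whole pipeline is testable
end to end without external data.

## Worked example

```bash
python analysis/01_simulate_scenario.py --seed 1
python analysis/02_normalize_matrices.py
python analysis/03_tad_changes.py
python analysis/04_loop_scoring.py
python analysis/05_slg_delg.py
```

The drivers write tables under `results/` and print, for seed 1:

```
scenario written to results/scenario (seed 1)
  genome: 1 x 20 Mb at 40 kb bins, 60 genes
  planted TAD events: {"conserve_expand": 1, "conserve_shrink": 1, "del": 1,
                       "fuse": 1, "neo": 1, "no_change": 6, "shift": 1, "split": 1}
  planted loops: 108 per condition (3 genes strengthened 5x in B)
  planted DEGs: 18 of 60
...
residual after correction: max |log2| = 0.0206
decay-profile correlation at 50% down-sampling: 1.0000
...
change breakdown over 13 events: {"conserve_expand": 1, "conserve_shrink": 1,
  "del": 1, "fuse": 1, "neo": 1, "no_change": 6, "shift": 1, "split": 1}
RC fraction 0.615, DC fraction 0.385
planted event multiset recovered exactly: True
...
SLGs: 20 strengthened in A, 3 in B (cutoff 0.15)
planted B-strengthened genes recovered: 3/3, false positives: 0
DEGs passing |log2FC| >= 0.58 and p <= 0.05: 18 (planted: 18)
DELGs: 7 of 20 A-SLGs, 0 of 3 B-SLGs differentially expressed
```

Reading the numbers: the classifier returned exactly the planted change
multiset (6 untouched TADs plus one event of each other type; RC
fraction 8/13 ≈ 0.615); all 3 genes whose loops were strengthened
five-fold in condition B were recovered with no false positives; the 18
planted expression effects all pass the DEG filter, and 7 of the
A-strengthened genes happen to be differentially expressed, making them
DELGs.  Condition A's larger SLG count is expected: with only 3 genes
truly strengthened in B, the negative tail of the VPPM-difference
distribution is pure noise, and the 0.15 cutoff within that subset
admits its upper range.

The same stages are available as subcommands of the installed `loopdiff`
CLI (`simulate`, `normalize`, `tad-diff`, `loops`, `slg`, `delg`,
`run-all`), driven by a YAML config carrying every threshold.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the default synthetic scenario through every stage (simulation,
normalization, TAD-change classification, loop scoring, SLG and DELG
calling) as an end-to-end smoke check and writes the acceptance JSON.
The pipeline's quantitative guarantees are property-based and live in
`tests/test_acceptance.py`: exact VPPM arithmetic, brute-force oracle
equivalence for the TAD classifier and the loop caller, exact recovery
of planted change events, ≥95% recovery of planted SLGs with zero false
positives, LOWESS bias recovery within ±0.02 log2, decay-profile
preservation under 50% down-sampling, DEG boundary inclusivity, and
byte-identical reports across reruns.
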