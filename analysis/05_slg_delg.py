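"""Identify strengthened looping genes and intersect with expression.

Computes per-gene VPPM differences between conditions, calls SLGs at the
0.15 normalized-score cutoff, filters the DEG table at |log2FC| >= 0.58
and p <= 0.05, and reports the differentially expressed looping genes,
checked against the planted truth.
"""

import argparse
import json
from pathlib import Path

from loopdiff.expression import filter_degs, intersect_delgs, read_deg_table
from loopdiff.hic_matrix import read_hicpro_matrix
from loopdiff.loop_scoring import (
    call_p1d1_loops,
    filter_sifs,
    read_genes_bed6,
    read_sifs,
    strengthened_looping_genes,
)

parser = argparse.ArgumentParser()
parser.add_argument("--scenario", type=Path, default=Path("results/scenario"))
parser.add_argument("--out", type=Path, default=Path("results/delg"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

genes = read_genes_bed6(args.scenario / "genes.bed")
tables = {}
for cond in ("condA", "condB"):
    mat = read_hicpro_matrix(args.scenario / f"{cond}_abs.bed",
                             args.scenario / f"{cond}.matrix",
                             args.scenario / f"{cond}.stats")
    sifs = filter_sifs(read_sifs(args.scenario / f"{cond}_sifs.tsv"))
    tables[cond] = call_p1d1_loops(sifs, genes, int(mat.total_valid_pairs), cond)

slg = strengthened_looping_genes(tables["condA"], tables["condB"])
slg.to_frame().to_csv(args.out / "slg.tsv", sep="\t", index=False)
print(f"SLGs: {len(slg.slg_a)} strengthened in A, {len(slg.slg_b)} in B "
      f"(cutoff {slg.cutoff})")

truth = json.loads((args.scenario / "truth.json").read_text())
planted = set(truth["strengthened_genes"])
print(f"planted B-strengthened genes recovered: {len(planted & slg.slg_b)}/{len(planted)}, "
      f"false positives: {len(slg.slg_b - planted)}")

deg_records = read_deg_table(args.scenario / "deg.tsv")
degs = filter_degs(deg_records)
print(f"DEGs passing |log2FC| >= 0.58 and p <= 0.05: {len(degs)} "
      f"(planted: {len(truth['deg_genes'])})")

delg_a, delg_b = intersect_delgs(slg, degs, a=tables["condA"], b=tables["condB"],
                                 deg_records=deg_records)
delg_a.table.to_csv(args.out / "delg_a.tsv", sep="\t", index=False)
delg_b.table.to_csv(args.out / "delg_b.tsv", sep="\t", index=False)
print(f"DELGs: {len(delg_a.delg_ids)} of {len(slg.slg_a)} A-SLGs, "
      f"{len(delg_b.delg_ids)} of {len(slg.slg_b)} B-SLGs differentially expressed")
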