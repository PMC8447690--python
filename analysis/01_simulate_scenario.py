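"""Generate the default two-condition synthetic scenario.

Writes every pipeline input (contact matrices, domain calls, SIF tables,
gene annotation, DEG table) plus its answer key to results/scenario and
prints what was planted.
"""

import argparse
import json
from pathlib import Path

from loopdiff.synth import ScenarioSpec, write_scenario

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/scenario"))
args = parser.parse_args()

spec = ScenarioSpec(seed=args.seed)
truth = write_scenario(spec, args.out)

print(f"scenario written to {args.out} (seed {args.seed})")
print(f"  genome: {spec.n_chrom} x {spec.chrom_length / 1e6:.0f} Mb at "
      f"{spec.bin_size // 1000} kb bins, {spec.n_genes} genes")
print(f"  planted TAD events: {json.dumps(truth.event_type_counts(), sort_keys=True)}")
print(f"  planted loops: {len(truth.loops_a)} per condition "
      f"({len(truth.strengthened_genes)} genes strengthened "
      f"{spec.effect_size:.0f}x in B)")
print(f"  planted DEGs: {len(truth.deg_genes)} of {spec.n_genes}")
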