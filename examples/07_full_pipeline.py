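"""The full workflow in one call: simulate -> scans -> ABC -> ancestry -> cp.

Runs the bundled demo configuration end-to-end and prints the headline
numbers from the machine-readable summary. The same workflow is available
from the shell as `feralscan run --seed 7 --out scratch/demo`.
"""

import json

from feralscan.pipeline import demo_config, run

summary = run(demo_config(7), "scratch/example_pipeline")

fst = summary["stages"]["fst"]
for name, block in fst.items():
    print(f"{name:14s} {block['n_regions']} outlier regions, "
          f"{block['total_bp']:,} bp "
          f"({block['genome_fraction_percent']:.2f}% of genome)")

shared = summary["stages"]["shared_regions"]
print(f"\nshared between the first two scans: {shared['n_regions']} regions, "
      f"{shared['total_bp']:,} bp")
for row in shared["per_chromosome"]:
    print(f"  {row['chrom']}: {row['n_regions']} ({row['percent']:.1f}%)")

abc = summary["stages"]["abc"]
print(f"\nABC best scenario: {abc['best']} "
      f"(posterior {abc['posteriors'][abc['best']]:.4f})")
print(f"SH_TEJ mean BH ancestry: "
      f"{summary['stages']['ancestry']['genome_mean_fraction_a']:.3f}")
print(f"\nfull summary: scratch/example_pipeline/summary.json")
print(json.dumps(summary["stages"]["cphap"], indent=2)[:300], "...")
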