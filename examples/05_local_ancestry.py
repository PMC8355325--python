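"""Mosaic local ancestry: which segments of SH_TEJ genomes come from BH?

Each SH_TEJ haplotype is decoded as an optimal mosaic of BH and modern-crop
reference haplotypes (exact dynamic program: mismatches + lambda * switches),
swept over a lambda grid with bagged panel resampling and a per-site
majority vote. Accuracy is scored against the generator's true tracts.
"""

import numpy as np

from feralscan.ancestry import ancestry_summary, extract_panels, infer_ancestry
from feralscan.simulate import SimulationConfig, simulate_populations

config = SimulationConfig(chrom_lengths={"chr1": 25_000_000}, alpha=0.5,
                          seed=11)
result = simulate_populations(config)

queries, panel_bh, panel_crop, names = extract_panels(
    result.matrix, result.popmap, admixed="SH_TEJ",
    source_a="BH", source_b="TEJ_modern")
amatrix = infer_ancestry(queries, panel_bh, panel_crop, n_bags=5, seed=0,
                         haplotype_names=names, source_a="BH",
                         source_b="crop", sites=result.matrix.sites)

print(ancestry_summary(amatrix).to_string(index=False))
print(f"\nper-haplotype BH fraction: "
      f"{np.round(amatrix.fraction_a()[:6], 3)} ...")

# score against the generator's true tracts
pos0 = result.matrix.sites["pos"].to_numpy() - 1
hq = result.popmap.haplotype_indices(result.matrix, "SH_TEJ")
truth = np.zeros_like(amatrix.labels)
for i, h in enumerate(hq):
    sub = result.truth.ancestry_tracts.query("haplotype == @h")
    for _, r in sub.iterrows():
        truth[i, (pos0 >= r.start) & (pos0 < r.end)] = int(r.source != "BH")
acc = (truth == amatrix.labels).mean()
print(f"\nper-site accuracy vs truth: {acc:.3f}")
# ~0.99 at 2-Mb tracts: tract boundaries account for nearly all errors.
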