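"""Chloroplast haplotypes: the maternal parent of the hybrid weed.

Classifies strains by exact identity of their organelle variant vectors
(strains with missing calls excluded) and tabulates haplotype frequencies
per population group. SH_TEJ weeds share the modern-crop haplotype —
evidence that the hybrid arose from BH pollen on a crop mother plant.
"""

from feralscan.cphaplo import classify, frequency_by_group
from feralscan.pipeline import demo_config
from feralscan.simulate import simulate_populations

result = simulate_populations(demo_config(7).simulation)

groups = classify(result.cp_table)
print(f"{groups.n_retained} strains retained, {len(groups.excluded)} "
      f"excluded for missing calls, {groups.n_haplotypes} haplotypes")

freq = frequency_by_group(groups, result.popmap)
print("\nhaplotype frequencies by group (rows sum to 1):")
print(freq.round(2).to_string())

crop_hap = freq.loc["TEJ_modern"].idxmax()
print(f"\nmodern crop haplotype: {crop_hap}; "
      f"SH_TEJ frequency of that haplotype: {freq.loc['SH_TEJ', crop_hap]:.2f}")
# Frequency 1.0 in SH_TEJ = every retained hybrid weed strain carries the
# crop chloroplast, i.e. a maternal crop lineage.
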