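"""Haplotype-based selection scans: iHS within weeds, XP-EHH weeds vs crop.

A planted sweep (80% of BH haplotypes sharing one core haplotype over
300 kb) produces extended haplotype homozygosity. iHS contrasts the
integrated EHH of ancestral vs derived alleles within BH; XP-EHH contrasts
pooled EHH between BH and the modern crop. Sites with -log10(p) > 4 are
called significant.
"""

from feralscan.ehh import crop_major_ancestral, ihs, xpehh
from feralscan.simulate import PlantedSweep, SimulationConfig, simulate_populations

config = SimulationConfig(
    chrom_lengths={"chr1": 10_000_000},
    sweeps=[PlantedSweep("chr1", 5_000_000, carrier_fraction=0.8,
                         population="BH")],
    seed=0,
)
result = simulate_populations(config)
sweep_pos = int(result.truth.sweep_sites["pos"].iloc[0])
print(f"planted sweep at chr1:{sweep_pos:,}")

# polarize by the major allele across the pooled crop groups
ancestral = crop_major_ancestral(result.matrix, result.popmap,
                                 ("TEJ_modern", "TEJ_landrace"))
track = ihs(result.matrix, result.popmap, "BH", ancestral=ancestral)
sig = track.significant(4.0)
print(f"\niHS: {len(track.table)} sites scored, {len(sig)} significant")
for _, row in sig.iterrows():
    print(f"  chr1:{int(row.pos):>9,}  iHS={row.score_std:+.2f}  "
          f"-log10p={row.neglog10p:.1f}  ({abs(row.pos - sweep_pos):,} bp "
          f"from the sweep)")

xp = xpehh(result.matrix, result.popmap, "BH", "TEJ_modern")
xsig = xp.significant(4.0)
near = xsig[(xsig["pos"] - sweep_pos).abs() <= 150_000]
print(f"\nXP-EHH: {len(xp.table)} sites scored, {len(xsig)} significant, "
      f"{len(near)} within 150 kb of the sweep")
# Positive XP-EHH means longer haplotype homozygosity in BH than in the
# crop — the signature of a sweep private to the weed.
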