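"""Generate a synthetic crop/weed rice study and inspect its ground truth.

Builds a small two-chromosome genome with six population groups (three
cultivated, three weedy), one planted de-domestication region and one
selective sweep in the BH weeds, and SH_TEJ individuals as BH x crop
haplotype mosaics. Prints the sample sheet and the planted truth.
"""

from feralscan.simulate import (
    PlantedRegion,
    PlantedSweep,
    SimulationConfig,
    simulate_populations,
    write_outputs,
)

config = SimulationConfig(
    chrom_lengths={"chr1": 3_000_000, "chr2": 2_000_000},
    divergent_regions=[PlantedRegion("chr1", 600_000, 900_000, f=0.55)],
    sweeps=[PlantedSweep("chr1", 2_400_000, carrier_fraction=0.8)],
    alpha=0.5,          # half of each SH_TEJ genome descends from BH weeds
    tract_mean=2e6,     # mean ancestry tract length, bp
    seed=7,
)
result = simulate_populations(config)

print(f"{result.matrix.n_samples} samples, {result.matrix.n_sites} SNPs")
for pop in result.popmap.populations:
    print(f"  {pop:14s} {len(result.popmap.samples_in(pop))} samples")
print("\nPlanted divergent regions (truth):")
print(result.truth.divergent_regions.to_string(index=False))
print("\nPlanted sweep sites (truth):")
print(result.truth.sweep_sites.to_string(index=False))

bh = result.truth.ancestry_tracts.query("source == 'BH'")
tot = result.truth.ancestry_tracts
frac = (bh.end - bh.start).sum() / (tot.end - tot.start).sum()
print(f"\nRealized BH fraction of SH_TEJ genomes: {frac:.3f} (target 0.5)")

paths = write_outputs(result, "scratch/example_study")
print(f"\nwrote {len(paths)} files under scratch/example_study/")
# The VCF, popmap, chromosome table and chloroplast table are the inputs
# every downstream example consumes; the truth tables score the results.
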