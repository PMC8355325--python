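"""Synthetic crop/weed population generator with planted truth.

Generates phased diploid genotypes for three cultivated groups
(TEJ_modern, TEJ_landrace, TRJ_landrace) and three weed groups
(BH, SH_TEJ, SH_TRJ) of temperate/tropical japonica rice, emulating the
statistical structure of a feralization study:

* allele frequencies follow a hierarchical Balding-Nichols model down a
  fixed population tree; the expected pairwise Weir-Cockerham theta between
  two sister populations is close to the average of their branch F values
  (cross-population allele pairs are uncorrelated, so theta reduces to the
  within-population correlation) — a closed form the scan modules can be
  tested against;
* configurable "de-domestication" regions where the weed branch draws its
  frequencies with a boosted F, producing localized windows of high
  differentiation;
* selective sweeps planted by haplotype copying: a configurable fraction of
  weed haplotypes share one core haplotype across a surrounding span, which
  directly produces the long-range haplotype homozygosity that iHS/XP-EHH
  detect;
* SH_TEJ individuals built as mosaics of sampled BH and TEJ_modern
  haplotypes with exponential tract lengths (single admixture pulse), and a
  crop-type maternal chloroplast;
* a chloroplast variant table with missing calls, mirroring organelle
  genotyping dropout.

Every planted feature is recorded in :class:`TruthTables` so downstream
scans can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cphaplo import CpVariantTable
from .io import (
    HaplotypeMatrix,
    PopulationMap,
    write_chrom_table,
    write_popmap,
    write_vcf,
)

__all__ = [
    "PlantedRegion",
    "PlantedSweep",
    "SimulationConfig",
    "TruthTables",
    "SimulationResult",
    "simulate_populations",
    "write_outputs",
]

# fixed population tree: (child, parent); frequencies are drawn root-down
_TREE = [
    ("TEJ_anc", "root"),
    ("TRJ_anc", "root"),
    ("crop_TEJ_anc", "TEJ_anc"),
    ("TEJ_modern", "crop_TEJ_anc"),
    ("TEJ_landrace", "crop_TEJ_anc"),
    ("BH", "TEJ_anc"),
    ("TRJ_landrace", "TRJ_anc"),
    ("SH_TRJ", "TRJ_anc"),
]

SAMPLED_GROUPS = ("TEJ_modern", "TEJ_landrace", "TRJ_landrace", "BH", "SH_TEJ", "SH_TRJ")

# reference window used only for the site-density sanity check
_DENSITY_WINDOW = 100_000


@dataclass(frozen=True)
class PlantedRegion:
    """A divergent region: the weed branch draws frequencies with boosted F."""

    chrom: str
    start: int  # 0-based half-open, bp
    end: int
    f: float
    population: str = "BH"


@dataclass(frozen=True)
class PlantedSweep:
    """A planted selective sweep: ``carrier_fraction`` of the population's
    haplotypes share one core haplotype over ``span`` bp around ``pos``."""

    chrom: str
    pos: int  # 1-based bp
    carrier_fraction: float = 0.8
    population: str = "BH"
    span: int = 300_000


@dataclass
class SimulationConfig:
    """Generator settings; defaults give a small two-chromosome genome with
    japonica-like group divergence."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000}
    )
    # sites per chromosome; None derives one site per `site_spacing` bp
    sites_per_chrom: dict[str, int] | int | None = None
    site_spacing: int = 5_000
    haplotypes: dict[str, int] = field(
        default_factory=lambda: {
            "TEJ_modern": 20,
            "TEJ_landrace": 20,
            "TRJ_landrace": 20,
            "BH": 20,
            "SH_TEJ": 20,
            "SH_TRJ": 10,
        }
    )
    # per-branch Balding-Nichols F; pairwise WC theta between sisters is
    # ~ the average of their branch F values (compound branches multiply
    # as 1 - prod(1 - F_i))
    branch_f: dict[str, float] = field(
        default_factory=lambda: {
            "TEJ_anc": 0.15,
            "TRJ_anc": 0.15,
            "crop_TEJ_anc": 0.01,
            "TEJ_modern": 0.02,
            "TEJ_landrace": 0.02,
            "BH": 0.05,
            "TRJ_landrace": 0.02,
            "SH_TRJ": 0.05,
        }
    )
    divergent_regions: list[PlantedRegion] = field(default_factory=list)
    sweeps: list[PlantedSweep] = field(default_factory=list)
    # fraction of each SH_TEJ haplotype copied from BH donors
    alpha: float = 0.5
    # mean ancestry tract length in bp (across alternating tracts)
    tract_mean: float = 2_000_000.0
    # ancestral allele-frequency range at the tree root
    p0_range: tuple[float, float] = (0.05, 0.95)
    # chloroplast
    cp_haplotype_by_pop: dict[str, int] = field(
        default_factory=lambda: {
            "TEJ_modern": 1,
            "TEJ_landrace": 2,
            "BH": 2,
            "SH_TEJ": 1,  # crop maternal lineage
            "TRJ_landrace": 3,
            "SH_TRJ": 2,
        }
    )
    cp_n_variants: int = 7
    cp_missing_rate: float = 0.11
    seed: int = 0

    def sites_for(self, chrom: str) -> int:
        if isinstance(self.sites_per_chrom, dict):
            return int(self.sites_per_chrom[chrom])
        if self.sites_per_chrom is not None:
            return int(self.sites_per_chrom)
        return max(2, self.chrom_lengths[chrom] // self.site_spacing)

    def validate(self) -> None:
        if not (0.0 <= self.alpha < 1.0 or self.alpha == 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.tract_mean <= 0:
            raise ValueError("tract mean must be positive")
        for name, f in self.branch_f.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"degenerate branch F for {name}: {f} (need 0 < F < 1)")
        for chrom, length in self.chrom_lengths.items():
            n = self.sites_for(chrom)
            if n < 2 * max(1, length // _DENSITY_WINDOW):
                raise ValueError(f"insufficient density on {chrom}: {n} sites")
        for r in self.divergent_regions:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"planted region on unknown chromosome {r.chrom}")
            if not (0 <= r.start < r.end <= self.chrom_lengths[r.chrom]):
                raise ValueError(f"planted region outside chromosome bounds: {r}")
            if not (0.0 < r.f < 1.0):
                raise ValueError(f"degenerate region F: {r.f}")
        for s in self.sweeps:
            if s.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {s.chrom}")
            if not (0.0 < s.carrier_fraction <= 1.0):
                raise ValueError("sweep carrier fraction must lie in (0, 1]")


@dataclass
class TruthTables:
    """Generator-side ground truth for recovery tests.

    ``ancestry_tracts`` tiles every SH_TEJ haplotype per chromosome with
    0-based half-open intervals labelled by source (``BH`` or ``crop``).
    """

    ancestry_tracts: pd.DataFrame
    divergent_regions: pd.DataFrame
    sweep_sites: pd.DataFrame
    cp_haplotype: dict[str, int]
    scenario: dict = field(default_factory=dict)


@dataclass
class SimulationResult:
    matrix: HaplotypeMatrix
    popmap: PopulationMap
    truth: TruthTables
    cp_table: CpVariantTable
    chrom_lengths: dict[str, int]
    config: SimulationConfig

    def __iter__(self):  # allow (matrix, popmap, truth) unpacking
        return iter((self.matrix, self.popmap, self.truth))


def _draw_child(rng, p_parent: np.ndarray, f: np.ndarray | float) -> np.ndarray:
    """Balding-Nichols: child frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    f = np.broadcast_to(np.asarray(f, dtype=float), p_parent.shape)
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p_parent * scale, 1e-12),
                    np.maximum((1.0 - p_parent) * scale, 1e-12))


def _site_positions(rng, length: int, n: int) -> np.ndarray:
    pos = rng.choice(length, size=n, replace=False) + 1  # 1-based
    pos.sort()
    return pos.astype(np.int64)


def _mosaic_tracts(rng, length: int, alpha: float, tract_mean: float):
    """Alternating exponential tracts; BH tracts have mean 2*L*alpha and crop
    tracts 2*L*(1-alpha) so the stationary BH fraction is alpha."""
    if alpha <= 0.0:
        return [(0, length, "crop")]
    if alpha >= 1.0:
        return [(0, length, "BH")]
    means = {"BH": 2.0 * tract_mean * alpha, "crop": 2.0 * tract_mean * (1.0 - alpha)}
    state = "BH" if rng.random() < alpha else "crop"
    tracts = []
    pos = 0
    while pos < length:
        seg = max(1, int(np.ceil(rng.exponential(means[state]))))
        end = min(pos + seg, length)
        tracts.append((pos, end, state))
        pos = end
        state = "crop" if state == "BH" else "BH"
    return tracts


def simulate_populations(config: SimulationConfig) -> SimulationResult:
    """Generate the full synthetic study: phased genotypes, population map,
    chloroplast table and truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    counts = dict(config.haplotypes)
    for pop in SAMPLED_GROUPS:
        n = counts.get(pop, 0)
        if n % 2 != 0:
            raise ValueError(f"odd haplotype count for {pop} (need diploids)")

    # --- sample bookkeeping -------------------------------------------------
    samples: list[str] = []
    pop_of: dict[str, str] = {}
    hap_rows: dict[str, np.ndarray] = {}
    row = 0
    for pop in SAMPLED_GROUPS:
        n_hap = counts.get(pop, 0)
        rows = []
        for i in range(n_hap // 2):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            pop_of[name] = pop
            rows.extend((row, row + 1))
            row += 2
        hap_rows[pop] = np.asarray(rows, dtype=np.intp)
    n_hap_total = row

    # --- per-chromosome genotypes ------------------------------------------
    site_frames = []
    allele_blocks = []
    tract_records = []
    sweep_records = []
    bases = np.array(list("ACGT"))
    for chrom, length in config.chrom_lengths.items():
        n_sites = config.sites_for(chrom)
        pos = _site_positions(rng, length, n_sites)
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        lo, hi = config.p0_range
        p0 = rng.uniform(lo, hi, size=n_sites)

        # root-down Balding-Nichols frequencies; weed branches may carry a
        # boosted F inside planted divergent regions
        freq: dict[str, np.ndarray] = {"root": p0}
        for child, parent in _TREE:
            f = np.full(n_sites, config.branch_f[child])
            for reg in config.divergent_regions:
                if reg.chrom == chrom and reg.population == child:
                    in_reg = (pos - 1 >= reg.start) & (pos - 1 < reg.end)
                    f[in_reg] = reg.f
            freq[child] = _draw_child(rng, freq[parent], f)

        block = np.zeros((n_hap_total, n_sites), dtype=np.int8)
        for pop in SAMPLED_GROUPS:
            if pop == "SH_TEJ" or len(hap_rows[pop]) == 0:
                continue
            p = freq[pop]
            block[hap_rows[pop]] = (
                rng.random((len(hap_rows[pop]), n_sites)) < p
            ).astype(np.int8)

        # planted sweeps: haplotype copying over the sweep span; the sweep
        # allele is a derived variant private to the carriers
        for sw in config.sweeps:
            if sw.chrom != chrom:
                continue
            pool = hap_rows[sw.population]
            n_car = max(2, int(round(sw.carrier_fraction * len(pool))))
            carriers = rng.choice(pool, size=min(n_car, len(pool)), replace=False)
            half = sw.span // 2
            in_span = (pos >= sw.pos - half) & (pos <= sw.pos + half)
            core_j = int(np.argmin(np.abs(pos - sw.pos)))
            donor = int(carriers[0])
            core_hap = block[donor, in_span].copy()
            for h in carriers:
                block[h, in_span] = core_hap
            block[:, core_j] = 0  # ancestral allele everywhere else
            block[np.asarray(carriers), core_j] = 1  # derived sweep allele
            sweep_records.append(
                {"chrom": chrom, "pos": int(pos[core_j]),
                 "population": sw.population,
                 "carrier_fraction": sw.carrier_fraction,
                 "n_carriers": int(len(carriers))}
            )

        # SH_TEJ mosaics: copy segments from simulated BH / TEJ_modern donors
        # (after sweep planting, so mosaic segments can inherit sweeps)
        bh_pool = hap_rows["BH"]
        crop_pool = hap_rows["TEJ_modern"]
        for h in hap_rows["SH_TEJ"]:
            if len(bh_pool) == 0 or len(crop_pool) == 0:
                raise ValueError("SH_TEJ mosaics need non-empty BH and TEJ_modern pools")
            tracts = _mosaic_tracts(rng, length, config.alpha, config.tract_mean)
            for start, end, source in tracts:
                donor_pool = bh_pool if source == "BH" else crop_pool
                donor = int(rng.choice(donor_pool))
                in_seg = (pos - 1 >= start) & (pos - 1 < end)
                block[h, in_seg] = block[donor, in_seg]
                tract_records.append(
                    {"haplotype": int(h), "chrom": chrom, "start": start,
                     "end": end, "source": source}
                )

        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "ref": bases[ref_idx], "alt": bases[alt_idx],
        }))
        allele_blocks.append(block)

    sites = pd.concat(site_frames, ignore_index=True)
    alleles = np.concatenate(allele_blocks, axis=1)
    matrix = HaplotypeMatrix(alleles, sites, samples)
    popmap = PopulationMap(pop_of)

    # --- chloroplast table --------------------------------------------------
    cp_table, cp_truth = _make_cp_table(rng, samples, pop_of, config)

    truth = TruthTables(
        ancestry_tracts=pd.DataFrame(
            tract_records,
            columns=["haplotype", "chrom", "start", "end", "source"],
        ),
        divergent_regions=pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end, "f": r.f,
              "population": r.population} for r in config.divergent_regions],
            columns=["chrom", "start", "end", "f", "population"],
        ),
        sweep_sites=pd.DataFrame(
            sweep_records,
            columns=["chrom", "pos", "population", "carrier_fraction", "n_carriers"],
        ),
        cp_haplotype=cp_truth,
    )
    return SimulationResult(matrix, popmap, truth, cp_table,
                            dict(config.chrom_lengths), config)


def _cp_vector(hap_id: int, n_variants: int) -> np.ndarray:
    """Deterministic distinct binary defining vector per haplotype id."""
    bits = [(hap_id - 1) >> k & 1 for k in range(n_variants)]
    return np.asarray(bits, dtype=np.int8)


def _make_cp_table(rng, samples, pop_of, config: SimulationConfig):
    n_var = config.cp_n_variants
    kinds = ["snp"] * max(0, n_var - 2) + ["indel"] * min(2, n_var)
    variants = pd.DataFrame({
        "id": [f"cp_v{i + 1}" for i in range(n_var)],
        "pos": np.sort(rng.choice(130_000, size=n_var, replace=False) + 1),
        "kind": kinds[:n_var],
    })
    calls = np.zeros((len(samples), n_var), dtype=np.int8)
    cp_truth: dict[str, int] = {}
    for i, s in enumerate(samples):
        hap = config.cp_haplotype_by_pop[pop_of[s]]
        cp_truth[s] = hap
        calls[i] = _cp_vector(hap, n_var)
    # organelle genotyping dropout: some strains get >=1 missing call
    for i in range(len(samples)):
        if rng.random() < config.cp_missing_rate:
            k = int(rng.integers(1, max(2, n_var // 2)))
            miss = rng.choice(n_var, size=k, replace=False)
            calls[i, miss] = -1
    return CpVariantTable(calls, list(samples), variants), cp_truth


# ---------------------------------------------------------------------------
# Output writing


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, popmap, chromosome table, chloroplast table and truth
    tables (1-based inclusive coordinates) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "popmap": outdir / "popmap.tsv",
        "chroms": outdir / "chromosomes.tsv",
        "cp_table": outdir / "chloroplast_variants.tsv",
        "truth_tracts": outdir / "truth_ancestry_tracts.tsv",
        "truth_regions": outdir / "truth_divergent_regions.tsv",
        "truth_sweeps": outdir / "truth_sweeps.tsv",
        "truth_cp": outdir / "truth_cp_haplotypes.tsv",
    }
    write_vcf(result.matrix, paths["vcf"], result.chrom_lengths)
    write_popmap(result.popmap, paths["popmap"])
    write_chrom_table(result.chrom_lengths, paths["chroms"])
    result.cp_table.to_tsv(paths["cp_table"])

    tracts = result.truth.ancestry_tracts.copy()
    if len(tracts):
        tracts["start"] = tracts["start"] + 1  # 1-based inclusive
    tracts.to_csv(paths["truth_tracts"], sep="\t", index=False)

    regions = result.truth.divergent_regions.copy()
    if len(regions):
        regions["start"] = regions["start"] + 1
    regions.to_csv(paths["truth_regions"], sep="\t", index=False)

    result.truth.sweep_sites.to_csv(paths["truth_sweeps"], sep="\t", index=False)
    pd.Series(result.truth.cp_haplotype, name="cp_haplotype").rename_axis(
        "sample"
    ).to_csv(paths["truth_cp"], sep="\t")
    return paths
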