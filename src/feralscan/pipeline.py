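"""End-to-end orchestration of the feralization scan workflow.

Stages run in dependency order on either a simulated study (the bundled
demo) or user-supplied files: windowed F_ST scans for each weed/crop pair,
cross-scan intersection into de-domestication blocks, iHS and XP-EHH
selection scans, ABC demographic scenario choice, mosaic local-ancestry
inference for the admixed weed group, and chloroplast haplotype
classification.  Every stage writes its own table; a machine-readable
``summary.json`` collects the headline numbers (region counts, shared
regions, genome fractions, per-chromosome percentages, ABC posteriors,
ancestry fractions, chloroplast haplotype frequencies).

All randomness flows from one root seed, split per stage, so a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ancestry as anc
from . import cphaplo, demography, fst
from .ehh import crop_major_ancestral, ihs, xpehh
from .io import (
    HaplotypeMatrix,
    PopulationMap,
    make_windows,
    read_chrom_table,
    read_popmap,
    read_vcf,
)
from .simulate import PlantedRegion, PlantedSweep, SimulationConfig, simulate_populations

logger = logging.getLogger("feralscan")

__all__ = ["RunConfig", "run", "demo_config", "validate_summary"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``simulation`` is set (the generator provides all inputs) or the
    four input paths are.  ``scan_pairs`` lists (name, weed group, crop
    groups) comparisons; the first two named scans are intersected.
    """

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    popmap: str | None = None
    chrom_table: str | None = None
    cp_table: str | None = None

    scan_pairs: list[tuple[str, str, tuple[str, ...]]] = field(
        default_factory=lambda: [
            ("BH_vs_TEJ", "BH", ("TEJ_modern", "TEJ_landrace")),
            ("SHTEJ_vs_TEJ", "SH_TEJ", ("TEJ_modern", "TEJ_landrace")),
            ("SHTRJ_vs_TRJ", "SH_TRJ", ("TRJ_landrace",)),
        ]
    )
    window: int = 100_000
    step: int = 10_000
    mad_m: float = 5.0
    min_sites: int = 5
    neglog10p_threshold: float = 4.0

    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "fst": True, "ehh": True, "abc": True,
            "ancestry": True, "cphap": True,
        }
    )

    ihs_population: str = "BH"
    xpehh_pair: tuple[str, str] = ("BH", "TEJ_modern")
    crop_groups: tuple[str, ...] = ("TEJ_modern", "TEJ_landrace", "TRJ_landrace")

    abc_n_sims: int = 1500
    abc_n_snps: int = 100
    abc_retain: float = 0.02

    admixed: str = "SH_TEJ"
    source_a: str = "BH"
    source_b: str = "TEJ_modern"
    lambda_grid: tuple[float, ...] = anc.DEFAULT_LAMBDA_GRID
    n_bags: int = 5

    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and not (self.vcf and self.popmap and self.chrom_table):
            raise ValueError("need either a simulation config or input paths")
        if self.window <= 0 or self.step <= 0 or self.mad_m <= 0:
            raise ValueError("thresholds must be positive")
        if self.neglog10p_threshold <= 0:
            raise ValueError("thresholds must be positive")


def demo_config(seed: int = 0) -> RunConfig:
    """The bundled reproducible demo: a small two-chromosome genome with two
    planted de-domestication regions shared between the BH and SH_TEJ scans,
    one BH-private region, and one sweep in BH."""
    sim = SimulationConfig(
        chrom_lengths={"chr1": 3_000_000, "chr2": 2_000_000},
        divergent_regions=[
            PlantedRegion("chr1", 600_000, 900_000, f=0.55, population="BH"),
            PlantedRegion("chr2", 1_200_000, 1_500_000, f=0.55, population="BH"),
            PlantedRegion("chr1", 1_800_000, 2_100_000, f=0.55, population="SH_TRJ"),
        ],
        sweeps=[PlantedSweep("chr1", 2_600_000, carrier_fraction=0.8,
                             population="BH")],
        alpha=0.5,
        seed=seed,
    )
    return RunConfig(simulation=sim, seed=seed)


def _stage_seed(root: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes
    ss = np.random.SeedSequence([root, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the summary dict and writes
    ``summary.json`` plus per-stage tables under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    summary: dict = {"seed": config.seed, "parameters": {
        "window": config.window, "step": config.step, "mad_m": config.mad_m,
        "neglog10p_threshold": config.neglog10p_threshold,
    }, "stages": {}}

    try:
        # --- inputs --------------------------------------------------------
        truth = None
        cp_table = None
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            logger.info("simulating study with seed %d", config.seed)
            result = simulate_populations(sim_cfg)
            matrix, popmap, truth = result.matrix, result.popmap, result.truth
            chrom_lengths = result.chrom_lengths
            cp_table = result.cp_table
        else:
            matrix = read_vcf(config.vcf)
            popmap = read_popmap(config.popmap)
            chrom_lengths = read_chrom_table(config.chrom_table)
            if config.cp_table:
                cp_table = cphaplo.CpVariantTable.from_tsv(config.cp_table)
        popmap.validate(matrix)
        summary["n_samples"] = matrix.n_samples
        summary["n_sites"] = matrix.n_sites

        # --- F_ST scans ----------------------------------------------------
        region_lists: dict[str, list[fst.OutlierRegion]] = {}
        if config.stages.get("fst", True):
            grid = make_windows(chrom_lengths, config.window, config.step)
            fst_summary = {}
            present = set(popmap.populations)
            for name, weed, crops in config.scan_pairs:
                if weed not in present or not set(crops) <= present:
                    logger.info("skipping scan %s (groups absent)", name)
                    continue
                scan = fst.window_fst(matrix, popmap, grid, weed, crops,
                                      min_sites=config.min_sites)
                scan = fst.call_outliers(scan, m=config.mad_m)
                regions = fst.merge_regions(scan)
                region_lists[name] = regions
                scan.to_tsv(outdir / f"fst_{name}.tsv")
                total_bp = int(sum(r.length for r in regions))
                fst_summary[name] = {
                    "n_regions": len(regions),
                    "total_bp": total_bp,
                    "genome_fraction_percent": fst.genome_fraction(
                        regions, chrom_lengths),
                }
                logger.info("scan %s: %d outlier regions (%d bp)",
                            name, len(regions), total_bp)
            summary["stages"]["fst"] = fst_summary
            names = [n for n, _, _ in config.scan_pairs if n in region_lists]
            if len(names) >= 2:
                shared = fst.intersect_scans(region_lists[names[0]],
                                             region_lists[names[1]])
                tally = fst.chromosome_tally(shared)
                summary["stages"]["shared_regions"] = {
                    "scans": names[:2],
                    "n_regions": len(shared),
                    "total_bp": int(sum(r.length for r in shared)),
                    "genome_fraction_percent": fst.genome_fraction(
                        shared, chrom_lengths),
                    "per_chromosome": tally.to_dict(orient="records"),
                }

        # --- EHH scans -----------------------------------------------------
        if config.stages.get("ehh", True):
            crop_present = tuple(g for g in config.crop_groups
                                 if g in popmap.populations)
            ancestral = crop_major_ancestral(matrix, popmap, crop_present) \
                if crop_present else None
            track_i = ihs(matrix, popmap, config.ihs_population,
                          ancestral=ancestral)
            track_x = xpehh(matrix, popmap, *config.xpehh_pair)
            track_i.to_tsv(outdir / "ihs.tsv")
            track_x.to_tsv(outdir / "xpehh.tsv")
            thr = config.neglog10p_threshold
            summary["stages"]["ehh"] = {
                "ihs_population": config.ihs_population,
                "ihs_n_scored": int(len(track_i.table)),
                "ihs_n_significant": int(len(track_i.significant(thr))),
                "xpehh_pair": list(config.xpehh_pair),
                "xpehh_n_scored": int(len(track_x.table)),
                "xpehh_n_significant": int(len(track_x.significant(thr))),
            }

        # --- ABC scenario choice ------------------------------------------
        if config.stages.get("abc", True):
            mapping = {config.source_b: "crop", config.source_a: "BH",
                       config.admixed: "SH"}
            keep = popmap.samples_in(*mapping)
            sub = matrix.subset_samples(keep)
            sub_pm = PopulationMap({
                s: mapping[popmap.population(s)] for s in keep
            })
            observed = demography.summarize(sub, sub_pm)
            n_hap = {
                "crop": 2 * len(popmap.samples_in(config.source_b)),
                "BH": 2 * len(popmap.samples_in(config.source_a)),
                "SH": 2 * len(popmap.samples_in(config.admixed)),
            }
            res = demography.abc_model_choice(
                observed, demography.hybrid_origin_scenarios(), n_hap,
                n_snps=config.abc_n_snps,
                n_sims_per_scenario=config.abc_n_sims,
                retain_fraction=config.abc_retain,
                seed=_stage_seed(config.seed, "abc"),
                n_bootstrap=100,
            )
            summary["stages"]["abc"] = {
                "posteriors": res.posteriors,
                "ci": {k: list(v) for k, v in res.ci.items()},
                "rejection_posteriors": res.rejection_posteriors,
                "best": res.best(),
                "method": res.method,
            }
            logger.info("ABC best scenario: %s", res.best())

        # --- local ancestry ------------------------------------------------
        if config.stages.get("ancestry", True):
            q, pa, pb, names = anc.extract_panels(
                matrix, popmap, config.admixed, config.source_a, config.source_b)
            amatrix = anc.infer_ancestry(
                q, pa, pb, lam_grid=config.lambda_grid, n_bags=config.n_bags,
                seed=_stage_seed(config.seed, "ancestry"),
                haplotype_names=names, source_a=config.source_a,
                source_b=config.source_b, sites=matrix.sites,
            )
            first_scan = next(iter(region_lists.values()), [])
            summ = anc.ancestry_summary(amatrix, first_scan)
            summ.to_csv(outdir / "ancestry_summary.tsv", sep="\t", index=False)
            amatrix.to_frame().to_csv(outdir / "ancestry.tsv", sep="\t",
                                      index=False)
            by_chrom = {
                row["chrom"]: row["mean_fraction_a"]
                for _, row in summ[summ["scope"] == "chromosome"].iterrows()
            }
            summary["stages"]["ancestry"] = {
                "admixed": config.admixed,
                "source_a": config.source_a,
                "source_b": config.source_b,
                "genome_mean_fraction_a": float(
                    summ.loc[summ["scope"] == "genome", "mean_fraction_a"].iloc[0]),
                "per_chromosome_fraction_a": by_chrom,
            }

        # --- chloroplast haplotypes ---------------------------------------
        if config.stages.get("cphap", True) and cp_table is not None:
            groups = cphaplo.classify(cp_table)
            freq = cphaplo.frequency_by_group(groups, popmap)
            freq.to_csv(outdir / "cp_haplotype_frequencies.tsv", sep="\t")
            summary["stages"]["cphap"] = {
                "n_haplotypes": groups.n_haplotypes,
                "n_retained": groups.n_retained,
                "n_excluded": len(groups.excluded),
                "frequencies": {
                    pop: {str(h): float(v) for h, v in row.items()}
                    for pop, row in freq.iterrows()
                },
            }

        summary["runtime_seconds"] = round(time.time() - t0, 2)
        validate_summary(summary)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("run complete in %.1fs", summary["runtime_seconds"])
        return summary
    except Exception:
        logger.exception("stage failure; see %s", outdir / "run.log")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


_SCHEMA = {
    "fst": {"n_regions": int, "total_bp": int, "genome_fraction_percent": float},
    "shared_regions": {"n_regions": int, "total_bp": int,
                       "genome_fraction_percent": float},
}


def validate_summary(summary: dict) -> None:
    """Light structural validation of the machine-readable summary."""
    for key in ("seed", "parameters", "stages"):
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
    fst_block = summary["stages"].get("fst", {})
    for name, block in fst_block.items():
        for field_name, typ in _SCHEMA["fst"].items():
            if field_name not in block:
                raise ValueError(f"fst scan {name} missing {field_name}")
            if not isinstance(block[field_name], (int, float)):
                raise ValueError(f"fst scan {name} field {field_name} not numeric")
    shared = summary["stages"].get("shared_regions")
    if shared is not None:
        for field_name in _SCHEMA["shared_regions"]:
            if field_name not in shared:
                raise ValueError(f"shared_regions missing {field_name}")
    abc_block = summary["stages"].get("abc")
    if abc_block is not None:
        total = sum(abc_block["posteriors"].values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("ABC posteriors do not sum to 1")
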