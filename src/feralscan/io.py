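"""Shared genotype containers, file formats and windowing conventions.

All coordinates are 0-based half-open internally; every file written or read
(VCF, popmap, truth tables, region reports) uses the 1-based inclusive
convention of the originating formats.  Conversion happens only at the I/O
boundary.

Genotypes are phased, biallelic, diploid: a :class:`HaplotypeMatrix` holds
2N haplotype rows (two consecutive rows per sample) over S sites, with
alleles coded 0 (REF), 1 (ALT) and -1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "PopulationMap",
    "WindowGrid",
    "VariantCounts",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_chrom_table",
    "write_chrom_table",
    "make_windows",
    "count_variants",
]


@dataclass
class HaplotypeMatrix:
    """Phased alleles for ``2N`` haplotypes over ``S`` biallelic sites.

    Parameters
    ----------
    alleles
        ``int8`` array of shape ``(2N, S)`` with values in {0, 1, -1};
        haplotypes ``2i`` and ``2i+1`` belong to sample ``i``.
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; sorted by (chrom, pos), strictly increasing within a
        chromosome.
    samples
        Sample identifiers, length ``N``.
    """

    alleles: np.ndarray
    sites: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.samples)} samples (need exactly two per sample)"
            )
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError("site table length does not match allele columns")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_of_haplotype(self, h: int) -> str:
        return self.samples[h // 2]

    def haplotype_rows(self, sample: str) -> tuple[int, int]:
        i = self.samples.index(sample)
        return 2 * i, 2 * i + 1

    def site_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def subset_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, mask],
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
        )

    def subset_samples(self, keep: list[str]) -> "HaplotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        return HaplotypeMatrix(self.alleles[rows], self.sites.copy(), list(keep))

    def diploid_genotypes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return per-sample allele-1 dosage and a validity mask.

        Dosage is 0/1/2 where both haplotypes are called; entries with any
        missing haplotype are flagged invalid (dosage set to 0 there).
        """
        a = self.alleles[0::2]
        b = self.alleles[1::2]
        ok = (a != MISSING) & (b != MISSING)
        dos = np.where(ok, a + b, 0).astype(np.int16)
        return dos, ok


@dataclass
class PopulationMap:
    """Mapping from sample id to population label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.assignments.items():
            if not p:
                raise ValueError(f"empty population label for sample {s!r}")

    def population(self, sample: str) -> str:
        return self.assignments[sample]

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignments.values()))

    def samples_in(self, *labels: str) -> list[str]:
        want = set(labels)
        return [s for s, p in self.assignments.items() if p in want]

    def haplotype_indices(self, matrix: HaplotypeMatrix, *labels: str) -> np.ndarray:
        """Row indices (into ``matrix.alleles``) of all haplotypes whose
        sample carries one of ``labels``."""
        unknown = set(labels) - set(self.populations)
        if unknown:
            raise KeyError(f"unknown population label(s): {sorted(unknown)}")
        rows = []
        for i, s in enumerate(matrix.samples):
            if self.assignments.get(s) in labels:
                rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.intp)

    def validate(self, matrix: HaplotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population label: {missing}")


@dataclass
class WindowGrid:
    """Sliding windows over chromosomes, half-open 0-based intervals."""

    window: int
    step: int
    windows: dict[str, np.ndarray] = field(default_factory=dict)

    def n_windows(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.windows[chrom])
        return sum(len(w) for w in self.windows.values())

    def iter_windows(self):
        for chrom, arr in self.windows.items():
            for start, end in arr:
                yield chrom, int(start), int(end)


def make_windows(chrom_lengths: dict[str, int], window: int, step: int) -> WindowGrid:
    """Build the scan grid: windows anchored at 0, ``step`` apart, truncated
    at the chromosome end; a window is emitted iff its start lies inside the
    chromosome."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window size")
    grid = WindowGrid(window=window, step=step)
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        grid.windows[chrom] = np.column_stack([starts, ends])
    return grid


# ---------------------------------------------------------------------------
# VCF


def write_vcf(matrix: HaplotypeMatrix, path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCFv4.2 with phased GT fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralscan\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in matrix.chromosomes:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        chroms = matrix.sites["chrom"].to_numpy()
        pos = matrix.sites["pos"].to_numpy()
        ref = matrix.sites["ref"].to_numpy()
        alt = matrix.sites["alt"].to_numpy()
        al = matrix.alleles
        code = {0: "0", 1: "1", MISSING: "."}
        for j in range(matrix.n_sites):
            gts = "\t".join(
                f"{code[int(al[2 * i, j])]}|{code[int(al[2 * i + 1, j])]}"
                for i in range(matrix.n_samples)
            )
            fh.write(f"{chroms[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, on_bad: str = "error") -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Parameters
    ----------
    on_bad
        ``"error"`` (default) raises on multi-allelic or unphased records;
        ``"skip"`` drops them silently.
    """
    from cyvcf2 import VCF

    if on_bad not in ("error", "skip"):
        raise ValueError("on_bad must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            if on_bad == "skip":
                continue
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}")
        col = np.empty(2 * len(samples), dtype=np.int8)
        bad = False
        for i, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if a >= 0 and b >= 0 and not phased and a != b:
                bad = True
                break
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        if bad:
            if on_bad == "skip":
                continue
            raise ValueError(f"unphased heterozygote at {v.CHROM}:{v.POS}")
        if chroms and v.CHROM == chroms[-1] and v.POS <= poss[-1]:
            raise ValueError(f"unsorted VCF at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(col)
    if not cols:
        raise ValueError("no usable records in VCF")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return HaplotypeMatrix(np.column_stack(cols), sites, samples)


# ---------------------------------------------------------------------------
# TSV side files


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


def read_popmap(path: str | Path) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            assignments[sample] = pop
    return PopulationMap(assignments)


def write_chrom_table(chrom_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_table(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


# ---------------------------------------------------------------------------
# Variant accounting


@dataclass(frozen=True)
class VariantCounts:
    """SNP/indel accounting for a variant table or call set."""

    snps: int
    indels: int

    @property
    def total(self) -> int:
        return self.snps + self.indels

    def as_dict(self) -> dict[str, int]:
        return {"snps": self.snps, "indels": self.indels, "total": self.total}


def count_variants(sites: pd.DataFrame) -> VariantCounts:
    """Classify variants as SNPs (both alleles length 1) or indels from a
    table with ``ref``/``alt`` columns."""
    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    snp = (ref.str.len() == 1) & (alt.str.len() == 1)
    return VariantCounts(snps=int(snp.sum()), indels=int((~snp).sum()))
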