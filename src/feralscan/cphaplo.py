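"""Chloroplast haplotype classification and per-group frequency tables.

The chloroplast is maternally inherited and effectively haploid, so a small
set of organelle variants (SNPs and indels, both treated as biallelic
presence/absence markers) identifies the maternal lineage of each strain.
Strains are grouped by exact identity of their allele vector; strains with
any missing call are excluded rather than imputed — with a handful of
variants exact matching is the only defensible grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, PopulationMap

__all__ = ["CpVariantTable", "HaplotypeGroups", "classify", "frequency_by_group"]


@dataclass
class CpVariantTable:
    """Haploid genotype calls, strains x variants.

    ``calls`` is an int8 array with values 0, 1 or -1 (missing);
    ``variants`` carries pos/ref/alt/kind metadata (kind in {snp, indel}).
    """

    calls: np.ndarray
    strains: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strains), len(self.variants)):
            raise ValueError("calls shape does not match strains x variants")
        ids = self.variants.get("id")
        if ids is not None and ids.duplicated().any():
            raise ValueError("duplicate variant ids")

    @classmethod
    def from_tsv(cls, path) -> "CpVariantTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        calls = df.to_numpy()
        calls = np.where(pd.isna(calls), MISSING, calls).astype(np.int8)
        variants = pd.DataFrame({"id": list(df.columns)})
        return cls(calls, list(df.index), variants)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.calls.astype(float), index=self.strains,
            columns=list(self.variants["id"]) if "id" in self.variants else None,
        )
        df = df.where(df >= 0, other=np.nan)
        df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class HaplotypeGroups:
    """Result of exact-match haplotype classification.

    Haplotype ids are numbered 1..H by decreasing carrier count, ties broken
    by first occurrence in strain order.
    """

    haplotypes: dict[int, tuple[int, ...]]
    assignment: dict[str, int]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_retained(self) -> int:
        return len(self.assignment)

    def carriers(self, hap_id: int) -> list[str]:
        return [s for s, h in self.assignment.items() if h == hap_id]


def classify(table: CpVariantTable) -> HaplotypeGroups:
    """Group strains by exact allele-vector identity.

    Strains with any missing call are excluded (reason recorded); the
    remainder are partitioned into haplotypes numbered by decreasing size.
    """
    if table.calls.shape[1] < 1:
        raise ValueError("need at least one variant")
    excluded: dict[str, str] = {}
    vectors: dict[tuple[int, ...], list[str]] = {}
    for i, strain in enumerate(table.strains):
        row = table.calls[i]
        if np.any(row == MISSING):
            excluded[strain] = "missing data at variant sites"
            continue
        vectors.setdefault(tuple(int(x) for x in row), []).append(strain)
    if not vectors:
        raise ValueError("no complete strains")
    # decreasing carrier count; ties by first occurrence (dict preserves it)
    order = sorted(
        vectors.items(),
        key=lambda kv: (-len(kv[1]), table.strains.index(kv[1][0])),
    )
    haplotypes: dict[int, tuple[int, ...]] = {}
    assignment: dict[str, int] = {}
    for hap_id, (vec, carriers) in enumerate(order, start=1):
        haplotypes[hap_id] = vec
        for s in carriers:
            assignment[s] = hap_id
    return HaplotypeGroups(haplotypes, assignment, excluded)


def frequency_by_group(groups: HaplotypeGroups, popmap: PopulationMap) -> pd.DataFrame:
    """Relative frequency of each haplotype per population label.

    Rows are populations, columns haplotype ids; each row sums to 1 over the
    retained strains of that population. Populations with no retained strain
    are omitted with a warning.
    """
    hap_ids = sorted(groups.haplotypes)
    rows = {}
    for pop in popmap.populations:
        members = [s for s in popmap.samples_in(pop) if s in groups.assignment]
        if not members:
            warnings.warn(f"population {pop!r} has no retained strains; row omitted")
            continue
        counts = np.zeros(len(hap_ids))
        for s in members:
            counts[hap_ids.index(groups.assignment[s])] += 1
        rows[pop] = counts / counts.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=hap_ids)
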