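"""Mosaic local-ancestry inference for admixed haplotypes.

An admixed haplotype (here: an SH_TEJ weed haplotype) is modelled as an
optimal mosaic of reference-panel haplotypes from its two putative source
populations (BH weeds and modern TEJ crops).  The per-haplotype problem is
the exact dynamic program

    minimize  sum_s mismatch(s, k_s) + lambda * #{s : k_s != k_{s-1}}

over assignments of one panel haplotype k_s per site s; the source label of
the copied haplotype gives the local ancestry.  No genetic map,
recombination rate or admixture-time parameter is required — the switch
penalty lambda is swept over a grid and panels are bootstrap-resampled
("bagging"), with a per-site majority vote over all runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .io import HaplotypeMatrix

__all__ = [
    "MosaicPath",
    "AncestryMatrix",
    "solve_mosaic",
    "infer_ancestry",
    "ancestry_summary",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass
class MosaicPath:
    """Optimal copying path for one query haplotype.

    ``ref_index`` indexes the concatenated panel (A first, then B);
    ``source`` is 0 for panel A, 1 for panel B, per site.
    """

    ref_index: np.ndarray
    source: np.ndarray
    cost: float
    switches: int
    mismatches: int


@dataclass
class AncestryMatrix:
    """Per-haplotype, per-site source labels for admixed individuals.

    ``labels`` is (n_haplotypes, n_sites) with 0 = source A, 1 = source B;
    consecutive row pairs belong to one diploid individual.  ``vote_a`` is
    the fraction of (lambda x bag) runs voting source A.
    """

    labels: np.ndarray
    vote_a: np.ndarray
    haplotype_names: list[str]
    source_a: str
    source_b: str
    sites: pd.DataFrame

    def fraction_a(self) -> np.ndarray:
        """Per-haplotype genome-wide fraction assigned to source A."""
        return 1.0 - self.labels.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        names = {0: self.source_a, 1: self.source_b}
        for i, h in enumerate(self.haplotype_names):
            for j in range(self.labels.shape[1]):
                recs.append({
                    "haplotype": h, "chrom": chrom[j], "pos": int(pos[j]),
                    "label": names[int(self.labels[i, j])],
                    "vote_fraction": float(self.vote_a[i, j]),
                })
        return pd.DataFrame(recs)


@njit(cache=True)
def _dp_mosaic(query, refs, lam):  # pragma: no cover - exercised via wrapper
    S = query.shape[0]
    K = refs.shape[0]
    cost = np.zeros(K)
    choice = np.zeros((S, K), dtype=np.int32)
    for k in range(K):
        q = query[0]
        r = refs[k, 0]
        cost[k] = 1.0 if (q != -1 and r != -1 and q != r) else 0.0
        choice[0, k] = k
    for s in range(1, S):
        best_prev = cost[0]
        arg_prev = 0
        for k in range(1, K):
            if cost[k] < best_prev:
                best_prev = cost[k]
                arg_prev = k
        new = np.empty(K)
        q = query[s]
        for k in range(K):
            stay = cost[k]
            switch = best_prev + lam
            if stay <= switch:  # tie broken toward no-switch
                base = stay
                choice[s, k] = k
            else:
                base = switch
                choice[s, k] = arg_prev
            r = refs[k, s]
            miss = 1.0 if (q != -1 and r != -1 and q != r) else 0.0
            new[k] = base + miss
        cost = new
    best = 0
    best_cost = cost[0]
    for k in range(1, K):
        if cost[k] < best_cost:
            best_cost = cost[k]
            best = k
    path = np.empty(S, dtype=np.int32)
    k = best
    for s in range(S - 1, -1, -1):
        path[s] = k
        k = choice[s, k]
    return path, best_cost


def solve_mosaic(query: np.ndarray, panel_a: np.ndarray, panel_b: np.ndarray,
                 lam: float) -> MosaicPath:
    """Exact optimal mosaic of one query over two reference panels.

    Ties are broken toward no-switch, then toward the lowest haplotype index
    in the concatenated (A then B) panel.  Missing query or reference
    alleles contribute zero mismatch (uninformative).
    """
    if lam < 0:
        raise ValueError("switch penalty must be non-negative")
    panel_a = np.asarray(panel_a, dtype=np.int8)
    panel_b = np.asarray(panel_b, dtype=np.int8)
    query = np.asarray(query, dtype=np.int8)
    if panel_a.size == 0 or panel_b.size == 0:
        raise ValueError("both panels must be non-empty")
    if panel_a.shape[1] != query.shape[0] or panel_b.shape[1] != query.shape[0]:
        raise ValueError("panels and query must share the site count")
    refs = np.concatenate([panel_a, panel_b], axis=0)
    path, cost = _dp_mosaic(query, refs, float(lam))
    source = (path >= panel_a.shape[0]).astype(np.int8)
    switches = int(np.sum(path[1:] != path[:-1]))
    mism = int(round(cost - lam * switches))
    return MosaicPath(ref_index=path, source=source, cost=float(cost),
                      switches=switches, mismatches=mism)


def infer_ancestry(
    queries: np.ndarray,
    panel_a: np.ndarray,
    panel_b: np.ndarray,
    lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_bags: int = 20,
    seed: int = 0,
    balance: bool = True,
    haplotype_names: list[str] | None = None,
    source_a: str = "A",
    source_b: str = "B",
    sites: pd.DataFrame | None = None,
) -> AncestryMatrix:
    """Bagged majority-vote local ancestry for a set of query haplotypes.

    For every lambda in ``lam_grid`` and every bag, the panels are resampled
    with replacement (with ``n_bags == 1`` the panels are used as-is) and
    the exact mosaic solved; the per-site label is the majority vote.  With
    ``balance=True`` the larger panel is subsampled (without replacement) to
    the size of the smaller before bagging, mirroring the source-panel
    balancing used when panel sizes are unequal.
    """
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    queries = np.atleast_2d(np.asarray(queries, dtype=np.int8))
    panel_a = np.asarray(panel_a, dtype=np.int8)
    panel_b = np.asarray(panel_b, dtype=np.int8)
    rng = np.random.default_rng(seed)
    if balance and panel_a.shape[0] != panel_b.shape[0]:
        k = min(panel_a.shape[0], panel_b.shape[0])
        if panel_a.shape[0] > k:
            panel_a = panel_a[rng.choice(panel_a.shape[0], size=k, replace=False)]
        else:
            panel_b = panel_b[rng.choice(panel_b.shape[0], size=k, replace=False)]
    nq, S = queries.shape
    votes_b = np.zeros((nq, S), dtype=np.int32)
    n_runs = 0
    for lam in lam_grid:
        for _ in range(n_bags):
            if n_bags == 1:
                pa, pb = panel_a, panel_b
            else:
                pa = panel_a[rng.integers(0, panel_a.shape[0], panel_a.shape[0])]
                pb = panel_b[rng.integers(0, panel_b.shape[0], panel_b.shape[0])]
            for i in range(nq):
                votes_b[i] += solve_mosaic(queries[i], pa, pb, lam).source
            n_runs += 1
    vote_a = 1.0 - votes_b / n_runs
    labels = (vote_a < 0.5).astype(np.int8)  # majority A unless B wins
    if haplotype_names is None:
        haplotype_names = [f"hap{i}" for i in range(nq)]
    if sites is None:
        sites = pd.DataFrame({"chrom": ["chrU"] * S, "pos": np.arange(1, S + 1)})
    return AncestryMatrix(labels, vote_a, haplotype_names, source_a, source_b, sites)


def ancestry_summary(amatrix: AncestryMatrix,
                     regions: list | None = None) -> pd.DataFrame:
    """Mean source-A ancestry fraction per chromosome and, optionally, per
    region (e.g. F_ST outlier regions); the genome-wide row is labelled
    ``genome``."""
    chrom = amatrix.sites["chrom"].to_numpy()
    pos0 = amatrix.sites["pos"].to_numpy() - 1
    frac_a = 1.0 - amatrix.labels  # 1 where source A
    rows = [{
        "scope": "genome", "chrom": "*", "start": -1, "end": -1,
        "mean_fraction_a": float(frac_a.mean()),
        "n_sites": int(amatrix.labels.shape[1]),
    }]
    for c in dict.fromkeys(chrom):
        m = chrom == c
        rows.append({
            "scope": "chromosome", "chrom": c, "start": -1, "end": -1,
            "mean_fraction_a": float(frac_a[:, m].mean()),
            "n_sites": int(m.sum()),
        })
    for r in regions or []:
        m = (chrom == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        if not m.any():
            continue
        rows.append({
            "scope": "region", "chrom": r.chrom, "start": int(r.start),
            "end": int(r.end),
            "mean_fraction_a": float(frac_a[:, m].mean()),
            "n_sites": int(m.sum()),
        })
    return pd.DataFrame(rows)


def extract_panels(matrix: HaplotypeMatrix, popmap, admixed: str,
                   source_a: str, source_b: str):
    """Convenience split of a :class:`HaplotypeMatrix` into query haplotypes
    and the two source panels (row blocks of the allele matrix)."""
    rows_q = popmap.haplotype_indices(matrix, admixed)
    rows_a = popmap.haplotype_indices(matrix, source_a)
    rows_b = popmap.haplotype_indices(matrix, source_b)
    names = []
    for r in rows_q:
        names.append(f"{matrix.sample_of_haplotype(int(r))}_h{int(r) % 2 + 1}")
    return (matrix.alleles[rows_q], matrix.alleles[rows_a],
            matrix.alleles[rows_b], names)
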