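"""Extended haplotype homozygosity statistics: EHH, iHH, iHS and XP-EHH.

EHH at a flanking site x, for the carriers of a core allele, is the
probability that two randomly chosen carrier haplotypes are identical over
the span from the core to x: sum_h C(n_h,2) / C(n_c,2) over distinct
extended haplotypes h.  iHH integrates the EHH decay curve over physical
distance (trapezoid, bp units, no genetic map).  iHS is the log-ratio of
ancestral to derived iHH at a site, standardized within derived-allele
frequency bins; XP-EHH is the cross-population analogue with pooled-allele
EHH per population, standardized genome-wide.  Two-sided normal p-values
are reported as -log10(p); the conventional significance threshold
-log10(p) > 4 corresponds to |standardized score| > ~3.89.

Haplotypes with a missing allele anywhere in the current span are dropped
from that span's pair counts (and from its denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import MISSING, HaplotypeMatrix, PopulationMap

__all__ = [
    "EHHCurve",
    "IhhResult",
    "ScoreTrack",
    "ehh",
    "ihh",
    "ihs",
    "xpehh",
    "crop_major_ancestral",
]


@dataclass
class EHHCurve:
    """EHH decay around a core site, per core allele.

    ``curves`` maps core allele -> (site indices, EHH values); indices are
    sorted ascending and include the core itself (EHH = 1 there).
    """

    core: int
    curves: dict[int, tuple[np.ndarray, np.ndarray]]
    carrier_counts: dict[int, int]


@dataclass
class IhhResult:
    """Integrated EHH per core allele, with truncation flags."""

    per_allele: dict[int, float]
    edge_truncated: dict[int, bool] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.per_allele[a] for a in sorted(self.per_allele))


@dataclass
class ScoreTrack:
    """Per-site selection scores.

    ``table`` columns: chrom, pos, freq_derived, score_raw, score_std,
    neglog10p.
    """

    table: pd.DataFrame
    statistic: str = ""

    def significant(self, threshold: float = 4.0) -> pd.DataFrame:
        return self.table[self.table["neglog10p"] > threshold]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _pair_fraction(group_sizes: np.ndarray, n: int) -> float:
    if n < 2:
        return 0.0
    num = np.sum(group_sizes * (group_sizes - 1)) / 2.0
    return float(num / (n * (n - 1) / 2.0))


def _decay(hap: np.ndarray, rows: np.ndarray, core: int, step: int,
           stop_below: float = 0.0):
    """Yield (site index, EHH) walking from the core in ``step`` direction.

    ``rows`` are the haplotype rows forming the initial pool (already
    restricted to carriers for allele-conditioned EHH, or grouped by core
    allele for pooled EHH via ``init_groups``).  Stops once EHH < stop_below
    (the crossing point is still yielded) or the chromosome end is reached.
    """
    n_sites = hap.shape[1]
    active = rows.copy()
    groups = np.zeros(len(active), dtype=np.int64)
    j = core
    while True:
        j += step
        if j < 0 or j >= n_sites:
            return
        col = hap[active, j]
        keep = col != MISSING
        if not np.all(keep):
            active = active[keep]
            groups = groups[keep]
            col = col[keep]
        if len(active) < 2:
            yield j, 0.0
            return
        _, groups = np.unique(
            np.stack([groups, col.astype(np.int64)]), axis=1, return_inverse=True
        )
        sizes = np.bincount(groups)
        e = _pair_fraction(sizes, len(active))
        yield j, e
        if e < stop_below:
            return


def ehh(haplotypes: np.ndarray, core: int, allele: int | None = None) -> EHHCurve:
    """Full EHH decay curve(s) around ``core`` for a single-chromosome
    haplotype block (rows = haplotypes, columns = sites).

    With ``allele=None`` both core alleles are computed.  An allele with
    fewer than two non-missing carriers is undefined and omitted.
    """
    hap = np.asarray(haplotypes)
    alleles = (0, 1) if allele is None else (allele,)
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    counts: dict[int, int] = {}
    for al in alleles:
        rows = np.flatnonzero(hap[:, core] == al)
        counts[al] = len(rows)
        if len(rows) < 2:
            continue
        idx = [core]
        val = [1.0]
        for j, e in _decay(hap, rows, core, -1):
            idx.append(j)
            val.append(e)
        idx.reverse()
        val.reverse()
        for j, e in _decay(hap, rows, core, +1):
            idx.append(j)
            val.append(e)
        curves[al] = (np.asarray(idx), np.asarray(val))
    if not curves:
        raise ValueError("core allele has fewer than two carriers")
    return EHHCurve(core=core, curves=curves, carrier_counts=counts)


def _integrate_one_side(pos: np.ndarray, val: np.ndarray, cutoff: float,
                        max_gap: float) -> tuple[float, bool]:
    """Trapezoid from the core outward; ``pos``/``val`` start at the core.

    Integration includes the first segment whose far end drops below the
    cutoff, then stops; a gap wider than ``max_gap`` truncates before the
    gap.  Returns (area, reached_end_above_cutoff)."""
    area = 0.0
    for k in range(1, len(pos)):
        d = abs(float(pos[k]) - float(pos[k - 1]))
        if d > max_gap:
            return area, False
        area += d * (float(val[k]) + float(val[k - 1])) / 2.0
        if val[k] < cutoff:
            return area, False
    return area, True


def ihh(curve: EHHCurve, positions: np.ndarray, cutoff: float = 0.05,
        max_gap: float = 200_000.0) -> IhhResult:
    """Integrated EHH (bp x EHH units) per core allele, both directions."""
    positions = np.asarray(positions, dtype=float)
    per: dict[int, float] = {}
    edge: dict[int, bool] = {}
    for al, (idx, val) in curve.curves.items():
        k0 = int(np.flatnonzero(idx == curve.core)[0])
        left_a, left_edge = _integrate_one_side(
            positions[idx[k0::-1]], val[k0::-1], cutoff, max_gap
        )
        right_a, right_edge = _integrate_one_side(
            positions[idx[k0:]], val[k0:], cutoff, max_gap
        )
        per[al] = left_a + right_a
        edge[al] = left_edge or right_edge
    return IhhResult(per_allele=per, edge_truncated=edge)


def crop_major_ancestral(matrix: HaplotypeMatrix, popmap: PopulationMap,
                         crop_groups: tuple[str, ...]) -> np.ndarray:
    """Per-site ancestral allele (0/1): the major allele across the pooled
    crop groups (ties resolved to the reference allele)."""
    rows = popmap.haplotype_indices(matrix, *crop_groups)
    al = matrix.alleles[rows]
    ones = np.sum(al == 1, axis=0)
    called = np.sum(al != MISSING, axis=0)
    return (ones * 2 > called).astype(np.int8)


def _truncated_ihh(hap, pos, rows, core, cutoff, max_gap):
    """One-allele iHH by incremental decay, stopping once EHH < cutoff."""
    total = 0.0
    edge = False
    for step in (-1, +1):
        prev_p = float(pos[core])
        prev_e = 1.0
        stopped = False
        for j, e in _decay(hap, rows, core, step, stop_below=cutoff):
            d = abs(float(pos[j]) - prev_p)
            if d > max_gap:
                stopped = True
                break
            total += d * (e + prev_e) / 2.0
            prev_p, prev_e = float(pos[j]), e
            if e < cutoff:
                stopped = True
                break
        if not stopped:
            edge = True
    return total, edge


def _standardize(raw: np.ndarray, freq: np.ndarray, n_bins: int,
                 min_bin: int) -> np.ndarray:
    """Frequency-binned standardization; bins with < min_bin sites are merged
    with their neighbour.  With n_bins == 1 this is genome-wide."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)
    # merge sparse bins leftward (rightward for the first)
    sizes = np.bincount(which, minlength=n_bins)
    remap = np.arange(n_bins)
    for b in range(n_bins):
        if 0 < sizes[b] < min_bin:
            tgt = b - 1 if b > 0 else b + 1
            while tgt > 0 and sizes[remap[tgt]] == 0:
                tgt -= 1
            remap[b] = remap[tgt] if 0 <= tgt < n_bins else b
    which = remap[which]
    out = np.empty_like(raw)
    for b in np.unique(which):
        sel = which == b
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        out[sel] = (raw[sel] - mu) / sd if sd > 0 else 0.0
    return out


def _finalize_track(records: list[dict], statistic: str, n_bins: int,
                    min_bin: int) -> ScoreTrack:
    cols = ["chrom", "pos", "freq_derived", "score_raw", "score_std", "neglog10p"]
    if not records:
        return ScoreTrack(pd.DataFrame(columns=cols), statistic)
    table = pd.DataFrame(records)
    raw = table["score_raw"].to_numpy(dtype=float)
    freq = table["freq_derived"].to_numpy(dtype=float)
    std = _standardize(raw, freq, n_bins, min_bin)
    with np.errstate(divide="ignore"):
        p = 2.0 * norm.sf(np.abs(std))
        neglog = -np.log10(np.maximum(p, 1e-300))
    table["score_std"] = std
    table["neglog10p"] = neglog
    return ScoreTrack(table[cols], statistic)


def ihs(matrix: HaplotypeMatrix, popmap: PopulationMap, population: str,
        ancestral: np.ndarray | None = None, cutoff: float = 0.05,
        max_gap: float = 200_000.0, freq_range: tuple[float, float] = (0.05, 0.95),
        n_bins: int = 20, min_bin: int = 10) -> ScoreTrack:
    """Within-population iHS: ln(iHH_ancestral / iHH_derived) per site,
    standardized within derived-allele-frequency bins.

    ``ancestral`` gives the ancestral allele (0/1) per site; ``None`` uses
    reference-allele polarization (ancestral = 0).  Sites with derived
    frequency outside ``freq_range`` or with a zero iHH are skipped.
    """
    rows = popmap.haplotype_indices(matrix, population)
    if ancestral is None:
        ancestral = np.zeros(matrix.n_sites, dtype=np.int8)
    records: list[dict] = []
    offset = 0
    for chrom in matrix.chromosomes:
        mask = matrix.site_mask(chrom)
        hap = matrix.alleles[np.ix_(rows, np.flatnonzero(mask))]
        pos = matrix.sites.loc[mask, "pos"].to_numpy(dtype=float)
        anc = ancestral[mask]
        for j in range(hap.shape[1]):
            col = hap[:, j]
            called = col != MISSING
            n = int(called.sum())
            if n < 2:
                continue
            der = 1 - int(anc[j])
            f_der = float(np.sum(col[called] == der) / n)
            if not (freq_range[0] <= f_der <= freq_range[1]):
                continue
            rows_a = np.flatnonzero(col == anc[j])
            rows_d = np.flatnonzero(col == der)
            if len(rows_a) < 2 or len(rows_d) < 2:
                continue
            ihh_a, _ = _truncated_ihh(hap, pos, rows_a, j, cutoff, max_gap)
            ihh_d, _ = _truncated_ihh(hap, pos, rows_d, j, cutoff, max_gap)
            if ihh_a <= 0 or ihh_d <= 0:
                continue
            records.append({
                "chrom": chrom, "pos": int(pos[j]), "freq_derived": f_der,
                "score_raw": math.log(ihh_a / ihh_d),
            })
        offset += hap.shape[1]
    return _finalize_track(records, "iHS", n_bins, min_bin)


def _pooled_ihh(hap, pos, core, cutoff, max_gap):
    """Population-pooled iHH: haplotypes partitioned by core allele (the
    core site is part of the identity span), integrated both ways."""
    col = hap[:, core]
    rows = np.flatnonzero(col != MISSING)
    if len(rows) < 2:
        return 0.0
    total = 0.0
    for step in (-1, +1):
        active = rows.copy()
        groups = col[active].astype(np.int64)
        sizes = np.bincount(np.unique(groups, return_inverse=True)[1])
        prev_e = _pair_fraction(sizes, len(active))
        prev_p = float(pos[core])
        j = core
        n_sites = hap.shape[1]
        while prev_e >= cutoff:
            j += step
            if j < 0 or j >= n_sites:
                break
            c = hap[active, j]
            keep = c != MISSING
            active, groups, c = active[keep], groups[keep], c[keep]
            if len(active) < 2:
                e = 0.0
            else:
                _, groups = np.unique(
                    np.stack([groups, c.astype(np.int64)]), axis=1,
                    return_inverse=True,
                )
                e = _pair_fraction(np.bincount(groups), len(active))
            d = abs(float(pos[j]) - prev_p)
            if d > max_gap:
                break
            total += d * (e + prev_e) / 2.0
            prev_p, prev_e = float(pos[j]), e
    return total


def xpehh(matrix: HaplotypeMatrix, popmap: PopulationMap,
          pop_a: str | tuple[str, ...], pop_b: str | tuple[str, ...],
          cutoff: float = 0.05, max_gap: float = 200_000.0,
          freq_range: tuple[float, float] = (0.05, 0.95)) -> ScoreTrack:
    """Cross-population XP-EHH: ln(iHH_popA / iHH_popB) with pooled-allele
    EHH per population, standardized genome-wide (single bin).

    Positive scores indicate longer haplotype homozygosity in ``pop_a``.
    """
    ga = (pop_a,) if isinstance(pop_a, str) else tuple(pop_a)
    gb = (pop_b,) if isinstance(pop_b, str) else tuple(pop_b)
    rows_a = popmap.haplotype_indices(matrix, *ga)
    rows_b = popmap.haplotype_indices(matrix, *gb)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both populations need at least two haplotypes")
    records: list[dict] = []
    for chrom in matrix.chromosomes:
        mask = matrix.site_mask(chrom)
        cols = np.flatnonzero(mask)
        hap_a = matrix.alleles[np.ix_(rows_a, cols)]
        hap_b = matrix.alleles[np.ix_(rows_b, cols)]
        pos = matrix.sites.loc[mask, "pos"].to_numpy(dtype=float)
        both = np.concatenate([hap_a, hap_b])
        for j in range(hap_a.shape[1]):
            col = both[:, j]
            called = col != MISSING
            n = int(called.sum())
            if n < 4:
                continue
            f = float(np.sum(col[called] == 1) / n)
            if not (freq_range[0] <= f <= freq_range[1]):
                continue
            ia = _pooled_ihh(hap_a, pos, j, cutoff, max_gap)
            ib = _pooled_ihh(hap_b, pos, j, cutoff, max_gap)
            if ia <= 0 or ib <= 0:
                continue
            records.append({
                "chrom": chrom, "pos": int(pos[j]), "freq_derived": f,
                "score_raw": math.log(ia / ib),
            })
    return _finalize_track(records, "XP-EHH", n_bins=1, min_bin=1)
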