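"""Windowed Weir-Cockerham F_ST scans, outlier regions and their algebra.

The scan follows the standard de-domestication design: differentiation
between a weed group and the pooled set of its potential crop ancestors is
estimated per sliding window (ratio-of-sums over the Weir & Cockerham 1984
variance components a, b, c), the window values are Z-transformed, and
windows at least ``m`` absolute median deviations above the median of Z
(upper tail, unscaled MAD, default m = 5) are flagged significant.
Contiguous significant windows are merged into outlier regions; two scans
can be intersected to find regions differentiated in both weed lineages
("de-domestication blocks").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HaplotypeMatrix, PopulationMap, WindowGrid

__all__ = [
    "WindowScan",
    "OutlierRegion",
    "site_components",
    "window_fst",
    "call_outliers",
    "merge_regions",
    "genome_fraction",
    "intersect_scans",
    "chromosome_tally",
]


@dataclass
class WindowScan:
    """Per-window scan results.

    ``table`` columns: chrom, start, end (0-based half-open bp), n_sites,
    fst, z, significant.  F_ST is NaN for windows with too few usable sites;
    such windows are excluded from the Z-transformation.
    """

    table: pd.DataFrame
    group_a: str = ""
    group_b: str = ""
    mad_threshold: float | None = None

    @property
    def defined(self) -> pd.DataFrame:
        return self.table[self.table["fst"].notna()]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["start"] = out["start"] + 1  # 1-based inclusive on disk
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True, order=True)
class OutlierRegion:
    """A merged run of significant windows (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    max_z: float = float("nan")
    windows: tuple[int, ...] = field(default=(), compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) two-population variance components


def site_components(n1, p1, h1, n2, p2, h2):
    """Per-site variance components (a, b, c) for two populations.

    Parameters are per population: ``n`` diploid sample size, ``p`` ALT
    allele frequency and ``h`` observed heterozygote frequency; all may be
    scalars or equal-length arrays.  Components follow the two-population
    (r = 2) Weir-Cockerham formulas; sites monomorphic across both
    populations return (0, 0, 0).  Sites where either population has fewer
    than two genotypes are invalid (NaN components) and must be skipped by
    the caller.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    mono = (p_bar <= 0.0) | (p_bar >= 1.0)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    if a.ndim == 0:
        return float(a), float(b), float(c)
    return a, b, c


def _pop_site_stats(matrix: HaplotypeMatrix, rows: np.ndarray):
    """Diploid n, ALT frequency and observed het frequency per site for the
    samples owning haplotype rows ``rows`` (missing genotypes excluded)."""
    a = matrix.alleles[rows[0::2]]
    b = matrix.alleles[rows[1::2]]
    ok = (a >= 0) & (b >= 0)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, a + b, 0).sum(axis=0) / (2.0 * n)
        h = np.where(ok & (a != b), 1, 0).sum(axis=0) / n
    return n, p, h


def window_fst(
    matrix: HaplotypeMatrix,
    popmap: PopulationMap,
    grid: WindowGrid,
    group_a: str | tuple[str, ...],
    group_b: str | tuple[str, ...],
    min_sites: int = 5,
) -> WindowScan:
    """Windowed ratio-of-sums F_ST = sum(a) / sum(a+b+c) between two groups.

    Either group may be a tuple of population labels, which are pooled
    (e.g. a weed group against modern + landrace crops together).  Windows
    with fewer than ``min_sites`` usable polymorphic sites are left
    undefined (NaN).
    """
    ga = (group_a,) if isinstance(group_a, str) else tuple(group_a)
    gb = (group_b,) if isinstance(group_b, str) else tuple(group_b)
    rows_a = popmap.haplotype_indices(matrix, *ga)
    rows_b = popmap.haplotype_indices(matrix, *gb)
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("both groups must be non-empty")

    n1, p1, h1 = _pop_site_stats(matrix, rows_a)
    n2, p2, h2 = _pop_site_stats(matrix, rows_b)
    a, b, c = site_components(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    usable = np.isfinite(denom) & (denom > 0)

    pos0 = matrix.sites["pos"].to_numpy() - 1  # 0-based site coords
    chrom_col = matrix.sites["chrom"].to_numpy()
    records = []
    for chrom, wins in grid.windows.items():
        on_chrom = chrom_col == chrom
        cpos = pos0[on_chrom]
        ca = np.where(usable[on_chrom], a[on_chrom], 0.0)
        cd = np.where(usable[on_chrom], denom[on_chrom], 0.0)
        cu = usable[on_chrom]
        # windows are sorted by start; sites sorted by pos
        cum_a = np.concatenate([[0.0], np.cumsum(ca)])
        cum_d = np.concatenate([[0.0], np.cumsum(cd)])
        cum_n = np.concatenate([[0], np.cumsum(cu.astype(int))])
        lo = np.searchsorted(cpos, wins[:, 0], side="left")
        hi = np.searchsorted(cpos, wins[:, 1], side="left")
        for k, (start, end) in enumerate(wins):
            ns = int(cum_n[hi[k]] - cum_n[lo[k]])
            da = cum_a[hi[k]] - cum_a[lo[k]]
            dd = cum_d[hi[k]] - cum_d[lo[k]]
            fst = da / dd if (ns >= min_sites and dd > 0) else np.nan
            records.append(
                {"chrom": chrom, "start": int(start), "end": int(end),
                 "n_sites": ns, "fst": fst, "z": np.nan, "significant": False}
            )
    table = pd.DataFrame(records)
    return WindowScan(table, group_a="+".join(ga), group_b="+".join(gb))


def call_outliers(scan: WindowScan, m: float = 5.0) -> WindowScan:
    """Z-transform defined windows and flag the upper MAD tail.

    Z = (F_ST - mean)/sd over defined windows; a window is significant iff
    Z - median(Z) >= m * MAD(Z) with the unscaled MAD (median of absolute
    deviations, no 1.4826 factor).  A degenerate (zero-MAD) score
    distribution raises rather than flagging everything.
    """
    table = scan.table.copy()
    defined = table["fst"].notna()
    if int(defined.sum()) < 10:
        raise ValueError("need at least 10 defined windows to call outliers")
    fst = table.loc[defined, "fst"].to_numpy(dtype=float)
    sd = fst.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    z = (fst - fst.mean()) / sd
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    if mad == 0:
        raise ValueError("degenerate score distribution (zero MAD)")
    table.loc[defined, "z"] = z
    table.loc[defined, "significant"] = (z - med) >= m * mad
    table["significant"] = table["significant"].fillna(False).astype(bool)
    return WindowScan(table, scan.group_a, scan.group_b, mad_threshold=m)


def _finite_max(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(max(vals)) if vals else float("nan")


def merge_regions(scan: WindowScan) -> list[OutlierRegion]:
    """Merge overlapping/abutting significant windows into outlier regions.

    With a step smaller than the window size, consecutive significant
    windows always overlap, so runs of contiguous significance become one
    region whose interval is the union of its member windows.
    """
    sig = scan.significant
    regions: list[OutlierRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        cur_windows: list[int] = []
        cur_z: list[float] = []
        for idx, row in sub.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if cur_start is None:
                cur_start, cur_end = s, e
                cur_windows, cur_z = [idx], [row["z"]]
            elif s <= cur_end:  # overlap or abut (gap 0)
                cur_end = max(cur_end, e)
                cur_windows.append(idx)
                cur_z.append(row["z"])
            else:
                regions.append(OutlierRegion(chrom, cur_start, cur_end,
                                             _finite_max(cur_z),
                                             tuple(cur_windows)))
                cur_start, cur_end = s, e
                cur_windows, cur_z = [idx], [row["z"]]
        if cur_start is not None:
            regions.append(OutlierRegion(chrom, cur_start, cur_end,
                                         _finite_max(cur_z),
                                         tuple(cur_windows)))
    return sorted(regions)


def genome_fraction(regions: list[OutlierRegion],
                    chrom_lengths: dict[str, int]) -> float:
    """Total region length as a percentage of total genome length."""
    total = sum(chrom_lengths.values())
    if total <= 0:
        raise ValueError("empty genome")
    covered = 0
    for r in regions:
        if r.chrom in chrom_lengths and not (
            0 <= r.start < r.end <= chrom_lengths[r.chrom]
        ):
            raise ValueError(f"region outside chromosome bounds: {r}")
        covered += r.length
    return 100.0 * covered / total


def intersect_scans(regions_a: list[OutlierRegion],
                    regions_b: list[OutlierRegion]) -> list[OutlierRegion]:
    """Maximal intervals covered by outlier regions in both scans."""
    out: list[OutlierRegion] = []
    by_chrom_b: dict[str, list[OutlierRegion]] = {}
    for r in regions_b:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    for ra in sorted(regions_a):
        for rb in sorted(by_chrom_b.get(ra.chrom, [])):
            s, e = max(ra.start, rb.start), min(ra.end, rb.end)
            if s < e:
                out.append(OutlierRegion(ra.chrom, s, e,
                                         _finite_max([ra.max_z, rb.max_z])))
    return sorted(out)


def chromosome_tally(regions: list[OutlierRegion]) -> pd.DataFrame:
    """Per-chromosome region counts with percentages of the total count."""
    counts: dict[str, int] = {}
    for r in regions:
        counts[r.chrom] = counts.get(r.chrom, 0) + 1
    total = sum(counts.values())
    rows = [
        {"chrom": c, "n_regions": n, "percent": 100.0 * n / total}
        for c, n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=["chrom", "n_regions", "percent"])
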