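"""Weir-Cockerham components, windowed scans, outlier calling and region algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralscan.fst import (
    OutlierRegion,
    WindowScan,
    call_outliers,
    chromosome_tally,
    genome_fraction,
    intersect_scans,
    merge_regions,
    site_components,
    window_fst,
)
from feralscan.io import HaplotypeMatrix, PopulationMap, make_windows


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Independent scalar transcription of the Weir & Cockerham (1984)
    two-population variance components, written directly from the published
    formulas with r = 2."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestSiteComponents:
    def test_no_differentiation_gives_zero_a(self):
        # equal frequencies and heterozygosity: the among-population
        # component vanishes in the large-sample limit (finite-sample a
        # carries a small negative bias correction)
        a_large, _, _ = site_components(100_000, 0.4, 0.3, 100_000, 0.4, 0.3)
        assert a_large == pytest.approx(0.0, abs=1e-4)
        a_small, b, c = site_components(10, 0.4, 0.3, 10, 0.4, 0.3)
        assert abs(a_small) < 0.02 and a_small <= 0.0

    def test_fixed_difference_gives_fst_one(self):
        a, b, c = site_components(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_monomorphic_across_both_returns_zeros(self):
        assert site_components(8, 0.0, 0.0, 6, 0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, size=2)
            g1 = rng.integers(0, 3, size=n1)  # genotype dosages
            g2 = rng.integers(0, 3, size=n2)
            p1, p2 = g1.mean() / 2, g2.mean() / 2
            h1, h2 = float((g1 == 1).mean()), float((g2 == 1).mean())
            got = site_components(n1, p1, h1, n2, p2, h2)
            if 0 < (n1 * p1 + n2 * p2) < n1 + n2:  # polymorphic overall
                want = wc_oracle(n1, p1, h1, n2, p2, h2)
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_undersized_population_flagged_nan(self):
        a, b, c = site_components(1, 0.5, 1.0, 10, 0.2, 0.1)
        assert np.isnan(a) and np.isnan(b) and np.isnan(c)


def _one_window_matrix(columns, samples_per_pop=3):
    """Haplotype matrix over one 1-kb window; `columns` is (2N, S)."""
    al = np.asarray(columns, dtype=np.int8)
    n_sites = al.shape[1]
    sites = pd.DataFrame({
        "chrom": ["c"] * n_sites,
        "pos": np.arange(1, n_sites + 1) * 10,
        "ref": ["A"] * n_sites, "alt": ["G"] * n_sites,
    })
    n = al.shape[0] // 2
    samples = [f"s{i}" for i in range(n)]
    popmap = PopulationMap({
        s: ("p1" if i < samples_per_pop else "p2")
        for i, s in enumerate(samples)
    })
    return HaplotypeMatrix(al, sites, samples), popmap


class TestWindowFst:
    def test_all_monomorphic_leaves_windows_undefined(self):
        m, pm = _one_window_matrix(np.zeros((12, 6)))
        grid = make_windows({"c": 1000}, 1000, 1000)
        scan = window_fst(m, pm, grid, "p1", "p2", min_sites=1)
        assert scan.table["fst"].isna().all()

    def test_single_site_window_equals_site_ratio(self):
        rng = np.random.default_rng(5)
        al = rng.integers(0, 2, size=(12, 1)).astype(np.int8)
        m, pm = _one_window_matrix(al)
        grid = make_windows({"c": 1000}, 1000, 1000)
        scan = window_fst(m, pm, grid, "p1", "p2", min_sites=1)
        dos_a = al[:6:2, 0] + al[1:6:2, 0]
        dos_b = al[6::2, 0] + al[7::2, 0]
        a, b, c = site_components(3, dos_a.mean() / 2, (dos_a == 1).mean(),
                                  3, dos_b.mean() / 2, (dos_b == 1).mean())
        assert scan.table["fst"].iloc[0] == pytest.approx(a / (a + b + c))

    def test_unknown_group_rejected(self, demo_sim):
        grid = make_windows(demo_sim.chrom_lengths, 100_000, 10_000)
        with pytest.raises(KeyError):
            window_fst(demo_sim.matrix, demo_sim.popmap, grid, "BH", "nope")

    def test_simulated_fst_matches_branch_parameter(self, demo_sim):
        """Genome-median window F_ST tracks the generator's BH/crop branch
        divergence (~0.04 under the demo branch parameters)."""
        grid = make_windows(demo_sim.chrom_lengths, 100_000, 10_000)
        scan = window_fst(demo_sim.matrix, demo_sim.popmap, grid,
                          "BH", ("TEJ_modern", "TEJ_landrace"))
        med = scan.defined["fst"].median()
        assert 0.0 < med < 0.12

    def test_weighted_estimator_not_strongly_negative(self, demo_sim):
        grid = make_windows(demo_sim.chrom_lengths, 100_000, 10_000)
        scan = window_fst(demo_sim.matrix, demo_sim.popmap, grid,
                          "BH", ("TEJ_modern", "TEJ_landrace"))
        fst = scan.defined["fst"]
        assert (fst >= -0.05).all() and (fst <= 1.0).all()


def _scan_from_scores(fst_values, width=1000):
    table = pd.DataFrame({
        "chrom": "c",
        "start": np.arange(len(fst_values)) * width,
        "end": (np.arange(len(fst_values)) + 1) * width,
        "n_sites": 10,
        "fst": fst_values,
        "z": np.nan,
        "significant": False,
    })
    return WindowScan(table)


class TestCallOutliers:
    def test_degenerate_equal_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            call_outliers(_scan_from_scores([0.2] * 50))

    def test_degenerate_mad_zero_error(self):
        scores = [0.1] * 99 + [0.9]  # MAD of Z is 0
        with pytest.raises(ValueError, match="degenerate"):
            call_outliers(_scan_from_scores(scores))

    def test_too_few_windows_error(self):
        with pytest.raises(ValueError, match="10 defined"):
            call_outliers(_scan_from_scores([0.1, 0.2, 0.3]))

    def test_planted_outliers_match_bruteforce_median_mad(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0.1, 0.02, size=10_000)
        planted = np.full(20, 0.1 + 8 * 0.02)
        values = np.concatenate([base, planted])
        scan = call_outliers(_scan_from_scores(values), m=5.0)
        flagged = set(scan.significant.index)
        # brute-force recomputation of the rule on the Z transform
        z = (values - values.mean()) / values.std(ddof=0)
        med = float(np.median(z))
        mad = float(np.median(np.abs(z - med)))
        expect = {i for i, v in enumerate(z) if v - med >= 5.0 * mad}
        assert flagged == expect
        assert set(range(10_000, 10_020)) <= flagged


class TestRegionAlgebra:
    def test_overlapping_windows_merge(self):
        scan = _scan_from_scores([0.5] * 2)
        scan.table.loc[:, ["start", "end"]] = [[0, 100_000], [10_000, 110_000]]
        scan.table["significant"] = True
        (region,) = merge_regions(scan)
        assert (region.start, region.end, region.length) == (0, 110_000, 110_000)

    def test_no_significant_windows_empty(self):
        assert merge_regions(_scan_from_scores([0.1] * 5)) == []

    def test_disjoint_windows_stay_separate(self):
        scan = _scan_from_scores([0.5] * 2)
        scan.table.loc[:, ["start", "end"]] = [[0, 100_000], [500_000, 600_000]]
        scan.table["significant"] = True
        assert len(merge_regions(scan)) == 2

    def test_merge_idempotent_and_coverage_conserving(self, demo_sim):
        from feralscan.fst import window_fst as wf

        grid = make_windows(demo_sim.chrom_lengths, 100_000, 10_000)
        scan = call_outliers(
            wf(demo_sim.matrix, demo_sim.popmap, grid, "BH",
               ("TEJ_modern", "TEJ_landrace")), m=5.0)
        regions = merge_regions(scan)
        # every significant bp is inside some region
        for _, row in scan.significant.iterrows():
            assert any(r.chrom == row["chrom"] and r.start <= row["start"]
                       and row["end"] <= r.end for r in regions)
        # idempotence: intersecting the regions with themselves changes nothing
        again = intersect_scans(regions, regions)
        assert [(r.chrom, r.start, r.end) for r in again] == \
            [(r.chrom, r.start, r.end) for r in regions]


class TestGenomeFraction:
    def test_empty_regions_zero(self):
        assert genome_fraction([], {"c": 1000}) == 0.0

    def test_whole_genome_region(self):
        assert genome_fraction([OutlierRegion("c", 0, 1000)], {"c": 1000}) == 100.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            genome_fraction([OutlierRegion("c", 0, 2000)], {"c": 1000})


class TestIntersect:
    def test_partial_overlap_by_hand(self):
        a = [OutlierRegion("c", 0, 200_000)]
        b = [OutlierRegion("c", 150_000, 300_000)]
        (shared,) = intersect_scans(a, b)
        assert (shared.start, shared.end, shared.length) == \
            (150_000, 200_000, 50_000)

    def test_disjoint_empty(self):
        a = [OutlierRegion("c", 0, 10)]
        b = [OutlierRegion("c", 20, 30)]
        assert intersect_scans(a, b) == []

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)),
                    min_size=0, max_size=8),
           st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)),
                    min_size=0, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, ivs_a, ivs_b):
        def mk(ivs):
            merged = []
            for s, w in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], s + w))
                else:
                    merged.append((s, s + w))
            return [OutlierRegion("c", s, e) for s, e in merged]

        a, b = mk(ivs_a), mk(ivs_b)
        ab = intersect_scans(a, b)
        ba = intersect_scans(b, a)
        assert [(r.start, r.end) for r in ab] == [(r.start, r.end) for r in ba]
        bp = sum(r.length for r in ab)
        assert bp <= min(sum(r.length for r in a) if a else 0,
                         sum(r.length for r in b) if b else 0) or (not a or not b)

    def test_per_chromosome_tally_percentages(self):
        regions = []
        for chrom, n in [("chr07", 29), ("chr01", 10), ("chr02", 9),
                         ("chr03", 18)]:
            regions += [OutlierRegion(chrom, i * 10, i * 10 + 5)
                        for i in range(n)]
        tally = chromosome_tally(regions).set_index("chrom")
        assert tally.loc["chr07", "percent"] == pytest.approx(43.9, abs=0.05)
        assert tally.loc["chr01", "percent"] == pytest.approx(15.2, abs=0.05)
        assert tally.loc["chr02", "percent"] == pytest.approx(13.6, abs=0.05)
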