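"""Coalescent scenario simulator, summaries and ABC model choice."""

import numpy as np
import pandas as pd
import pytest

from feralscan.demography import (
    ScenarioModel,
    abc_model_choice,
    gof_check,
    hybrid_origin_scenarios,
    load_scenarios,
    simulate_scenario,
    summarize,
    toy_split_scenarios,
)
from feralscan.io import HaplotypeMatrix, PopulationMap

SINGLE = ScenarioModel(name="one", populations=["A"], sizes={"A": 10_000.0},
                       events=[], priors={})


def _two_pop(t_split):
    return ScenarioModel(
        name=f"split{t_split}", populations=["A", "B"],
        sizes={"A": 10_000.0, "B": 10_000.0},
        events=[{"type": "split", "time": float(t_split),
                 "derived": "B", "ancestral": "A"}],
    )


def msprime_fixed_s_sfs(n, n_reps, seed):
    """Independent implementation of the fixed-S placement (one mutation per
    genealogy, branch chosen proportionally to length) on msprime trees."""
    import msprime

    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=float)
    reps = msprime.sim_ancestry(samples=n // 2, ploidy=2,
                                population_size=10_000,
                                num_replicates=n_reps, random_seed=seed + 1)
    for ts in reps:
        tree = ts.first()
        u = rng.random() * tree.total_branch_length
        acc = 0.0
        for node in tree.nodes():
            if tree.parent(node) == -1:
                continue
            acc += tree.branch_length(node)
            if u <= acc:
                counts[len(list(tree.samples(node)))] += 1
                break
    return counts[1:n] / n_reps


class TestCoalescentCore:
    def test_sfs_matches_independent_msprime_oracle(self):
        n, reps = 4, 3000
        mat, _ = simulate_scenario(SINGLE, {}, {"A": n}, reps, seed=7)
        mine = np.bincount(mat.alleles.sum(axis=0), minlength=n)[1:n] / reps
        orac = msprime_fixed_s_sfs(n, reps, seed=11)
        se = np.sqrt(mine * (1 - mine) / reps + orac * (1 - orac) / reps)
        assert (np.abs(mine - orac) <= 3 * se).all()
        # qualitative neutral shape: frequency classes decrease like ~1/i
        assert mine[0] > mine[1] > mine[2]

    def test_every_site_segregates(self):
        mat, _ = simulate_scenario(SINGLE, {}, {"A": 8}, 500, seed=1)
        counts = mat.alleles.sum(axis=0)
        assert (counts > 0).all() and (counts < 8).all()

    def test_fst_increases_with_split_time(self):
        means = []
        for t in (500, 2_000, 8_000):
            vals = []
            for rep in range(10):
                mat, pm = simulate_scenario(_two_pop(t), {},
                                            {"A": 10, "B": 10}, 150,
                                            seed=1000 * t + rep)
                vals.append(summarize(mat, pm).as_series()["fst_A_B"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_full_admixture_equals_pure_bh_descent(self):
        """With r = 1 every SH lineage takes the BH side of the pulse, so the
        summaries match a plain SH->BH split at the same time."""
        admix = ScenarioModel(
            name="r1", populations=["crop", "BH", "SH"],
            sizes={"crop": 10_000.0, "BH": 10_000.0, "SH": 10_000.0},
            events=[
                {"type": "admix", "time": 200.0, "admixed": "SH",
                 "src_a": "BH", "src_b": "crop", "prob": 1.0},
                {"type": "split", "time": 3_000.0, "derived": "BH",
                 "ancestral": "crop"},
            ])
        split = ScenarioModel(
            name="s", populations=["crop", "BH", "SH"],
            sizes={"crop": 10_000.0, "BH": 10_000.0, "SH": 10_000.0},
            events=[
                {"type": "split", "time": 200.0, "derived": "SH",
                 "ancestral": "BH"},
                {"type": "split", "time": 3_000.0, "derived": "BH",
                 "ancestral": "crop"},
            ])
        n_hap = {"crop": 8, "BH": 8, "SH": 8}
        sa = np.mean([summarize(*simulate_scenario(admix, {}, n_hap, 150,
                                                   seed=i)).values
                      for i in range(15)], axis=0)
        sb = np.mean([summarize(*simulate_scenario(split, {}, n_hap, 150,
                                                   seed=100 + i)).values
                      for i in range(15)], axis=0)
        np.testing.assert_allclose(sa, sb, atol=0.06)

    def test_bad_topology_rejected(self):
        with pytest.raises(ValueError, match="coalesce"):
            ScenarioModel(name="bad", populations=["A", "B"],
                          sizes={"A": 1e4, "B": 1e4}, events=[])

    def test_odd_haplotype_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            simulate_scenario(SINGLE, {}, {"A": 5}, 10, seed=0)


class TestSummaries:
    def test_identical_populations_near_zero_fst(self):
        mat, pm = simulate_scenario(_two_pop(1), {}, {"A": 20, "B": 20},
                                    600, seed=3)
        s = summarize(mat, pm).as_series()
        assert abs(s["fst_A_B"]) < 0.02

    def test_sample_order_invariance(self):
        mat, pm = simulate_scenario(_two_pop(500), {}, {"A": 6, "B": 6},
                                    100, seed=5)
        s1 = summarize(mat, pm)
        perm = [3, 0, 5, 1, 4, 2]
        mat2 = HaplotypeMatrix(
            np.concatenate([mat.alleles[[2 * i, 2 * i + 1]] for i in perm]),
            mat.sites, [mat.samples[i] for i in perm])
        pm2 = PopulationMap({s: pm.population(s) for s in mat2.samples})
        s2 = summarize(mat2, pm2)
        np.testing.assert_allclose(s1.values, s2.values, rtol=1e-12)

    def test_f3_negative_for_admixed_mosaic(self):
        """A target built as a 50/50 site-level mosaic of two diverged sources
        has a negative admixture f3."""
        rng = np.random.default_rng(8)
        S = 4_000
        pa = rng.uniform(0.1, 0.9, S)
        # strongly diverged source frequencies
        pb = np.clip(pa + rng.choice([-1, 1], S) * 0.4, 0.02, 0.98)
        ha = (rng.random((10, S)) < pa).astype(np.int8)
        hb = (rng.random((10, S)) < pb).astype(np.int8)
        pick = rng.random((10, S)) < 0.5
        hx = np.where(pick, ha, hb).astype(np.int8)
        al = np.concatenate([ha, hb, hx])
        sites = pd.DataFrame({"chrom": "c", "pos": np.arange(1, S + 1),
                              "ref": "A", "alt": "G"})
        samples = [f"s{i}" for i in range(15)]
        pm = PopulationMap({s: ["A", "B", "X"][i // 5]
                            for i, s in enumerate(samples)})
        s = summarize(HaplotypeMatrix(al, sites, samples), pm).as_series()
        assert s["f3_X__A_B"] < 0


class TestModelChoice:
    @staticmethod
    @pytest.fixture(scope="class")
    def toy_result():
        scens = toy_split_scenarios()
        mat, pm = simulate_scenario(scens[1], {"t": 3_000.0},
                                    {"A": 12, "B": 12}, 100, seed=3)
        obs = summarize(mat, pm)
        res = abc_model_choice(obs, scens, {"A": 12, "B": 12}, n_snps=100,
                               n_sims_per_scenario=600, retain_fraction=0.02,
                               seed=5, n_bootstrap=60)
        return obs, res

    def test_true_scenario_recovered(self, toy_result):
        _, res = toy_result
        assert res.best() == "mid_split"
        assert res.posteriors["mid_split"] > 0.9

    def test_posteriors_normalized_and_ci_brackets(self, toy_result):
        _, res = toy_result
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        for name, (lo, hi) in res.ci.items():
            assert 0.0 <= lo <= res.posteriors[name] <= hi <= 1.0

    def test_rejection_agrees_with_logistic(self, toy_result):
        _, res = toy_result
        for name in res.posteriors:
            assert abs(res.posteriors[name]
                       - res.rejection_posteriors[name]) <= 0.1

    def test_identical_scenarios_split_posterior(self):
        a = _two_pop(1_000)
        b = ScenarioModel(name="twin", populations=a.populations,
                          sizes=a.sizes, events=a.events)
        mat, pm = simulate_scenario(a, {}, {"A": 8, "B": 8}, 80, seed=9)
        res = abc_model_choice(summarize(mat, pm), [a, b], {"A": 8, "B": 8},
                               n_snps=80, n_sims_per_scenario=300,
                               retain_fraction=0.1, seed=2, n_bootstrap=30)
        assert abs(res.posteriors["split1000"] - 0.5) < 0.2

    def test_full_retention_rejection_equals_prior_proportions(self):
        a, b = _two_pop(500), _two_pop(5_000)
        b.name = "other"
        mat, pm = simulate_scenario(a, {}, {"A": 6, "B": 6}, 40, seed=4)
        res = abc_model_choice(summarize(mat, pm), [a, b], {"A": 6, "B": 6},
                               n_snps=40, n_sims_per_scenario=150,
                               retain_fraction=1.0, seed=6, n_bootstrap=10)
        # everything retained: rejection posterior is the prior proportion
        assert res.rejection_posteriors["split500"] == pytest.approx(0.5)
        assert res.rejection_posteriors["other"] == pytest.approx(0.5)


class TestGof:
    def test_observed_from_fitted_scenario_inside_hull(self):
        sc = _two_pop(2_000)
        params = [{} for _ in range(20)]
        mat, pm = simulate_scenario(sc, {}, {"A": 10, "B": 10}, 100, seed=12)
        rep = gof_check(sc, params, summarize(mat, pm), n_ppc=60,
                        n_haplotypes={"A": 10, "B": 10}, n_snps=100, seed=13)
        assert rep["inside_hull"]
        assert rep["mahalanobis_percentile"] < 99.0
        # PCA of the simulated cloud is centred by construction
        np.testing.assert_allclose(rep["sim_pc"].mean(axis=0), 0.0, atol=1e-9)

    def test_wildly_wrong_scenario_flagged(self):
        sc = _two_pop(100)
        mat, pm = simulate_scenario(_two_pop(40_000), {}, {"A": 10, "B": 10},
                                    100, seed=14)
        rep = gof_check(sc, [{}] * 10, summarize(mat, pm), n_ppc=60,
                        n_haplotypes={"A": 10, "B": 10}, n_snps=100, seed=15)
        assert not rep["inside_hull"]
        assert rep["mahalanobis_percentile"] > 99.0

    def test_too_few_ppc_rejected(self):
        sc = _two_pop(100)
        mat, pm = simulate_scenario(sc, {}, {"A": 4, "B": 4}, 20, seed=1)
        with pytest.raises(ValueError, match="at least 10"):
            gof_check(sc, [{}], summarize(mat, pm), n_ppc=5,
                      n_haplotypes={"A": 4, "B": 4}, n_snps=20)


def test_scenario_yaml_round_trip(tmp_path):
    import yaml

    doc = {"scenarios": [{
        "name": "s1", "populations": ["A", "B"],
        "sizes": {"A": "N", "B": 5_000.0},
        "events": [{"type": "split", "time": "t", "derived": "B",
                    "ancestral": "A"}],
        "priors": {"N": ["loguniform", 1e3, 1e5],
                   "t": ["uniform", 100, 1000]},
    }]}
    path = tmp_path / "sc.yaml"
    path.write_text(yaml.safe_dump(doc))
    (sc,) = load_scenarios(path)
    params = sc.draw_params(np.random.default_rng(0))
    assert 1e3 <= params["N"] <= 1e5 and 100 <= params["t"] <= 1000
    mat, pm = simulate_scenario(sc, params, {"A": 4, "B": 4}, 30, seed=2)
    assert mat.n_sites == 30


def test_bundled_hybrid_scenarios_simulate():
    rng = np.random.default_rng(0)
    for sc in hybrid_origin_scenarios():
        params = sc.draw_params(rng)
        mat, pm = simulate_scenario(sc, params,
                                    {"crop": 6, "BH": 6, "SH": 6}, 50,
                                    seed=3)
        assert mat.n_sites == 50
        assert set(pm.populations) == {"crop", "BH", "SH"}
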