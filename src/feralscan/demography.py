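"""ABC model choice among crop-weed demographic scenarios.

A scenario is a backward-in-time topology over a small set of populations:
population splits (all lineages of a derived population move into its
ancestor) and at most one admixture pulse (each lineage of the admixed
population independently chooses source A with probability r).  Unlinked
SNP genealogies are simulated with a structured coalescent under fixed-S
conditioning: every SNP gets exactly one mutation, placed on a branch drawn
proportionally to branch length, so every simulated site segregates —
matching how a thinned SNP panel is ascertained.

Model choice follows the standard ABC recipe: simulate parameter draws from
the priors under each scenario, summarize (per-population expected
heterozygosity, pairwise Hudson F_ST, three-population f3 admixture
statistics), retain the simulations closest to the observed summary vector
(Euclidean distance after median/MAD standardization), and estimate
posterior scenario probabilities by multinomial logistic regression over
the retained set, with bootstrap confidence intervals.  A posterior
predictive check projects simulated and observed summaries onto the first
two principal axes of the retained scenario's simulations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import HaplotypeMatrix, PopulationMap

__all__ = [
    "ScenarioModel",
    "SummaryVector",
    "ABCResult",
    "simulate_scenario",
    "summarize",
    "abc_model_choice",
    "gof_check",
    "hybrid_origin_scenarios",
    "toy_split_scenarios",
    "load_scenarios",
]

_MAX_HAPLOTYPES = 64  # descendant sets are uint64 bitmasks


# ---------------------------------------------------------------------------
# Scenario specification


@dataclass
class ScenarioModel:
    """A demographic topology with parameter priors.

    ``populations`` lists every population (sampled or ancestral);
    ``sizes`` maps population -> diploid Ne (float or prior-parameter name);
    ``events`` is a list of dicts ordered backward in time, each either

    * ``{"type": "split", "time": t, "derived": P, "ancestral": Q}``
    * ``{"type": "admix", "time": t, "admixed": P, "src_a": Q, "src_b": R,
      "prob": r}``

    where ``t``/``r`` are floats or prior-parameter names.  ``priors`` maps
    parameter name -> (kind, low, high) with kind in {"uniform",
    "loguniform"}.  Parameter draws violating the backward time ordering
    are rejected and redrawn.
    """

    name: str
    populations: list[str]
    sizes: dict[str, float | str]
    events: list[dict]
    priors: dict[str, tuple[str, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_admix = sum(1 for e in self.events if e["type"] == "admix")
        if n_admix > 1:
            raise ValueError("at most one admixture event per scenario")
        self._check_topology()

    def _check_topology(self) -> None:
        alive = set(self.populations)
        for e in self.events:
            if e["type"] == "split":
                if e["derived"] not in alive or e["ancestral"] not in alive:
                    raise ValueError(f"split references dead population: {e}")
                alive.discard(e["derived"])
            else:
                for key in ("admixed", "src_a", "src_b"):
                    if e[key] not in alive:
                        raise ValueError(f"admixture references dead population: {e}")
                alive.discard(e["admixed"])
        if len(alive) != 1:
            raise ValueError(
                f"scenario {self.name!r} does not coalesce to a single root "
                f"(left: {sorted(alive)})"
            )

    def _value(self, v, params: dict[str, float]) -> float:
        return float(params[v]) if isinstance(v, str) else float(v)

    def draw_params(self, rng: np.random.Generator,
                    max_tries: int = 1000) -> dict[str, float]:
        for _ in range(max_tries):
            params: dict[str, float] = {}
            for name, (kind, lo, hi) in self.priors.items():
                if kind == "uniform":
                    params[name] = float(rng.uniform(lo, hi))
                elif kind == "loguniform":
                    params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    raise ValueError(f"unknown prior kind {kind!r}")
            times = [self._value(e["time"], params) for e in self.events]
            if all(t2 > t1 for t1, t2 in zip(times, times[1:])):
                ok = True
                for e in self.events:
                    if e["type"] == "admix":
                        r = self._value(e["prob"], params)
                        if not (0.0 < r < 1.0):
                            ok = False
                if ok:
                    return params
        raise RuntimeError("could not draw ordered parameters from the priors")

    def compile(self, params: dict[str, float]):
        """Resolve parameters into the flat arrays the coalescent core uses."""
        pop_index = {p: i for i, p in enumerate(self.populations)}
        sizes = np.array(
            [self._value(self.sizes[p], params) for p in self.populations]
        )
        if np.any(sizes <= 0):
            raise ValueError("population sizes must be positive")
        E = len(self.events)
        ev_time = np.zeros(E)
        ev_type = np.zeros(E, dtype=np.int8)
        ev_pop = np.zeros(E, dtype=np.int32)
        ev_src1 = np.zeros(E, dtype=np.int32)
        ev_src2 = np.zeros(E, dtype=np.int32)
        ev_prob = np.zeros(E)
        for i, e in enumerate(self.events):
            ev_time[i] = self._value(e["time"], params)
            if e["type"] == "split":
                ev_type[i] = 0
                ev_pop[i] = pop_index[e["derived"]]
                ev_src1[i] = pop_index[e["ancestral"]]
            else:
                ev_type[i] = 1
                ev_pop[i] = pop_index[e["admixed"]]
                ev_src1[i] = pop_index[e["src_a"]]
                ev_src2[i] = pop_index[e["src_b"]]
                ev_prob[i] = self._value(e["prob"], params)
        return pop_index, sizes, (ev_time, ev_type, ev_pop, ev_src1, ev_src2, ev_prob)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioModel":
        priors = {
            k: (v[0], float(v[1]), float(v[2]))
            for k, v in d.get("priors", {}).items()
        }
        return cls(name=d["name"], populations=list(d["populations"]),
                   sizes=dict(d["sizes"]), events=list(d["events"]),
                   priors=priors)


def load_scenarios(path) -> list[ScenarioModel]:
    """Load a list of scenarios from a YAML file (top-level ``scenarios``)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [ScenarioModel.from_dict(d) for d in doc["scenarios"]]


# ---------------------------------------------------------------------------
# Coalescent core (fixed-S: one mutation per unlinked SNP genealogy)


@njit(cache=True)
def _sim_sites(pop0, sizes, ev_time, ev_type, ev_pop, ev_src1, ev_src2,
               ev_prob, n_snps, seed):  # pragma: no cover - via wrapper
    np.random.seed(seed)
    n = pop0.shape[0]
    out = np.zeros((n, n_snps), dtype=np.int8)
    max_dead = 2 * n
    for s in range(n_snps):
        pop = pop0.copy()
        desc = np.empty(n, dtype=np.uint64)
        birth = np.zeros(n)
        alive = np.ones(n, dtype=np.bool_)
        for i in range(n):
            desc[i] = np.uint64(1) << np.uint64(i)
        dead_desc = np.empty(max_dead, dtype=np.uint64)
        dead_len = np.empty(max_dead)
        n_dead = 0
        n_alive = n
        t = 0.0
        ei = 0
        while n_alive > 1:
            # total coalescence rate over populations
            rate = 0.0
            for p in range(sizes.shape[0]):
                k = 0
                for i in range(n):
                    if alive[i] and pop[i] == p:
                        k += 1
                if k > 1:
                    rate += k * (k - 1) / (4.0 * sizes[p])
            t_event = ev_time[ei] if ei < ev_time.shape[0] else 1.0e300
            if rate > 0.0:
                dt = np.random.exponential(1.0 / rate)
            else:
                dt = 1.0e300
            if t + dt >= t_event:
                t = t_event
                if ev_type[ei] == 0:  # split: move derived into ancestral
                    for i in range(n):
                        if alive[i] and pop[i] == ev_pop[ei]:
                            pop[i] = ev_src1[ei]
                else:  # admixture pulse
                    for i in range(n):
                        if alive[i] and pop[i] == ev_pop[ei]:
                            if np.random.random() < ev_prob[ei]:
                                pop[i] = ev_src1[ei]
                            else:
                                pop[i] = ev_src2[ei]
                ei += 1
                continue
            t += dt
            # choose population proportional to its rate
            u = np.random.random() * rate
            acc = 0.0
            chosen = -1
            for p in range(sizes.shape[0]):
                k = 0
                for i in range(n):
                    if alive[i] and pop[i] == p:
                        k += 1
                if k > 1:
                    acc += k * (k - 1) / (4.0 * sizes[p])
                    if u <= acc:
                        chosen = p
                        break
            if chosen < 0:
                continue
            # choose an unordered pair uniformly within the population
            k = 0
            for i in range(n):
                if alive[i] and pop[i] == chosen:
                    k += 1
            i1 = np.random.randint(0, k)
            i2 = np.random.randint(0, k - 1)
            if i2 >= i1:
                i2 += 1
            a = -1
            b = -1
            c = 0
            for i in range(n):
                if alive[i] and pop[i] == chosen:
                    if c == i1:
                        a = i
                    if c == i2:
                        b = i
                    c += 1
            # record both children as dead branches; parent reuses slot a
            dead_desc[n_dead] = desc[a]
            dead_len[n_dead] = t - birth[a]
            n_dead += 1
            dead_desc[n_dead] = desc[b]
            dead_len[n_dead] = t - birth[b]
            n_dead += 1
            desc[a] = desc[a] | desc[b]
            birth[a] = t
            alive[b] = False
            n_alive -= 1
        # drop one mutation on a branch chosen proportionally to length
        total = 0.0
        for d in range(n_dead):
            total += dead_len[d]
        u = np.random.random() * total
        acc = 0.0
        pick = n_dead - 1
        for d in range(n_dead):
            acc += dead_len[d]
            if u <= acc:
                pick = d
                break
        mask = dead_desc[pick]
        for i in range(n):
            if (mask >> np.uint64(i)) & np.uint64(1):
                out[i, s] = 1
    return out


def simulate_scenario(model: ScenarioModel, params: dict[str, float],
                      n_haplotypes: dict[str, int], n_snps: int,
                      seed: int) -> tuple[HaplotypeMatrix, PopulationMap]:
    """Simulate a phased panel of unlinked segregating SNPs under a scenario.

    ``n_haplotypes`` maps sampled population -> haplotype count (must be
    even; two haplotypes per diploid sample).  Sites are placed 10 kb apart
    on a single pseudo-chromosome, mirroring a thinned SNP panel.
    """
    for p in n_haplotypes:
        if p not in model.populations:
            raise ValueError(f"sampled population {p!r} not in scenario")
        if n_haplotypes[p] % 2 != 0:
            raise ValueError("haplotype counts must be even (diploids)")
    n_total = sum(n_haplotypes.values())
    if n_total > _MAX_HAPLOTYPES:
        raise ValueError(f"at most {_MAX_HAPLOTYPES} haplotypes supported")
    pop_index, sizes, events = model.compile(params)
    pop0 = np.concatenate([
        np.full(n_haplotypes[p], pop_index[p], dtype=np.int32)
        for p in n_haplotypes
    ])
    alleles = _sim_sites(pop0, sizes, *events, n_snps, seed & 0x7FFFFFFF)
    samples = []
    assignments = {}
    for p in n_haplotypes:
        for i in range(n_haplotypes[p] // 2):
            name = f"{p}_{i + 1:02d}"
            samples.append(name)
            assignments[name] = p
    sites = pd.DataFrame({
        "chrom": "chrU",
        "pos": np.arange(1, n_snps + 1) * 10_000,
        "ref": "A", "alt": "T",
    })
    return HaplotypeMatrix(alleles, sites, samples), PopulationMap(assignments)


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass
class SummaryVector:
    """Fixed-order ABC summary vector with named entries."""

    names: list[str]
    values: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _pop_freqs(matrix: HaplotypeMatrix, popmap: PopulationMap):
    stats = {}
    for pop in sorted(popmap.populations):
        rows = popmap.haplotype_indices(matrix, pop)
        al = matrix.alleles[rows]
        called = (al >= 0).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(al >= 0, al, 0).sum(axis=0) / called
        stats[pop] = (p, called)
    return stats


def summarize(matrix: HaplotypeMatrix, popmap: PopulationMap) -> SummaryVector:
    """Expected heterozygosities, pairwise Hudson F_ST and f3 statistics.

    Ordering is deterministic: populations sorted by name; pairs and triples
    in lexicographic order.  f3(X; Y, Z) uses the standard sample-size bias
    correction; a negative value indicates admixture in the target X.
    """
    stats = _pop_freqs(matrix, popmap)
    pops = sorted(stats)
    if any(stats[p][1].min() < 2 for p in pops):
        raise ValueError("every population needs >= 2 called haplotypes per site")
    names: list[str] = []
    values: list[float] = []
    for p in pops:
        f, n = stats[p]
        het = 2.0 * f * (1.0 - f) * n / (n - 1.0)
        names.append(f"het_{p}")
        values.append(float(het.mean()))
    for p, q in itertools.combinations(pops, 2):
        f1, n1 = stats[p]
        f2, n2 = stats[q]
        num = ((f1 - f2) ** 2
               - f1 * (1 - f1) / (n1 - 1.0)
               - f2 * (1 - f2) / (n2 - 1.0))
        den = f1 * (1 - f2) + f2 * (1 - f1)
        total = den.sum()
        names.append(f"fst_{p}_{q}")
        values.append(float(num.sum() / total) if total > 0 else 0.0)
    for x in pops:
        others = [p for p in pops if p != x]
        for y, z in itertools.combinations(others, 2):
            fx, nx = stats[x]
            fy, _ = stats[y]
            fz, _ = stats[z]
            f3 = (fx - fy) * (fx - fz) - fx * (1 - fx) / (nx - 1.0)
            names.append(f"f3_{x}__{y}_{z}")
            values.append(float(f3.mean()))
    return SummaryVector(names, np.asarray(values))


# ---------------------------------------------------------------------------
# Model choice


@dataclass
class ABCResult:
    posteriors: dict[str, float]
    ci: dict[str, tuple[float, float]]
    rejection_posteriors: dict[str, float]
    distance_threshold: float
    retained: pd.DataFrame  # scenario, distance, params..., summaries...
    method: str = "logistic"

    def best(self) -> str:
        return max(self.posteriors, key=self.posteriors.get)


def _standardizer(X: np.ndarray):
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    mad = np.where(mad > 0, mad, 1.0)
    return med, mad


def abc_model_choice(
    observed: SummaryVector,
    scenarios: list[ScenarioModel],
    n_haplotypes: dict[str, int],
    n_snps: int,
    n_sims_per_scenario: int = 10_000,
    retain_fraction: float = 0.01,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> ABCResult:
    """Rejection + multinomial-logistic ABC posterior scenario probabilities.

    Simulations are standardized per summary dimension by median/MAD, the
    ``retain_fraction`` closest to the observed vector kept, and a
    multinomial logistic regression of scenario label on summaries fitted
    over the retained set; the posterior is the fitted probability at the
    observed point.  95% CIs come from a nonparametric bootstrap over the
    retained simulations.
    """
    from sklearn.linear_model import LogisticRegression

    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    params_list = []
    for sc in scenarios:
        for _ in range(n_sims_per_scenario):
            params = sc.draw_params(rng)
            sim_seed = int(rng.integers(0, 2**31 - 1))
            mat, pm = simulate_scenario(sc, params, n_haplotypes, n_snps, sim_seed)
            rows.append(summarize(mat, pm).values)
            labels.append(sc.name)
            params_list.append(params)
    X = np.asarray(rows)
    y = np.asarray(labels)
    med, mad = _standardizer(X)
    Xs = (X - med) / mad
    obs = (observed.values - med) / mad
    dist = np.sqrt(((Xs - obs) ** 2).sum(axis=1))
    n_keep = max(len(scenarios) * 2, int(round(retain_fraction * len(dist))))
    keep = np.argsort(dist)[:n_keep]
    threshold = float(dist[keep[-1]])

    order = [sc.name for sc in scenarios]
    counts = pd.Series(y[keep]).value_counts()
    rejection = {name: float(counts.get(name, 0)) / n_keep for name in order}
    for name in order:
        if rejection[name] == 0.0:
            warnings.warn(f"scenario {name!r} absent from the retained set")

    def fit_predict(idx) -> dict[str, float] | None:
        present = np.unique(y[idx])
        if len(present) < 2:
            return {name: float(name == present[0]) for name in order}
        try:
            clf = LogisticRegression(max_iter=2000, C=1.0)
            clf.fit(Xs[idx], y[idx])
            proba = clf.predict_proba(obs.reshape(1, -1))[0]
            out = {name: 0.0 for name in order}
            for cls, p in zip(clf.classes_, proba):
                out[cls] = float(p)
            return out
        except Exception:
            return None

    method = "logistic"
    post = fit_predict(keep)
    if post is None:
        warnings.warn("logistic fit failed; falling back to rejection proportions")
        post = dict(rejection)
        method = "rejection"
    total = sum(post.values())
    post = {k: v / total for k, v in post.items()}

    boots = {name: [] for name in order}
    for _ in range(n_bootstrap):
        idx = keep[rng.integers(0, n_keep, n_keep)]
        bp = fit_predict(idx)
        if bp is None:
            continue
        for name in order:
            boots[name].append(bp[name])
    ci = {}
    for name in order:
        if boots[name]:
            lo, hi = np.percentile(boots[name], [2.5, 97.5])
        else:
            lo = hi = post[name]
        ci[name] = (float(min(lo, post[name])), float(max(hi, post[name])))

    retained = pd.DataFrame(Xs[keep], columns=observed.names)
    retained.insert(0, "scenario", y[keep])
    retained.insert(1, "distance", dist[keep])
    retained["_params"] = [params_list[i] for i in keep]
    return ABCResult(posteriors=post, ci=ci, rejection_posteriors=rejection,
                     distance_threshold=threshold, retained=retained,
                     method=method)


def gof_check(
    model: ScenarioModel,
    posterior_params: list[dict[str, float]],
    observed: SummaryVector,
    n_ppc: int,
    n_haplotypes: dict[str, int],
    n_snps: int,
    seed: int = 0,
) -> dict:
    """Posterior-predictive goodness-of-fit check in summary-statistic PCA.

    Simulates ``n_ppc`` datasets with parameters resampled from the retained
    posterior sample, projects simulated + observed summaries onto the first
    two principal axes of the simulated set, and reports convex-hull
    containment and the observed point's Mahalanobis percentile.
    """
    from scipy.spatial import Delaunay
    from sklearn.decomposition import PCA

    if n_ppc < 10:
        raise ValueError("need at least 10 posterior-predictive simulations")
    if not posterior_params:
        raise ValueError("empty posterior parameter sample")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_ppc):
        params = posterior_params[int(rng.integers(0, len(posterior_params)))]
        sim_seed = int(rng.integers(0, 2**31 - 1))
        mat, pm = simulate_scenario(model, params, n_haplotypes, n_snps, sim_seed)
        rows.append(summarize(mat, pm).values)
    X = np.asarray(rows)
    med, mad = _standardizer(X)
    Xs = (X - med) / mad
    obs = (observed.values - med) / mad
    pca = PCA(n_components=2)
    sim_pc = pca.fit_transform(Xs)
    obs_pc = pca.transform(obs.reshape(1, -1))[0]
    hull = Delaunay(sim_pc)
    inside = bool(hull.find_simplex(obs_pc) >= 0)
    cov = np.cov(sim_pc, rowvar=False)
    inv = np.linalg.pinv(cov)
    centered = sim_pc - sim_pc.mean(axis=0)
    d_sim = np.einsum("ij,jk,ik->i", centered, inv, centered)
    dv = obs_pc - sim_pc.mean(axis=0)
    d_obs = float(dv @ inv @ dv)
    percentile = 100.0 * float(np.mean(d_sim <= d_obs))
    return {
        "inside_hull": inside,
        "mahalanobis_percentile": percentile,
        "sim_pc": sim_pc,
        "obs_pc": obs_pc,
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
    }


# ---------------------------------------------------------------------------
# Bundled scenario sets


def hybrid_origin_scenarios() -> list[ScenarioModel]:
    """The four competing origins of SH (straw-hull) weedy rice: hybrid
    BH x crop origin versus three pure-divergence orderings.

    Sampled populations are crop, BH and SH; Ne priors are log-uniform
    1e3..1e5 diploids and event times uniform in generations.
    """
    sizes = {"crop": "N_crop", "BH": "N_bh", "SH": "N_sh"}
    ne_priors = {
        "N_crop": ("loguniform", 1e3, 1e5),
        "N_bh": ("loguniform", 1e3, 1e5),
        "N_sh": ("loguniform", 1e3, 1e5),
    }
    s1 = ScenarioModel(
        name="hybrid_origin",
        populations=["crop", "BH", "SH"],
        sizes=sizes,
        events=[
            {"type": "admix", "time": "t_h", "admixed": "SH",
             "src_a": "BH", "src_b": "crop", "prob": "r"},
            {"type": "split", "time": "t_1", "derived": "BH",
             "ancestral": "crop"},
        ],
        priors={**ne_priors,
                "t_h": ("uniform", 10, 500),
                "t_1": ("uniform", 500, 5000),
                "r": ("uniform", 0.1, 0.9)},
    )
    s2 = ScenarioModel(
        name="weed_ancestor",
        populations=["crop", "BH", "SH"],
        sizes=sizes,
        events=[
            {"type": "split", "time": "t_w", "derived": "SH", "ancestral": "BH"},
            {"type": "split", "time": "t_1", "derived": "BH", "ancestral": "crop"},
        ],
        priors={**ne_priors,
                "t_w": ("uniform", 10, 500),
                "t_1": ("uniform", 500, 5000)},
    )
    s3 = ScenarioModel(
        name="bh_first",
        populations=["crop", "BH", "SH"],
        sizes=sizes,
        events=[
            {"type": "split", "time": "t_sh", "derived": "SH", "ancestral": "crop"},
            {"type": "split", "time": "t_bh", "derived": "BH", "ancestral": "crop"},
        ],
        priors={**ne_priors,
                "t_sh": ("uniform", 10, 500),
                "t_bh": ("uniform", 500, 5000)},
    )
    s4 = ScenarioModel(
        name="sh_first",
        populations=["crop", "BH", "SH"],
        sizes=sizes,
        events=[
            {"type": "split", "time": "t_bh", "derived": "BH", "ancestral": "crop"},
            {"type": "split", "time": "t_sh", "derived": "SH", "ancestral": "crop"},
        ],
        priors={**ne_priors,
                "t_bh": ("uniform", 10, 500),
                "t_sh": ("uniform", 500, 5000)},
    )
    return [s1, s2, s3, s4]


def toy_split_scenarios(n: float = 10_000.0) -> list[ScenarioModel]:
    """Three two-population scenarios whose split-time priors give nearly
    disjoint F_ST supports — a controlled test bed for scenario recovery."""
    out = []
    for name, lo, hi in [("recent_split", 100, 200),
                         ("mid_split", 2000, 4000),
                         ("old_split", 20000, 40000)]:
        out.append(ScenarioModel(
            name=name,
            populations=["A", "B"],
            sizes={"A": n, "B": n},
            events=[{"type": "split", "time": "t", "derived": "B",
                     "ancestral": "A"}],
            priors={"t": ("uniform", lo, hi)},
        ))
    return out
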