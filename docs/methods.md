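# Methods

This note documents the models implemented in `feralscan`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and windowing

Internally all intervals are 0-based half-open; every file read or written
(VCF, popmap, truth tables, scan reports) is 1-based inclusive, with
conversion only at the I/O boundary. Scan windows are anchored at position
0, spaced by the step, and truncated at the chromosome end (a window is
emitted iff its start lies inside the chromosome). Trailing short windows
are kept, not dropped, so merged-region bp totals account for the actual
genome. Away from the edges each site falls in exactly window/step
overlapping windows. Missing alleles are excluded from allele counts
site-by-site; no re-imputation is attempted (inputs are assumed phased and
imputed upstream).

## Windowed F_ST scan

Per site, the two-population Weir–Cockerham (1984) variance components
*a* (among populations), *b* (among individuals within populations) and
*c* (within individuals) are computed from diploid sample sizes, allele
frequencies and observed heterozygosity; the window statistic is the
ratio-of-sums Σa / Σ(a+b+c) over member sites (the "weighted" windowed
estimator), which is less noisy than averaging per-site ratios. Sites
monomorphic across both groups contribute nothing; windows with fewer than
`min_sites` (default 5) usable sites are left undefined and excluded from
standardization. The weed group is compared against the pooled set of its
potential crop ancestors (e.g. BH vs modern+landrace TEJ together).

Finite-sample note: with identical frequencies and heterozygosity in both
groups, *a* is slightly negative (the bias-correction term), vanishing in
the large-sample limit; window estimates on undifferentiated data may
likewise dip slightly below zero. This is a property of the estimator, not
a bug.

**Outlier rule.** Defined windows are Z-transformed
(Z = (F_ST − mean)/sd); a window is significant iff
Z − median(Z) ≥ m·MAD(Z), with the *unscaled* MAD (no 1.4826 factor) and
m = 5 by default — "at least five absolute deviations from the median",
upper tail only, since divergence from the crop is one-sided in this
design. A zero-MAD score distribution raises an error rather than flagging
everything. Significant windows that overlap or abut are merged into
outlier regions (with a 10-kb step and 100-kb windows, consecutive
significant windows always overlap); regions from two scans are intersected
to find blocks differentiated in both weed lineages, with per-chromosome
count tallies and genome-fraction accounting (region bp / genome bp, as
percent). The IRGSP-1.0 pseudomolecule lengths (373,245,519 bp total) are
bundled for accounting against the rice reference.

## EHH statistics

EHH at flanking site x for the carriers of a core allele is
Σ_h C(n_h,2)/C(n,2) over distinct extended haplotypes spanning core→x;
haplotypes with a missing call anywhere in the span are dropped from both
numerator and denominator for that span. On complete data EHH is
non-increasing away from the core; with missing-data dropping it can
occasionally rise when a singleton class drops out, so the monotonicity
guarantee applies to complete data.

iHH integrates EHH over physical distance (trapezoid, bp units; no genetic
map), separately per direction, stopping after the first segment whose far
end falls below the cutoff (default 0.05) and truncating at inter-site gaps
wider than 200 kb; integration that reaches a chromosome end while EHH is
still above the cutoff is flagged edge-truncated.

**iHS** = ln(iHH_ancestral/iHH_derived) per site, for sites with derived
frequency in [0.05, 0.95] and both allele classes having ≥2 carriers and
positive iHH. Scores are standardized within 20 equal-width derived-
frequency bins (bins with <10 sites merged with a neighbour); p-values are
two-sided normal, reported as −log10 p, so the conventional threshold
−log10 p > 4 corresponds to |standardized score| ≈ 3.89. Polarization
matters for the sign: the default used by the pipeline treats the major
allele across the pooled crop groups as ancestral (`crop_major_ancestral`);
reference-allele polarization is available by passing no ancestral vector.

**XP-EHH** = ln(iHH_pop1/iHH_pop2) with pooled-allele EHH per population:
the haplotype partition starts at the core site (the core allele is part of
the identity span), and scores are standardized genome-wide (a single bin).
Positive values mean longer haplotype homozygosity in the first population.

Desk-scale caveat: the frequency-binned standardization assumes bins
populated by many neutral sites. On small simulated genomes a planted sweep
can contribute a noticeable share of its own frequency bin and inflate the
bin sd; the recovery studies therefore use a 20-Mb / 4,000-site genome with
a single 300-kb sweep (1.5% of sites), where bin occupancy is adequate.

## ABC demographic scenario choice

A scenario is a backward-in-time event list over named populations:
population splits and at most one admixture pulse (each lineage of the
admixed population independently takes source A with probability r).
Population sizes are constant diploid Ne per population; times are in
generations. Priors are uniform or log-uniform per parameter; draws
violating the backward time ordering are rejected and redrawn.

Unlinked SNPs are simulated with a structured coalescent under **fixed-S
conditioning**: each SNP gets its own genealogy and exactly one mutation,
placed on a branch drawn proportionally to branch length — matching how an
ascertained, thinned SNP panel behaves. Note this is not the same as
Poisson mutation: the resulting frequency-class probabilities are
E[L_i/L], which at small sample sizes sits measurably above the classical
1/i proportions for singletons; the test suite checks the simulator against
an independent msprime/tskit implementation of the same placement.
Descendant sets are uint64 bitmasks, so at most 64 haplotypes can be
sampled per simulation — ample for ABC panels, and the per-simulation cost
is small enough for 10,000 simulations per scenario in about a minute
(numba-compiled core).

Summaries: per-population expected heterozygosity, all pairwise Hudson
F_ST (ratio of averages with sample-size bias correction), and
bias-corrected three-population f3 statistics for every (target; pair)
combination — a compact vector that separates the bundled scenario sets;
it is deliberately explicit and swappable rather than a black-box summary
set. Summaries are standardized per dimension by median/MAD; the
`retain_fraction` closest simulations by Euclidean distance (default 1%)
enter a multinomial logistic regression of scenario label on summaries,
and the posterior is the fitted probability at the observed vector. 95%
CIs come from a nonparametric bootstrap over the retained set (refitting
the regression per resample); if the fit fails the rejection proportions
are used with a warning, and a scenario absent from the retained set is
reported at probability 0. The goodness-of-fit check simulates from
parameters resampled out of the retained posterior sample, projects
simulated and observed summaries on the first two principal axes of the
simulated cloud, and reports convex-hull containment plus the observed
point's empirical Mahalanobis percentile.

Bundled scenario sets: `hybrid_origin_scenarios()` — the four competing
origins of SH weedy rice (hybrid BH × crop origin vs three pure-divergence
orderings), with log-uniform Ne priors (10³–10⁵) and uniform time priors —
and `toy_split_scenarios()`, three two-population splits whose time priors
give nearly disjoint F_ST supports, used as a controlled recovery test bed.
Desk-scale default is 10⁴ simulations per scenario; production scale
(10⁶/scenario) is a parameter, not a different code path.

## Local ancestry

Per admixed haplotype, the exact dynamic program minimizes
Σ_s mismatch(s, k_s) + λ·#switches over assignments of one reference
haplotype per site; the source panel of the copied reference is the local
ancestry. Missing query or reference alleles contribute zero mismatch
(uninformative rather than imputed). Ties break toward no-switch, then
toward the lowest reference index; at exact cost ties between panels the
label can therefore depend on panel order — the bagged vote makes this
immaterial in practice. λ is swept over {1.5, 2, …, 5} with bagged panel
resampling (panels resampled with replacement per bag; with one bag the
panels are used as-is) and a per-site majority vote; unequal panels are
first subsampled to equal size (panel balancing). Diploid individuals are
phased upstream; the two haplotypes are solved independently and reported
as two rows per individual. Switch count is non-increasing in λ (verified
by property test); the DP equals exhaustive enumeration on small instances.

## Synthetic-data generator

Allele frequencies follow a hierarchical Balding–Nichols model down a fixed
tree: root frequency p₀ ~ Uniform(0.05, 0.95), each branch drawing the
child frequency from Beta(p(1−F)/F, (1−p)(1−F)/F). Two useful closed
forms: the pairwise Weir–Cockerham θ between two sister populations is
approximately the *average* of their branch F values (cross-population
allele pairs are uncorrelated, so θ reduces to the within-population
correlation), and sequential branches compound as 1 − Π(1−F_i). Default
branch values give TEJ/TRJ divergence ≈ 0.3 and weed/crop divergence
≈ 0.04 — a strongly structured selfer at modest weed–crop differentiation.

Planted features and their rationale:

* **Divergent regions** — the weed branch draws with a boosted F (default
  0.55 in the demo) inside the region; downstream window F_ST rises only
  locally.
* **Sweeps** — haplotype copying, not forward simulation: a carrier
  fraction (default 0.8, detectable but unfixed) of the population's
  haplotypes receives one shared core haplotype over a 300-kb span, and the
  core site carries a derived allele private to the carriers (a sweep is of
  a derived mutation; leaving the non-carrier background frequency free
  can push the core site to fixation and out of the iHS frequency window).
  Sweeps are planted before mosaics so hybrid haplotypes can inherit them.
* **Mosaics** — SH_TEJ haplotypes alternate exponential tracts copied from
  sampled BH and modern-crop haplotypes. BH tracts have mean 2·L·α and crop
  tracts 2·L·(1−α), so the stationary BH fraction is exactly α and the
  across-tract mean length is L (default α = 0.5, L = 2 Mb — a recent
  single-pulse hybrid). α = 0 and α = 1 are valid boundaries (pure crop /
  pure BH copies).
* **Chloroplast table** — seven organelle variants; each lineage carries a
  fixed haplotype vector (SH_TEJ shares the modern-crop vector: maternal
  crop origin), and ~11% of strains receive ≥1 missing call, emulating
  organelle genotyping dropout.

Sites are placed uniformly at random (1 per 5 kb by default, ~20 per 100-kb
window), sorted and deduplicated. Determinism: one `numpy` Generator seeded
from the config; identical config and seed give byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium outside planted sweeps and
mosaics (neutral sites are exchangeable draws, so EHH decays faster than in
real selfing rice), recombination-rate variation, gene conversion,
selfing-rate dynamics, sequencing error and genotype-likelihood
uncertainty, indels in the nuclear genome, and selection outside the
planted features. Recovery rates measured here are best-case figures for
the statistical machinery, not field performance estimates.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each method's assumptions hold:
calibration of Balding–Nichols F at 2,000 sites × 10 seeds with 50+50
samples; F_ST region recovery on 5-Mb genomes (10 seeds); iHS sweep
recovery on 20-Mb / 4,000-site genomes (10 seeds; see the standardization
caveat above); ABC recovery at 10,000 simulations per scenario on the toy
set with 24 sampled haplotypes and 100 SNPs; local ancestry at 5,000 sites,
α = 0.5, 2-Mb tracts, balanced 10+10 panels (5 seeds); the bundled demo
pipeline on a 5-Mb two-chromosome genome.

## Known limitations

* Coalescent core: ≤64 sampled haplotypes, constant per-population sizes,
  one admixture pulse, no within-locus recombination (summaries are LD-free
  by design).
* iHS/XP-EHH significance uses the normal approximation on standardized
  scores; empirical score distributions are heavier-tailed, so −log10 p
  values are nominal, as is conventional for these statistics.
* Chloroplast classification is exact-match by design; it does not impute
  missing organelle calls or build haplotype networks.
* The MAD outlier rule is applied to Z scores; applying it to raw window
  F_ST flags the same windows (the transform is affine) but reported Z
  values would differ if the rule were defined on the raw scale.
* Local ancestry emits per-haplotype labels only; genotype-level smoothing
  across the two haplotypes of an individual is out of scope.
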