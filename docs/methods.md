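# Methods

## The structured coalescent with time-dependent rates

`mscmig` simulates gene genealogies backward in time inside a rooted
ultrametric species tree. Each branch of the species tree is a
Wright–Fisher population described by a scaled effective size
ν(t) = N_e·τ, where τ is the generation time expressed in the model's
time unit (`GenerationScale` converts back: N_e = ν/τ; with time in
generations, τ = 1 and ν = N_e). The model depends only on ratios of
population sizes and times, so τ enters only in unit conversions.

Two event families drive the process:

* **Coalescence** of two of the ℓ lineages in a branch, at rate
  C(ℓ,2)/ν(t).
* **Backward migration.** Forward migration is specified as m_{a→b}(t),
  the *fraction of population a emigrating per time unit*, giving an
  emigrant flow m_{a→b}·ν_a. A lineage in *b* therefore jumps backward
  into *a* at rate f_{b→a}(t) = m_{a→b}(t)·ν_a(t)/ν_b(t) — the ratio of
  arriving emigrants to the receiving population. The fraction
  parametrization keeps migration interpretable (expected migrants per
  population unit per generation) when population sizes themselves change.

When a decorated clade has split into several extant branches, the split
is treated as the clade's "internal affair": the total flow between the
two sides is computed as if each side were one population (summed ν), and
emigrants are distributed among the extant receiving branches in
proportion to their ν values. Concretely, for a lineage in branch x of
side X jumping backward to branch y of side Y under a decoration with
fraction m(t), the per-lineage rate is m(t)·ν_y(t)/ν_X(t) with
ν_X = Σ over extant X-branches. With single branches on both sides this
reduces to the classical backward rate above, and summing over y makes
the total flow independent of how the Y side happens to be subdivided
(this invariance is property-tested). Alternative split semantics in
which a split cuts off part of the contact are *not* modelled.

## Exact waiting-time sampling

All inputs — ν per branch and m per decoration — are nonnegative
piecewise-linear functions of time (`PiecewiseLinearFunction`; constant
extension beyond the last breakpoint, and an explicit
compact-support variant for migration bands). On any interval where all
components are simultaneously linear, every event rate has the rational
form

    h(t) = (a1 + b1·t)(a2 + b2·t) / (a3 + b3·t).

Polynomial division gives h(t) = c0 + c1·t + c2/(a3 + b3·t) (or a plain
quadratic when b3 = 0, which is integrated directly to avoid dividing by
zero), so the cumulative hazard is an explicit polynomial-plus-logarithm
expression per segment. `RateIntegral` caches the segment partition (the
union of all component breakpoints, clipped to the interval on which the
hazard applies) and solves the inverse-transform equation
∫_{t0}^{t} h = −log(1−U), U ~ Uniform[0,1), by walking segments until the
cumulative hazard brackets the target and then running Brent root-finding
on the closed-form cumulative inside that single segment (xtol = rtol =
1e−14; the round-trip identity is tested at 1e−9 relative). Segment
coefficients are recovered by evaluating each component at two *interior*
points of the segment — exact for linear pieces and robust to the jump
discontinuities at the ends of a compact migration support.

Degenerate cases are pinned down deterministically: u = 0 returns the
start time (zero cumulative-hazard target); events whose hazard never
reaches the target before the horizon return +∞, as do impossible events
(coalescence with fewer than two lineages, migration of an empty branch);
a population size that is nonpositive anywhere lineages can reside raises
`SingularPopulationError` rather than silently producing an infinite
coalescence rate.

## The event loop

Simulation proceeds per *epoch* — the interval between consecutive
species divergences (plus a final unbounded epoch above the root). Within
an epoch the extant branch set is fixed, so the per-branch unit coalescent
hazards and the per-ordered-pair migration hazards are built once and
cached. At every step one candidate waiting time is drawn per possible
event (coalescent targets are scaled by C(ℓ,2), migration targets by ℓ);
the minimum is applied and *all* candidates are redrawn — with
time-varying rates the classical single-draw shortcut for competing
exponentials is unavailable. If no candidate falls before the next
divergence, the event is rejected: time advances to the divergence, the
daughter species' lineage sets merge (nearest divergence only, then
redraw). Ties among equal minima (measure zero) break toward the fixed
enumeration order: coalescences in species order, then migrations in
ordered-pair order. Species with zero sampled lineages still exist as
migration destinations. When every rate is constant the procedure reduces
exactly to the classical competing-exponentials structured coalescent
(tested by Kolmogorov–Smirnov against the exponential law).

A coalescence is counted **inconsistent** when its time is more recent
than the species-tree MRCA height of the sampled species below its two
children — impossible under strict divergence, possible with migration.
Because the notion could also be read per species pair, a second counter
reports the number of species pairs joined by some too-recent coalescence
(`count_inconsistent_pairs`); all headline numbers use the per-node
counter.

## The gradual-separation scenario

The scenario generator defines the package's study conditions; its
defaults are fixed, not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| n_species | 5 | Yule tips |
| samples_per_species | 10 | gene lineages sampled per species |
| yule_rate λ | 0.8 | births per lineage per time unit |
| tip_mean | 0.85 | real-space mean of present-day ν |
| pop_sd_log | 0.4 | log-space sd of present-day ν |
| expansion | 0.7 | older-end/younger-end ν ratio per branch |
| interval_sd_log | 0.25 | log-space sd of separation-interval lengths |

*Yule trees.* Generated backward (join a uniform pair after an
Exp(λ·i) wait while i lineages remain); the mean root height is
Σ_{i=2..n} 1/(λi) ≈ 1.604 for n = 5, λ = 0.8.

*Population assignment.* The precise procedure behind the published
expansion-factor/standard-deviation parametrization is not fully
specified anywhere we could rely on, so the package fixes its own
concrete reading — the main reverse-engineered component. Each tip
branch's present-day ν is log-normal with real-space mean `tip_mean` and
log-sd 0.4 (μ = log(mean) − σ²/2); every branch is linear with older-end
value 0.7× its younger-end value (populations grow toward the present);
an internal branch's younger end is the mean of its children's older
ends; the root population is constant at that mean. `tip_mean = 0.85` is
chosen so that expected within-species diversity 2·(clock rate)·E[pair
TMRCA] ≈ 2·0.005·0.85 ≈ 0.0085 matches the diversity regime the package
targets; downstream quantities that depend on this reconstruction
(migration-incidence fractions, count multipliers, diversity summaries)
are therefore checked against generous bands rather than tight
tolerances.

*Separation intervals.* Each divergence at height t_d receives an
interval length L ~ LogNormal with **real-space mean** S/(2λ) and
log-space sd 0.25 (μ = log(S/2λ) − σ²/2 — the mean is read as real-space;
the alternative log-space reading would shift lengths by only e^{σ²/2} ≈
3%). t_s = max(t_d − L, 0): intervals are truncated at the present.
Nesting is enforced root-to-tips: a child divergence's t_s may not exceed
its parent's, offending draws are redrawn up to 100 times and then
clamped to the parent's t_s — preserving the drawn distribution where
possible with a deterministic fallback. The migration fraction between
the daughter clades is m(t) = M·(t−t_s)/(t_d−t_s) on [t_s, t_d], applied
symmetrically in both directions; M = 0 or S = 0 degenerates to the
strict MSC with t_s = t_d.

*Weak and strong trees.* The weak speciation tree keeps divergences at
t_d (separation begins); the strong tree moves each to t_s (separation
completes). After nesting enforcement the strong tree is still a valid
ultrametric tree, with equal parent/child heights possible only through
the clamping fallback or the t_s ≥ 0 floor.

## Sequences

Jukes–Cantor with a strict clock: the root state is uniform, sites are
iid, and along a branch of duration Δt the probability a site changes is
(3/4)(1 − e^{−4d/3}) with d = rate·Δt (changed sites pick one of the
other three states uniformly). No rate heterogeneity, no indels —
matching the simple radiation regime the package targets. Summaries are
the standard ones: fraction of identical sites per pair, mean per-site
pairwise difference (overall / within species / between species; the
overall value is exactly the pair-count-weighted mean of the other two),
count of segregating columns, and distinct-row haplotype counts.

In the no-migration identity experiment (Yule λ = 0.4, constant
populations uniform within ±20% of 5/8, 6 individuals per species, 4 loci
× 1600 bp, rate 0.005) "two random individuals" is read as *same-species*
pairs (≈99.4% identity), in contrast to the explicitly cross-species
figure (≈97.1%); the two figures are only mutually consistent under this
reading. The ±20% spread is read as uniform on [0.5, 0.75].

## Validation oracles

Two independent cross-checks of the event loop:

*Euler discretization* (`euler_simulate`). In each step of length dt every
possible event fires with probability rate·dt, at most one event per
step; a per-step total above 1 raises (dt too large; accuracy is first
order in dt). On stretches where all rates are constant the number of
quiet steps is drawn geometrically — distributionally identical to
stepping one-by-one, just faster; time-varying stretches step explicitly.

*Matrix-exponential closed form* (`CTMCModel`). For two populations with
constant ν and m, the lineage configuration (i, j) is a finite CTMC whose
generator Q collects coalescent rates C(·,2)/ν and per-lineage backward
migration rates. exp(QT) gives the configuration distribution at the
divergence horizon T (rows sum to 1 to 1e−10, checked); lineages
surviving into the ancestral population finish under a single-population
coalescent whose TMRCA is hypoexponential with rates C(k,2)/ν_anc, k
descending — giving the exact root-height density and CDF. Probabilities
over many time points use the eigendecomposition of Q (verified against
`scipy.linalg.expm`). The CTMC covers only the constant-rate
two-population case; the Euler oracle covers the general regime, where no
closed form exists.

The acceptance suite checks three-way agreement (main simulator vs Euler
vs closed form, KS at α = 0.01, n = 20,000 per sampler) on two
configurations of a two-species tree with T = 2, m = 0.1, ν_a = 1,
ν_b = 2, ν_anc = 1: one lineage per species, and two from *a* plus one
from *b*.

## Experiments

`run_grid` summarizes migration activity over (M, S) points: per
replicate a fresh scenario species tree and a single gene tree, reporting
mean migration counts, mean inconsistent coalescences and the fraction of
trees with at least one migration, with Monte-Carlo standard errors.
Because migration waiting times over a linearly declining band are
governed by the hazard product M·S, mean counts fit the saturating form
a·h^c/(h^c + b) with h = M·S (`fit_hazard_curve`, least squares via
`scipy.optimize.curve_fit`; the exponent can be pinned for nested-model
comparisons).

Tree distances use the rooted branch score: over the union of clades of
two same-leaf-set rooted trees, the square root of the summed squared
differences of subtending branch lengths (absent clades contribute their
full length). The reference normalization constant for the "normalized"
variant is not restated in the sources available to this package, so the
raw score is primary and the normalized variant divides by the number of
clade terms. `weak_strong_classification` reports mean distances to the
weak and strong trees, the closer-to-weak indicator, and the mean pair
location (t̂ − t_s)/(t_w − t_s) averaged over taxon pairs (1 = weak end,
0 = strong end). Since posterior inference from finite sequences is out
of scope, the perfect-data analogue `divergence_bound_tree` estimates
each divergence by the most recent cross-clade coalescence over loci —
the "infinite sequence length" limit of sequence-based estimates.

## Problem sizes and determinism

Simulation sizes in the shipped tests are chosen to give stable
Monte-Carlo checks at desk scale: 10,000 Yule trees for the height check;
2,000 scenario replicates per (M, S) point for migration incidence
(bands of roughly ±half the target value, reflecting the reconstructed
population assignment); 100 tree sets for the identity experiment
(±0.3/±0.8 percentage points); 20,000 root heights per sampler for the
oracle comparisons; 1,500 replicates per point for the (M, S) symmetry
check. All randomness flows through explicitly seeded
`numpy.random.Generator` instances; KS-based tests are seeded so their
p-value thresholds are deterministic. The acceptance script derives all
of its randomness from `--seed`.

## Known limitations

* No recombination and no serially sampled tips (all tips at time 0).
* Only the "internal affair" split semantics; scenarios where a split
  cuts one daughter off from prior contact are not representable.
* Exponential growth or step demographies must be approximated by
  piecewise-linear refinement.
* The population-assignment procedure is a reconstruction (see above);
  quantities downstream of it are soft-checked.
* The CTMC oracle is limited to two constant-rate populations.
* Posterior species-tree inference (and thus detection-rate studies that
  require it) is outside the package's scope; the perfect-data
  divergence-bound analogue stands in for it.
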