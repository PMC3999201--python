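# Methods

This note documents the models implemented in `lineaburst`, the
conventions behind them, and what the synthetic-data generators do and do
not emulate.

## Scope and data flow

The package reproduces, as a reusable pipeline, a COI-based species
delimitation and diversification analysis for testate amoebae
(Hyalospheniidae-like data): aligned sequences are deduplicated, pairwise
K2P distances feed a 99%-similarity clustering, a time-calibrated gene
tree is delimited into entities with the GMYC model, a posterior sample
of chronograms is screened for diversification-rate shifts with a
simulated critical ΔAICrc, and standing diversity plus a crown age yield
net diversification rates. Tree inference and divergence dating are
out of scope: chronograms are consumed, never produced.

## Sequence layer

**Deduplication.** Two aligned sequences are *compatible* when they agree
at every position where both carry a determinate character (A, C, G, T or
the alignment gap); N is a wildcard. Compatibility is not transitive, so
connected components of the compatibility graph are collapsed; the member
with the most determinate (non-N, non-gap) characters is kept, ties
broken by input order. "Longest" is interpreted as determinate coverage
because all aligned strings share one padded length, and real COI
fragments differ only in how much of the alignment they cover.

**K2P distances.** Sites where either sequence has N or a gap are removed
pairwise (complete deletion would leave few columns for partial-length
fragments). With transition and transversion proportions P and Q over the
m retained sites,

d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q).

Pairs with a non-positive log argument are flagged saturated and excluded
from clustering (treated as infinitely distant), with a logged warning.

**Threshold clustering.** "99% similarity" is implemented as K2P distance
≤ 0.01 (the distances are computed with K2P, and at 1% divergence K2P and
p-distance agree to ~1e−4; a `metric="p"` flag provides the uncorrected
alternative). Single linkage (connected components of the ≤-cutoff graph)
is the default, matching common barcode-threshold practice; complete
linkage is available behind a flag. Cluster numbering follows first-seen
input order, so output is deterministic and order-invariant up to
relabeling.

## GMYC delimitation

The single-threshold GMYC model assumes branching older than a threshold
age T reflects speciation and branching younger than T reflects
within-species coalescence. Waiting intervals are delimited by the
branching events *plus the threshold itself*, so every interval lies
wholly on one side of each local threshold. During interval i the total
branching rate is

b_i = λ₁·k_i^p₁ + λ₂·Σ_j [n_ij(n_ij − 1)]^p₂

where n_ij is the lineage count of coalescent group j (a subtree crossing
T) and k_i counts species-level lineages: every observed lineage above
the threshold, plus one persisting species lineage per coalescent group
below it. The persistence term reflects that each delimited species
continues to exist below T even though no further speciation is observed
there; it also guarantees k_i ≥ 1 in every interval, so every event has a
strictly positive rate. The log-likelihood is

logL = Σ_events ln b_(interval ending at the event) − Σ_i b_i·x_i,

with the crown conditioned on (no event term). Events are priced by the
*combined* rate of their interval, as in the published formulation of the
model; pricing by a single process component instead would make a model
with one pooled coalescent group dominate the true many-group structure
(the pooled n(n−1) term absorbs both regimes) and was rejected for that
reason. The null model is the degenerate threshold younger than every
node — a generalized Yule process b = λ₀·k^p₀ — and the mixed likelihood
reduces to it exactly at that threshold, so logL_alt ≥ logL_null by
construction.

**Fitting.** Threshold candidates are midpoints between consecutive
distinct node ages plus the two degenerate extremes (above the root: one
entity; below every node: all singletons). Midpoints avoid ambiguity for
events lying exactly at T. Per candidate, (λ₁, p₁, λ₂, p₂) are fitted by
L-BFGS-B from 5 seeded starts (rates in log space; exponents bounded in
[1e−3, 3], since unconstrained exponents diverge on small trees). The
single-process degenerate cases profile out their rate in closed form,
leaving a concave 1-D problem solved exactly — this is also how the null
model is fitted, so the null value is never an optimizer artifact.

**Testing and counting.** The LR test against the null uses df = 3 by
convention (the chi-bar-square boundary issue is known and not
implemented). Entities include singletons; clusters are entities with ≥ 2
tips. The multiple-threshold variant runs a greedy stepwise search:
starting from the single-threshold optimum, each coalescent group carries
a ladder of local threshold candidates, and the adjacent-rung move with
the best AIC improvement (counting 4 continuous parameters + the number
of distinct thresholds) is accepted until none improves. The search is an
approximation — exhaustive search over per-group thresholds is
exponential — and in well-separated data it typically accepts no moves.

## Diversification models

All models condition on the crown and drop the same combinatorial
constants, so AIC values are comparable across models. With branching
times t₂ ≥ … ≥ t_n and total lineage-time S = Σ k·x_k = 2t₂ + Σ_{i≥3} t_i:

* **Pure birth:** logL(λ) = (n−2)·ln λ − λS, λ̂ = (n−2)/S (closed form).
* **Constant birth–death** (net rate r = λ−μ, extinction fraction
  a = μ/λ): logL(r, a) = (n−2)·ln r − rS + n·ln(1−a) −
  2·Σ_{i=2}^n ln(1 − a·e^{−r·t_i}), written in the numerically stable
  log1p form; it reduces to pure birth exactly at a = 0. Fitted by
  multi-start L-BFGS-B over (ln r, a).
* **Yule-k-rate (k = 2, 3):** piecewise-constant pure birth with shift
  ages searched exhaustively over observed branching times (ordered pairs
  for k = 3; an event at a shift age belongs to the older epoch). Each
  epoch contributes d·ln(d/LT) − d at its MLE rate d/LT; an epoch with no
  events takes the boundary MLE rate 0 (contribution 0). AIC charges
  2k − 1 parameters.

**ΔAICrc** is AIC(best constant) − AIC(best variable); positive values
favor rate variation. Because shift ages are free parameters chosen at
branching times, the null distribution of ΔAICrc is not centred at the
AIC penalty — its median is ≈ 1 and its 95th percentile ≈ 4–6 on trees of
a few dozen tips — which is exactly why the critical value must be
simulated: `critical_delta_aic` refits the best rate-constant model,
simulates `n_sim` (default 1000) trees of the same tip count under its
MLEs, and returns the α-quantile (default 0.95) of the simulated
statistic.

**Ensemble analysis** samples n trees (default 100, without replacement;
the with-replacement flag exists because the sampling convention of the
original analysis is not recorded) from a posterior set, fits the best
constant model and a yule3 (or yule2) model per tree, classifies each
shift as an increase or decrease by comparing the epoch rate younger than
the shift with the older one, and pools shift ages across trees into
means with 2.5/97.5% quantile intervals. The exceedance fraction compares
per-tree ΔAICrc against either one pooled critical value (simulated once
under the median constant-rate fit; default) or per-tree critical values
(slower, behind a flag).

**Net diversification.** `magallon_sanderson` implements the
method-of-moments estimators from standing diversity n, age t and
relative extinction ε: stem r̂ = ln(n(1−ε) + ε)/t and the crown form
r̂ = [ln(n(1−ε²)/2 + 2ε + (1−ε)·√(n(nε² − 8ε + 2nε + n))/2) − ln 2]/t,
which reduces to ln(n/2)/t at ε = 0. It is strictly decreasing in ε and
increasing in n.

## Synthetic data

The generators produce every input the pipeline consumes, with known
truth and bit-reproducible output under a seed.

* **sim_yule(n, λ):** waits with k lineages are Exp(kλ), k = 2..n; the
  present is the instant the (n+1)-th lineage would appear, so the final
  interval has its natural exponential length. Topology grows by uniform
  splits.
* **sim_yule_shift:** epoch rates are defined on fixed ages before
  present, but a forward simulation cannot know the present in advance;
  the tree is therefore drawn by time rescaling — a rate-1 conditioned
  Yule in transformed time u = Λ(age) = ∫λ(s)ds mapped back through the
  piecewise-linear Λ⁻¹. Equal rates reduce exactly to `sim_yule`. A
  consequence worth knowing: with rates (0.05, 0.5) and a shift at 7 Myr,
  the crown age is highly variable and ~15% of 100-tip trees have crowns
  younger than the shift itself, which bounds how often any estimator can
  recover the shift age.
* **sim_bd:** forward Gillespie from the crown, accepted at the first
  instant a birth would raise the survivor count past the target
  (rejection with a 10⁵-attempt cap on clade extinction); extinct
  lineages are pruned to give the reconstructed tree.
* **sim_species_coalescent:** within every species-tree branch the k gene
  lineages coalesce at rate k(k−1)/2 ÷ `coalescent_scale`, i.e. the scale
  is the expected *pairwise* coalescent time in Myr — a deliberately
  unit-free parameterization (no Ne × generation-time bookkeeping)
  matching the Myr-calibrated trees the pipeline works on. Unmerged
  lineages pass to the ancestral branch; the root population is
  unbounded.
* **sim_sequences:** GTR+Γ with the rate matrix normalized to one
  expected substitution per site per Myr; Γ heterogeneity uses the
  standard k equal-probability categories with category means (default
  4). Defaults are COI-like: AT-rich base composition, ~4:1 transition
  bias, Γ shape 0.5, 600 bp. An optional masking step overwrites a random
  terminal run of up to a configured fraction of sites with N per
  sequence, emulating partial-length fragments for the dedup filter.

What the generators do **not** emulate: alignment error, indels,
saturation at deep divergences, rate variation among lineages (no relaxed
clock), non-ultrametric sampling, or fossilized birth–death processes.
Passing recovery tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to real-data
violations of them.

## Study conditions used by the test suite

The recovery and calibration suites run at the scales of the study
system: species delimitation on 10 species × 4 samples with species
divergences ≥ 20× the coalescent depth; rate-shift recovery on 100-tip
trees with a 0.05 → 0.5 shift at 7 Myr; null calibration on 25-tip
constant-rate trees with 500 simulations per side; GMYC type-I behavior
on 40-tip pure-Yule trees. These sizes keep the full suite within a few
minutes on one CPU while leaving every statistical check at its stated
power.

## Numerical choices and degenerate inputs

* Chronogram tip ages are normalized to exactly 0 after checking that the
  root-to-tip spread is within a relative tolerance (default 1e−6;
  dating-software exports carry rounding noise); larger spreads raise an
  error with a per-tip deviation report.
* Polytomies are rejected unless explicitly resolved (zero-length, seeded)
  because all likelihoods here assume binary branching.
* Ties among node ages produce zero-length waiting intervals; their
  survival terms vanish and event terms use the tied interval's counts.
* `k2p` raises on zero overlap; matrix construction flags such pairs and
  excludes them downstream instead.
* Rate parameters are optimized in log space; exponents are box-bounded;
  every optimizer is multi-start with seeded, reproducible starts.
* Reports contain no timestamps and serialize with sorted keys, so a
  fixed configuration and seed reproduce byte-identical bundles.

## Known limitations

* The multiple-threshold search is greedy and keyed to the groups of the
  single-threshold optimum; it cannot move a threshold *above* the
  single-threshold estimate for lineages outside those groups.
* The LR test's df = 3 convention ignores the boundary/selection effect
  of profiling the threshold; empirically the test is conservative on
  pure-Yule trees here, but the p-values are approximations.
* The pooled critical ΔAICrc assumes the posterior trees share a tip
  count and broadly similar constant-rate fits.
* `bd_profile_ci_r` profiles only the net rate; the extinction fraction
  itself is weakly identified on reconstructed trees, and its point
  estimates spread widely (the tests assert only a broad median band).
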