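# Methods

## Model

The data are modeled as a univariate Gaussian mixture
p(x|Θ) = Σ_{m=1..M} α_m N(x; μ_m, σ_m) with weights on the simplex. Fitted
models are always reported in canonical form — components sorted by ascending
mean — so that parameter vectors are comparable across runs despite label
switching. M = 1 is allowed only as a degenerate baseline (EM closed form);
the evolutionary fitter requires M ≥ 2.

## Error functions

**Binned χ² error.** The data range [min, max] is split into B equal-width
bins (left-closed, last bin closed). With observed counts k_j and bin
probabilities p_j computed as CDF differences between the edges (exact, no
midpoint-density approximation), the error is Pearson's
χ² = Σ_j (k_j − p_j N)²/(p_j N). Bin probabilities are floored at 1e-4/B
before scaling by N so empty tail bins cannot produce unbounded terms; the
floor is far below any probability that matters at the sample sizes used.
The default bin count comes from the Scott-type bandwidth
h = 3.49·sd·n^(−1/3): B = ceil(range/h), clamped to [2, n], with the sample
sd (ddof = 1). Any other B can be passed explicitly (`n_bins` / `--bins`).

**Mode-overlap error.** For component m let own_i = α_m N(x_i; μ_m, σ_m) and
other_i = max_{j≠m} α_j N(x_i; μ_j, σ_j), evaluated at the data points. The
per-component overlap is Σ_i min(own_i, other_i) / Σ_i own_i — the fraction
of the component's weighted density mass (as seen through the sample) that is
covered by its strongest competitor. It is exactly 1 for duplicated
components, tends to 0 as components separate, and the overall overlap error
is the maximum over components, so one buried component is enough to flag the
model. Evaluating at the data points (an importance-sample of the mixture)
rather than on a regular grid keeps the measure O(nM) and concentrates it
where data actually live; for the sample sizes used here the difference from
a grid quadrature of the same ratio is negligible.

## The evolutionary fit

Candidates are flat vectors (μ_1..μ_M, σ_1..σ_M, α_1..α_M) with weights
stored normalized. Means and sds are drawn uniformly inside a search box
derived from the data: means within [min, max], sds within
[range/1000, range] (the lower edge prevents single-point spikes); both
overridable. Component blocks within each vector are kept sorted by mean:
this aligns homologous components across the population, without which the
arithmetic crossover averages unrelated modes and the population collapses
toward a single central blob.

Each generation runs: evaluate → select → mutate → recombine.

* **Fitness** = −[t·χ̂² + (1−t)·overlap] with χ̂² = χ²/(χ²+B) ∈ [0, 1), so
  both terms are commensurable and t = 1 reduces exactly to pure χ²
  optimization. The blend is injectable (`combine=`) for experimentation.
* **Selection** is rank-weighted tournament: tournament_size entrants drawn
  uniformly with replacement, winner drawn with probability proportional to
  its fitness rank within the tournament (best = size, worst = 1). The top
  `elitism_count` individuals (default 5, i.e. 5% of the default population)
  pass into the next generation untouched, which makes the best-so-far
  fitness non-decreasing.
* **Mutation** hits each non-elite individual with probability
  mutation_prob (default 0.1) and redraws one uniformly chosen parameter
  slot within its bounds (weights renormalized afterwards). Redrawing a
  single slot is the classic real-coded uniform mutation; redrawing many
  slots at once proved too disruptive for the optimizer to refine solutions
  within the default budget (a multi-slot count remains available via the
  `n_slots` argument).
* **Recombination** pairs off a random disjoint fraction (default 0.8) of
  the non-elite slots; each pair is replaced by its children
  c1 = a·p1 + (1−a)·p2, c2 = (1−a)·p1 + a·p2 with one shared blend weight
  a ~ U[0, 1]. This averaging acts as the local optimizer of the algorithm.

Defaults: population 100, 300 generations, tournament size 3. The run is a
pure function of (data, M, config): a single numpy PCG64 generator seeded
from `config.seed` drives initialization and then, per generation, selection,
mutation and recombination in that fixed order. The returned result carries
the best-ever model, its χ² and overlap, the per-generation best-fitness
trace, and the seed.

The log-likelihood used by AIC floors the mixture density at 1e-300 so that
outliers cannot produce −inf. AIC uses k = 3M − 1 free parameters (M means,
M sds, M − 1 free weights). The likelihood-ratio utility returns only the
statistic max(0, 2ΔlogL): the χ² reference is invalid for mixtures because
the null sits on the parameter-space boundary, so no p-value is attached.

## Bayesian decision boundaries and classification

For each mean-adjacent pair, the boundary is the x in [μ_m, μ_{m+1}] where
α_m N(x; μ_m, σ_m) = α_{m+1} N(x; μ_{m+1}, σ_{m+1}), i.e. the root of a
quadratic in x (linear for equal sds, with the closed form
midpoint + σ²·ln(α_m/α_{m+1})/(μ_{m+1} − μ_m)). Conventions for the
degenerate cases: with two in-interval roots (unequal variances, no sign
change at the endpoints) the root nearest the midpoint of the means is used;
with no in-interval root (one component dominates throughout) the cut is
placed where the absolute log-density difference over the interval is
minimal, so M − 1 cuts always exist for classification. Classification
itself assigns each point to the component with the largest weighted density
(ties to the lower, i.e. lower-mean, label), which coincides with the
boundary partition wherever a true crossing exists.

## EM baseline

A minimal univariate EM fitter provides the likelihood-maximization
contrast: quantile-spread deterministic initialization (means at the
(2i+1)/2M sample quantiles, sds at the sample sd, uniform weights), standard
responsibility/moment updates, stopping when the log-likelihood improves by
less than `tol` (default 1e-8) or after `max_iter` (default 500). Variances
are floored at 1e-8·range² to prevent singular collapse; a component whose
responsibility mass falls below 1e-10·N raises an error rather than being
silently repaired. Because the initialization is deterministic, repeated
runs are bit-identical — the intended contrast with the seed-dependent
evolutionary fit. This is a reference EM, not a clone of any particular
model-selection framework.

## Synthetic scenarios

The built-in scenarios define the study conditions; their parameters are
fixed constants with pinned seeds, all with n = 1000:

* `trimodal_separated`: μ = (0, 5, 10), σ = 1, α = 1/3 — separations of 5σ,
  the benign recovery benchmark.
* `four_modes`: μ = (0, 3.5, 7, 10.5), σ = 1, α = 1/4 — moderate separation
  at a higher mode count.
* `central_dominant`: μ = (−3, 0, 3), σ = (1.5, 1, 1.5), α = (.15, .7, .15)
  — low-weight margin modes overlapping a dominant center; likelihood-only
  fits keep the components entangled (EM's overlap error ≈ 0.76 on the
  pinned sample) while the overlap-penalized fit separates them.
* `superimposed`: equal means, σ = (1, 3), α = (.5, .5) — near-maximal
  overlap (≈ 0.84 at the truth), a shape the separation-seeking fitter is
  deliberately unsuited to.

Sampling is ancestral (component index by weight, then a normal draw). The
generator emulates clean mixture draws only: no measurement floors/ceilings,
rounding, censoring or non-Gaussian subgroup shapes. Tests passing on these
scenarios demonstrate correct recovery of genuinely Gaussian subgroups;
they say nothing about robustness to such artifacts in real instruments.

## Problem sizes and numerical choices

Tests and the acceptance script run the fitter at its defaults on n = 1000
samples, 10 seeds for robustness and model-selection summaries — sizes at
which one full fit takes a couple of seconds and the entire reproduction
under a minute on one CPU. Between-seed coefficients of variation are
reported as sd/|mean| per parameter; for a parameter whose true value is 0
(the first mode of the trimodal scenario) that ratio is ill-defined, and the
absolute between-seed sd is reported and bounded instead. Quantile inversion
brackets the root at means ± 10 max(σ) and widens geometrically before
Brent's method; χ² and overlap computations are deterministic (pure
vectorized arithmetic, no tolerance-dependent branches).

## Known limitations

* The overlap penalty is asymmetric by design: it punishes buried or
  superimposed components, so data genuinely composed of same-mean,
  different-variance subpopulations should be fitted with t = 1 or plain EM.
* AIC with k = 3M − 1 is the conventional count; mixture AIC comparisons are
  heuristic near degenerate fits (vanishing weights).
* The GA explores a box parameterization; means outside [min, max] of the
  data or sds above the data range are unreachable by construction.
* No early stopping: the iteration budget is fixed, and convergence is
  judged only by the recorded fitness trace.
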