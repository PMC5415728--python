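# Methods

## Model and hypotheses

A gene's counts under condition 1 are x₁,…,x_{n₁} ~ NB(μ, ϕ₁) and under
condition 2 are y₁,…,y_{n₂} ~ NB(γμ, ϕ₂), where NB(μ, ϕ) has mean μ,
dispersion ϕ and variance μ + μ²ϕ (ϕ → 0 recovers Poisson). The hypothesis
of interest is H₀: γ = 1 against H₁: γ ≠ 1, tested per gene at a nominal
per-comparison error rate α (no family-wise or FDR machinery is applied;
α is interpreted marginally).

Dispersion is tied to mean expression through the functional trend
ϕ_tr(μ) = a₁/μ + a₀ (a₀ ≥ 0 the asymptotic dispersion, a₁ ≥ 0 the
inverse-mean inflation; not both zero). Simulations use
ϕ₁ = ϕ_tr(μ) evaluated at the *control* mean, and ϕ₂ = ϕ₁ in equal mode or
ϕ₂ = ϕ₁ · r in unequal mode (default ratio r = 1.5). The ratio describes
the data-generating process, so it applies under both hypotheses — the
null constrains only γ. Fitting under unequal mode estimates two free
per-group dispersions under both hypotheses; the ratio is never imposed on
the fit, only on the generator.

## Estimation

The mean parameters have closed-form MLEs: under H₀ the shared mean is the
pooled average μ̃ = (n₁x̄ + n₂ȳ)/(n₁+n₂); under H₁, μ̂ = x̄ and γ̂ = ȳ/x̄
(the per-group sample means are the NB mean MLEs for any fixed dispersion).
Only the dispersion requires numerics: the profile log-likelihood is
maximized by golden-section search on log ϕ over [10⁻⁶, 50] (60
iterations, bracketing to ~10⁻¹¹ relative). Underdispersed data push ϕ̂ to
the lower bound; this is reported as non-convergence but the fit is still
returned (the bound is the constrained optimum). The search is vectorized
across simulation replicates — one golden-section iteration evaluates the
likelihood for the whole batch at once — which is what brings 10⁵-replicate
calibrations from hours to seconds.

Test statistics:

* LRT: L = −2(ℓ₀ − ℓ₁). Nesting guarantees L ≥ 0; optimizer noise in
  (−10⁻⁸, 0) is clipped to zero, anything more negative is flagged.
* Wald: W = (log γ̂ / ŝe)², where ŝe² is the (log γ, log γ) entry of the
  inverse observed information of the full log-parameterization
  (log μ, log γ, log ϕ) — or (log μ, log γ, log ϕ₁, log ϕ₂) in unequal
  mode — obtained by central finite differences with step 10⁻⁵ on the log
  scale. The observed (not expected) information is used; at these sample
  sizes it is the quantity actually available from a fitted dataset.

Datasets in which either group's sample mean is zero leave γ̂ ∈ {0, ∞} and
both statistics undefined. Such replicates are excluded rather than
imputed, and the exclusion fraction is reported (with a warning above 1%)
so that designs with very small μ·n can be judged. Replicates with a
singular observed information are excluded on the same basis; both are
rare outside extreme designs.

## Empirical-parametric calibration

For a design, T_null datasets are simulated under γ = 1 and the chosen
statistic computed on each. The critical value is the order statistic at
ceiling rank ⌈(1−α)m⌉ of the m retained statistics — a conservative,
exactly reproducible convention (no interpolation; the quantile type is a
genuinely open choice and this one errs toward control). The default
simulation sizes are T_null = 100,000 and T_alt = 10,000; a design whose
tail is unresolvable (T_null·α < 10) triggers a warning. The achieved
false positive rate is always evaluated on an *independent* null batch
(disjoint seed substream), because scoring the calibration batch against
its own percentile is circular and biased.

Power is the fraction of T_alt alternative-hypothesis statistics exceeding
the calibrated cutoff, reported with its binomial Monte-Carlo standard
error √(p(1−p)/T_retained).

## Randomness and reproducibility

All draws descend from one root seed through `numpy.random.SeedSequence`
spawn keys. Each (design, role) pair — calibration null batch, alternative
batch, evaluation null batch — has its own substream, keyed by a CRC32 of
the design parameters that the batch actually depends on (the null batches
exclude γ and α). Consequences: reusing a cached calibration across a γ or
α grid is bit-identical to recomputing it; grid cells can run in parallel
in any order; and the γ-batch differs between γ values while the null
batch is shared, exactly as the procedure requires. Counts are generated
by the gamma–Poisson mixture (rate ~ Gamma(shape 1/ϕ, scale μϕ), then
Poisson), which fixes the size = 1/ϕ convention in a single place.

## Grids, sample-size search

`power_grid` crosses n × μ × γ × α, caching null calibrations across γ and
α within each (n, μ, statistic, mode) cell, since the null simulation is
the dominant cost and does not involve γ. `sample_size_for_power` brackets
by doubling from n_min and bisects on the integer grid; because
Monte-Carlo power is not strictly monotone in n, decisions use the running
maximum of the evaluated powers, and the bracketing solution is walked
downward while the target stays met. A target not reached at n_max returns
a not-achievable flag, never an exception.

## Trend estimation from pilot data

The trend ϕ_tr(μ) = a₁/μ + a₀ is fitted from a pilot genes × samples count
matrix with a two-group annotation:

1. **Normalization** — median-of-ratios size factors: the reference is the
   per-gene geometric mean over samples (restricted to genes with
   all-positive counts), each sample's factor is the median ratio to the
   reference, and factors are rescaled to geometric mean 1.
2. **Gene-wise dispersion** — normalized counts are rounded to integers and
   treated as NB observations with free per-group means; the shared
   dispersion is profiled by the same bounded search as the test fits,
   with a floor of 10⁻⁸ for rows showing no overdispersion. Rounding
   re-uses the single NB likelihood implementation; at the trend level the
   bias this introduces is negligible.
3. **Regression** — ordinary least squares of dispersion on (1, 1/mean)
   over genes with normalized mean > 1 and dispersion above the floor, one
   trimming pass dropping residuals beyond 3 MADs, refit, coefficients
   clipped at zero. At least 50 usable genes are required (warning below
   200).

This is deliberately a plain trend estimator, not an empirical-Bayes
shrinkage fit: only the fitted curve — not per-gene dispersions — feeds the
power simulation, and any consistent estimator of the trend serves that
role. Per-gene estimates at S ≈ 20 samples are individually noisy and
biased toward the boundary for weakly-dispersed genes; the robust
regression absorbs this at the curve level, which is why the recovery
tolerances on synthetic pilots are ±30% on a₀ and ±50% on a₁ rather than
tight.

## Synthetic data

Two generators define the simulated study conditions:

* Test datasets: NB counts at the design's (μ, γμ, ϕ₁, ϕ₂), the direct
  embodiment of the model above.
* Pilot matrices (`simulate_pilot_matrix`): G genes × S samples, gene
  means log-uniform on [4, 2000] (spanning low-count to deeply-sequenced
  genes), dispersions exactly on a known trend, equal means in both
  groups — a pilot dominated by non-differential genes.

What these do *not* emulate: per-sample library-size variation (all
samples share a common scale; the normalization step is exercised by
construction rather than by realistic depth imbalance), differential
genes in the pilot, gene–gene correlation, and zero inflation beyond what
NB produces. Passing tests therefore demonstrate correctness of the
calibration and power machinery under the NB model, not robustness to
violations of it.

Default parameter values used throughout examples and tests: trend
coefficients (a₀, a₁) = (0.26, 3.65), with low-dependency (1.56, 3.65) and
high-dependency (0.032, 3.65) variants for sensitivity analyses — note a
smaller a₀ means less dispersion and hence more power; unequal-dispersion
ratio 1.5; grids n ∈ {5, 10, 20, 30, 40}, μ ∈ {4, 20, 100, 500},
γ ∈ {1/3, 1/2, 1/1.5, 1, 1.5, 2, 3}, α ∈ {0.01, 0.005, 0.001, 0.0005}.
γ multiplies the condition-1 mean (γ̂ = ȳ/x̄), so γ and 1/γ are distinct
designs when μ is fixed for condition 1.

## Numerical choices and problem sizes

* NB pmf evaluated entirely in log space via log-gamma; the x = 0 and
  normalization identities are exact to ≤10⁻¹² over μ ∈ [4, 500],
  ϕ ∈ [0.05, 2].
* Dispersion bounds [10⁻⁶, 50] cover Poisson-like to extremely noisy
  genes; the golden-section tolerance leaves log-likelihoods within 10⁻⁴
  of a 10⁴-point grid maximization.
* Hessian step 10⁻⁵ on the log scale balances truncation against round-off
  for log-likelihoods of magnitude ≲10³.
* Test and default problem sizes are chosen so the full suite runs in a
  few minutes on one core: full 10⁵-replicate calibration where the
  headline claim demands it, 2×10⁴–5×10⁴ for distributional-shape and
  ordering checks, 2×10³ alternative replicates for monotonicity sweeps
  (asserted within 3 Monte-Carlo standard errors).

## Known limitations

* Two-group designs only; no covariates, multi-factor GLMs, or exact
  tests.
* Equal library sizes within the simulation; size factors exist only in
  the pilot-trend pathway.
* Marginal (per-comparison) error control; dataset-level power with
  per-gene effect sizes is out of scope.
* The non-estimable exclusion rule slightly biases tail estimates when
  μ·n is so small that exclusions are common; the exclusion fraction is
  reported precisely so this regime is visible.
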