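# nbpower

Power and sample-size analysis for RNA-Seq differential expression at the
single-gene (marginal) level, under the negative binomial model, with
simulation-calibrated critical values that keep the false positive rate at
the nominal level.

## Why

Designing an RNA-Seq experiment requires knowing, for a gene with control
mean expression μ and fold ratio γ between two conditions, how many samples
per group are needed to detect γ ≠ 1 at a given per-comparison error rate α.
Counts are modeled as negative binomial, NB(μ, ϕ) with variance μ + μ²ϕ, and
the two standard tests of H₀: γ = 1 — the Wald test on log γ and the
likelihood-ratio test (LRT) — are usually referred to the asymptotic χ²₁
distribution. At the sample sizes typical of sequencing studies (3–40 per
group) that approximation is anti-conservative: the χ²₁ cutoff rejects true
nulls far more often than α, so power computed against it is an illusion
bought with excess false positives.

`nbpower` instead simulates the null distribution of the chosen statistic
for the *exact* design at hand and uses its empirical 100(1−α)th percentile
as the rejection cutoff (an "empirical parametric test"). Power is then the
fraction of alternative-hypothesis simulations exceeding that calibrated
cutoff, and every power estimate is accompanied by the false positive rate
achieved on an independent null batch — so error control is verified, not
assumed.

## The model

* Counts: x₁..x_{n₁} ~ NB(μ, ϕ₁), y₁..y_{n₂} ~ NB(γμ, ϕ₂).
* Dispersion follows the mean-dispersion trend ϕ_tr(μ) = a₁/μ + a₀,
  estimable from a pilot count matrix; ϕ₂ = ϕ₁ (equal mode) or
  ϕ₂ = ϕ₁ · ratio (unequal mode).
* LRT: L = −2 log(sup_{Θ₀} L / sup_Θ L), with the null mean MLE
  μ̃ = (n₁x̄ + n₂ȳ)/(n₁ + n₂) and alternative MLEs μ̂ = x̄, γ̂ = ȳ/x̄;
  dispersions are profiled out by bounded likelihood maximization.
* Wald: W = (log γ̂ / σ̂_{log γ})², with the standard error taken from the
  numerically differentiated observed information.

Fitting is vectorized across simulation replicates, so a calibration with
100,000 null datasets takes seconds, not hours.

## Worked example

```python
from nbpower import (DesignSpec, DispersionTrend, calibrate,
                     estimate_power, sample_size_for_power)

trend = DispersionTrend(a0=0.26, a1=3.65)   # phi = 0.26 + 3.65/mu
design = DesignSpec(n1=10, n2=10, mu=20, gamma=2.0, alpha=0.01,
                    trend=trend, T_null=20_000, T_alt=2_000,
                    statistic="wald", seed=3)

cal = calibrate(design)
res = estimate_power(design)
ss = sample_size_for_power(design.with_(mu=100.0), target_power=0.8,
                           n_min=2, n_max=40)
```

prints (via the obvious `print` statements):

```
empirical cutoff : 9.054
chi2(1) cutoff   : 6.635
FPR at chi2 cutoff: 0.0234  (nominal 0.01)
power            : 0.274 +/- 0.010
achieved FPR     : 0.0083
n for 80% power  : 17
```

Read: for 10 samples per group at mean expression 20, the calibrated Wald
cutoff is 9.05 — well above the χ²₁ value of 6.63, which here would more
than double the intended α (0.0234 vs 0.01). Against the honest cutoff, a
2-fold change is detected with only 27% power, and the achieved false
positive rate (0.0083, from an independent null batch) confirms control.
At mean expression 100 the design reaches 80% power with 17 per group.

## Command line

```sh
nbpower trendfit counts.tsv labels.tsv -o out/     # fit phi = a1/mu + a0
nbpower calibrate -n 5 --mu 20 --alpha 0.001 -o out/   # cutoffs + QQ TSV
nbpower power --config power.yaml -o out/          # power over grids
nbpower samplesize --config design.yaml -o out/    # smallest adequate n
```

`counts.tsv` is a genes × samples integer matrix (first column gene ids,
header of sample ids); `labels.tsv` maps sample ids to groups 1/2. Every
run writes a `manifest.json` (config + seed + version) from which its
outputs are bit-reproducible. All randomness descends from one root seed
through keyed substreams, so results are independent of parallelism and
evaluation order.

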