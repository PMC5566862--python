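# Methods

This note records the statistical procedures implemented in `powermix`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Per-study power

Power is defined prospectively: the probability that a study's test
rejects at two-sided level α (default 0.05) assuming the population
effect equals the pooled effect of the study's meta-analysis.  This
differs from post hoc power, which would plug in the study's own
estimate.

**Binary outcomes (odds ratio).**  Given the control-group base rate p₀
and the pooled odds ratio, the treated-group rate is
p₁ = OR·p₀/(1−p₀+OR·p₀).  Expected 2×2 counts are e₁₁ = n₁p₁,
e₁₀ = n₁(1−p₁), e₀₁ = n₀p₀, e₀₀ = n₀(1−p₀), and the first-order SE of
the log odds ratio is √(Σ 1/eᵢⱼ).  With μ = |ln OR|/SE and z* the upper
α/2 normal quantile, power = Φ(μ−z*) + Φ(−μ−z*).  At OR = 1 this equals
α exactly for any sample size — the power of a truly null effect is the
type I error rate, which is why studies in null meta-analyses pile up
at 0.05.

**Relative risks** use the analogous delta-method statistic on the log
risk ratio, SE = √((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀)) with p₁ = RR·p₀.
This recipe is a deliberate first-order analogue of the odds-ratio
treatment: the two ratio measures are handled symmetrically, which
should be kept in mind when comparing against software that uses exact
or arcsine-based formulas.

**Standardized mean differences** use the noncentral *t* distribution:
two-sample λ = d√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2 (one-sample λ = d√n,
df = n−1), power = P(|T′(df, λ)| > t*α/2).  Noncentral-t tails come from
scipy's vetted implementation; the null case is routed through the
central t so that power(d = 0) is α to machine precision.  When a
catalogue supplies only a total N, the caller should split it
⌈N/2⌉/⌊N/2⌋ — the most conservative symmetric allocation.

**Accuracy.**  The noncentral-t power is exact for normal data.  The
binary-outcome formulas are first-order approximations: exact
enumeration of all 2×2 tables shows their error against the
finite-sample Wald rejection rate is about 0.005–0.01 at 100 per group,
and below 5·10⁻⁴ by roughly 400 per group.  The Monte-Carlo agreement
tests therefore use design points (chosen by that enumeration) where
the approximation error is negligible relative to Monte-Carlo noise,
and a separate test bounds the small-n error at 0.01.

## Regularized Gaussian mixtures

The density of the n power values is modelled as
p(x) = Σᵢ₌₁ᵏ πᵢ 𝒩(x; μᵢ, σᵢ²), fitted by EM.  Defaults follow the
analysis protocol the package reproduces:

| parameter | default | rationale |
| --- | --- | --- |
| regularization | 0.001 | added to each variance at every M-step; prevents components collapsing onto single points (infinite likelihood) while still resolving the narrow near-α mode |
| restarts | 50 | independent kmeans++ initializations; the best final log-likelihood wins, ties to the lowest restart index |
| tol | 1e-6 | relative log-likelihood change declaring convergence |
| max_iter | 1000 | per restart |
| kmax | 15 (population datasets), 10 (single subfields) | sweep range for BIC selection |

All restarts advance in lock-step as one batched numpy computation, so a
full sweep at n = 730 takes well under a second per k.  Fits are run on
the raw power values in [α, 1] without transformation; the pile-up at
1.0 is absorbed by a narrow component rather than a truncated
likelihood, so fitted component tails (and HDIs) can extend slightly
beyond [0, 1].

Because the regularizer is applied *after* the M-step, the likelihood
is not mathematically guaranteed to ascend at a fixed point: if an
iteration fails to improve the log-likelihood, the chain freezes at its
previous (better) parameters.  In practice the guard almost never
triggers; the recorded trace is non-decreasing by construction and the
ascent property is asserted over randomized datasets in the tests.

Degenerate inputs: all-identical data with k > 1 returns a flagged fit
with variances at the floor; with regularization disabled the fitter
detects collapse (variance at the numerical floor) and flags the fit —
this mode exists only to demonstrate why the regularizer is needed.

**Model selection.**  BIC = −2·logL + p·ln n with p = 3k−1 free
parameters (k means, k variances, k−1 weights).  The sweep reports the
BIC-minimizing k and the gap to the runner-up; a gap of 10 or more on
the natural-log scale is labelled strong evidence.  On well-separated
synthetic mixtures at n = 730 the selection recovers the true component
count in ≥ 80% of seeds (asserted in the tests for k* ∈ {1, 2, 4}).

## Dirichlet-process mixture (robustness check)

A truncated stick-breaking DP mixture is fitted by coordinate-ascent
variational inference with conjugate Normal-Gamma component priors:
v_t ~ Beta(1, α), π_t = v_t Π_{s<t}(1−v_s), τ_t ~ Gamma(a₀, b₀),
μ_t|τ_t ~ 𝒩(m₀, (β₀τ_t)⁻¹).  Defaults: truncation T = 20,
concentration α = 1, β₀ = a₀ = 1, with m₀ and b₀ centred empirically on
the data mean and variance.  The ELBO is computed in closed form and is
non-decreasing across iterations (asserted in tests).

The number of occupied components is reported as the count of
components whose expected share of observations N_t/n exceeds 1/n.
(The raw stick means are unsuitable for this: a fixed concentration
leaves residual prior mass ≈ α/(n+α) on the empty truncation tail,
exactly at the 1/n scale.)  The DPGMM is a qualitative cross-check on
the BIC selection — agreement within about one component is the
expected behaviour — and the finite regularized mixture remains the
primary inference.

## Highest-density intervals

The 95% HDI of a fitted mixture is the super-level set
{x : p(x) ≥ c} with c chosen by bisection so the enclosed probability
(evaluated with the exact mixture CDF over the level set's intervals)
equals the target mass within ±0.002.  Level-set boundaries are located
on a 4096-point grid spanning every component's mean ± 6 SD, with
linear interpolation at the crossings; a grid too coarse to reach the
mass tolerance raises an error rather than returning a bad interval.
For multimodal fits the HDI is a union of disjoint intervals — the
informative summary a central interval cannot provide.  Raw-data
summaries (2.5th/97.5th percentiles) use numpy's linear interpolation
convention throughout.

## Subfield comparisons

The K-group test of equivalence is a permutation test: the observed
tie-corrected Kruskal–Wallis H is compared with its distribution under
n_perm (default 9999) random label permutations, with the add-one
p-value (1 + #{H_perm ≥ H_obs})/(1 + n_perm), so p ≥ 1/(n_perm+1).  The
statistic is a design choice — the protocol being reproduced names the
test but not its statistic — and H is the natural K-group companion of
the Mann–Whitney follow-ups.  Pairwise Mann–Whitney U tests (reference
group = lowest-median subfield) use the tie-corrected normal
approximation without continuity correction and report raw p-values; a
Holm adjustment is available but off by default, matching the
reproduced analysis's unadjusted reporting.

## Field simulations

A hypothetical field is n_sim = 50,000 one-sample-t studies at n = 45,
α = 0.05.  A fraction `prop_true` of effects is drawn from
𝒩(effect_mean, 0.07²) truncated to (0, ∞) by exact rejection sampling
(not clipping); the rest are half-Gaussian |𝒩(0, 0.07²)|.  Effect means
0.3 and 0.49 give "low-power" (~50% median) and "high-power" (~90%
median) fields.  Mixing 25% true effects with 75% null-like effects
produces the bimodal shape — a pile-up near α plus the true-effect mode
— that pure low-power fields cannot produce.  An alternative mode holds
the effect fixed and varies sample sizes log-normally instead; it is
off by default.

## Synthetic catalogue generator

Published meta-analysis tables print pooled effects and CIs but not the
per-study group sizes and base rates that power computation needs, so
the generator emulates them with known ground truth.  Structure is
copied from the built-in catalogue: 49 meta-analyses, the same
per-meta-analysis study counts (730 studies), the same subfield
composition, and 7 planned null meta-analyses (3 genetic, 4 treatment)
whose pooled effect is exactly null — making every one of their studies'
powers exactly α.

Per subfield, meta-analytic effects are drawn from positive-truncated
normal (Cohen's d) or log-normal (odds ratio) laws, and per-group study
sizes from log-normal laws.  The default locations and scales were
calibrated against the power formulas so subfield median powers
approximate the real catalogue's ordering (genetic lowest at ~0.10,
treatment ~0.2, imaging ~0.33, neurochemistry/psychology ~0.45–0.55,
miscellaneous highest) and the overall histogram is multimodal with a
low-power mode dominated by genetic and null studies.  CIs are
synthesized from the summed per-study Fisher information (normal
approximation on the analysis scale), and significance markers are set
from whether the CI excludes the null; consequently a few additional
meta-analyses with modest effects honestly come out non-significant
beyond the planned seven, as happens in real catalogues.

What the generator does **not** emulate: publication bias (which would
inflate pooled effects and hence the power estimates), between-study
heterogeneity within a meta-analysis (all studies share the pooled
effect exactly), correlated designs, and unequal group sizes beyond
independent draws.  Tests passing on synthetic catalogues therefore
validate the pipeline's mechanics and the qualitative multimodality
phenomena, not any quantitative claim about real literatures.

## Pipeline

`run_reanalysis` computes per-study powers and fits BIC-selected
mixtures on fourteen datasets — all studies; excluding null
meta-analyses; each of the six subfields (kmax 10); and each
leave-one-subfield-out complement (kmax 15, same as the full dataset) —
then computes 95% HDIs per winner, cross-tabulates hard component
assignments against subfield and null labels, and runs the subfield
tests.  Every dataset's sweep receives its own seed derived from the
master seed via `numpy.random.SeedSequence`, so identical configuration
yields byte-identical reports.  Tests and examples run the pipeline at
reduced settings (kmax 3–4, 8 restarts) — the scaled-down problem sizes
chosen for the test suite; the defaults reproduce the full protocol.

## Known limitations

* The binary-outcome power formulas are first-order; at fewer than ~100
  participants per group their error against the exact Wald rejection
  rate approaches a percentage point.
* The relative-risk treatment mirrors the odds-ratio recipe by design
  and is not an exact method.
* Mixture components are Gaussian on the raw power scale; boundary
  effects near 0 and 1 are modelled by narrow components, and fitted
  tails (and HDIs) can spill slightly outside [0, 1].
* The DP concentration is fixed rather than given a gamma hyperprior;
  the DPGMM is a robustness check, not the primary inference.
* The permutation test's statistic and permutation count are package
  choices; exact p-value reproduction of any specific published analysis
  is not a goal.
* Real-data runs at the level of individual studies require a
  user-supplied studies file (group sizes and base rates per study);
  the built-in catalogue alone supports only meta-analysis-level
  operations.
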