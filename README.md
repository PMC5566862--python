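# powermix

Statistical power of primary studies under meta-analytic effect sizes,
and the mixture structure of power distributions across a research
field.

## The problem

A field-wide claim like "median statistical power is 21%" compresses
hundreds of studies into one number.  If those studies fall into
distinct subpopulations — null effects pinned at the type I error rate,
underpowered candidate gene association studies, well-powered psychology
meta-analyses — a single median misleads: the distribution is
multimodal, and no measure of central tendency describes it.  `powermix`
provides the machinery to look underneath the median:

* **Per-study power.**  The power of study *i* is the probability it
  declares significance assuming the population effect equals the pooled
  (weighted-mean) effect θ̂ of its meta-analysis — not the study's own
  estimate (this is *not* post hoc power).  For binary outcomes the test
  statistic is ln(OR)/SE with SE = √(1/e₁₁ + 1/e₁₀ + 1/e₀₁ + 1/e₀₀) over
  the expected 2×2 cell counts, referenced to the standard normal; for
  standardized mean differences the noncentral *t* distribution is used
  (two-sample: λ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2).  When the pooled
  effect is exactly null (OR = 1, d = 0), power equals α for every
  sample size.
* **Mixture modelling.**  One-dimensional Gaussian mixtures
  p(x) = Σᵢ πᵢ 𝒩(x; μᵢ, σᵢ²) fitted by EM with kmeans++ initialization
  and 50 restarts; a regularization constant (0.001) added to each
  variance at every M-step prevents likelihood singularities (a
  component collapsing onto a single observation).  The number of
  components is selected by BIC = −2·logL + (3k−1)·ln n, with ΔBIC ≥ 10
  treated as strong evidence; a truncated variational Dirichlet-process
  mixture serves as a selection-free robustness check.
* **Multimodal summaries.**  95% highest-density intervals of the fitted
  mixture (possibly several disjoint intervals), raw percentiles, and
  component-by-subfield cross-tabulations.
* **Group comparison.**  A permutation test of subfield equivalence on
  the Kruskal–Wallis statistic plus pairwise Mann–Whitney U follow-ups.
* **Field simulation.**  Hypothetical fields mixing true effects
  (positive-truncated Gaussian) with null-like effects (half-Gaussian),
  showing how the proportion of true effects shapes the power
  distribution.

The package ships a 49-meta-analysis neuroscience catalogue (730
studies, six methodological subfields, seven null meta-analyses) as a
built-in fixture, and a synthetic-data generator that emulates the
study-level designs (group sizes, base rates) that published tables do
not print.

## Worked example

```python
import numpy as np
import powermix as pm

catalogue = pm.load_builtin_catalogue()          # 49 meta-analyses, 730 studies
len(pm.null_meta_analyses(catalogue))            # 7 null meta-analyses

# the catalogue does not print per-study designs; emulate them
cat, truth = pm.generate_catalogue(pm.default_synth_config(seed=0))
powers = pm.compute_study_powers(cat)
powers["power"].median()                         # 0.277
powers.groupby("subfield")["power"].median()     # genetic 0.10 ... psychology 0.58

sweep = pm.sweep_and_select(powers["power"].to_numpy(), 8, pm.FitConfig(seed=0))
print(sweep.winner_k)                            # 4
for c in sweep.winner.components:
    print(f"weight {c.weight:.2f}  mean {c.mean:.2f}")

res = pm.hdi(sweep.winner, mass=0.95)
print(res.intervals)                             # two disjoint intervals
```

Output of the mixture fit above:

```
winner k = 4 delta BIC = 8.9
  weight 0.22  mean 0.05  sd 0.032     <- null + tiny-effect studies near alpha
  weight 0.32  mean 0.20  sd 0.066     <- underpowered mode
  weight 0.34  mean 0.46  sd 0.105     <- moderately powered mode
  weight 0.12  mean 0.79  sd 0.085     <- well-powered mode
95% HDI: [-0.01, 0.65], [0.70, 0.86]
```

The overall median (0.28) sits between modes: the distribution is a
blend of a near-α pile-up (every study in a null meta-analysis has
power exactly 0.05 regardless of its size), an underpowered mass
dominated by genetic studies, and adequately powered clusters.  The same
analysis runs end to end from the shell:

```sh
powermix synth --seed 0 --out-catalogue cat.csv --out-studies studies.csv
powermix power --catalogue cat.csv --studies studies.csv --out powers.csv
powermix fit-gmm --input powers.csv --kmax 8 --seed 0 --out sweep.json
powermix reanalyze --synthetic --outdir report/ --seed 0
powermix simulate-field --effect-mean 0.3 --seed 1 --out field.csv
# -> median power 0.504, mean power 0.510; histogram in field.csv
```

`reanalyze` fits mixtures on fourteen datasets (all studies, excluding
null meta-analyses, each subfield, and each leave-one-subfield-out
complement) and writes CSV tables plus a JSON report of fits, HDIs and
subfield tests.

## Layout

| module | contents |
| --- | --- |
| `powermix.catalog` | data model, built-in catalogue, CSV I/O, validation |
| `powermix.power` | per-study power formulas (OR, RR, one/two-sample t) |
| `powermix.mixture` | regularized EM, kmeans++, BIC sweeps, densities |
| `powermix.dpgmm` | truncated variational Dirichlet-process mixture |
| `powermix.density` | highest-density intervals, percentile summaries |
| `powermix.groups` | permutation equivalence test, Mann–Whitney U |
| `powermix.fieldsim` | hypothetical-field power simulations |
| `powermix.synth` | synthetic catalogue generator with ground truth |
| `powermix.pipeline` | end-to-end orchestration and reports |
| `powermix.cli` | `powermix` command-line interface |

See `docs/methods.md` for the statistical details, default parameters
and known limitations.
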