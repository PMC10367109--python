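# esoikit

Analytics for the sexual-orientation continuum: questionnaire scoring,
a social-pressure mixture model, and synthetic survey cohorts.

## The problem

Large online surveys measure sexual orientation with the 18-item Epstein
Sexual Orientation Inventory (ESOI): nine items about opposite-sex (OS)
fantasies, attractions and behaviors and nine about same-sex (SS) ones.
Each respondent is placed on a 0–18 continuum by two derived scores:

- **MSO** (mean sexual orientation) — the midpoint of the points
  associated with the two subscale inclinations, `MSO = 9 + s − o`,
  where `o, s ∈ [0, 9]` are the equally-weighted OS and SS subscale
  sums (items normalized to [0, 1]). 0 means exclusively opposite-sex
  inclinations, 18 exclusively same-sex, 9 a balanced mix (also the
  score of a fully asexual respondent).
- **SOR** (sexual orientation range) — the breadth `o + s` of the
  continuum interval the inclinations span.

Self-labels ("straight", "gay/lesbian", …) map onto broad, overlapping
MSO distributions, and the mismatch between a respondent's label anchor
(0 for straight, 18 for gay/lesbian) and their MSO — the **deviation
score** — correlates with the distress they report about their
orientation.

The population-level model is the **social-pressure theory (SPT)**
mixture: MSO is distributed as a two-component linear combination of
sinh-arcsinh (Jones–Pewsey) densities,

    f(x) = (1 − π) f_SAS(x; μ₁, σ, ε₁, δ) + π f_SAS(x; μ₂, σ, ε₂, δ),

where π is the weight of the pressure-resistant SS component and a
scalar social pressure S deforms the components linearly
(μ₁ = 9 − λ₁S, ε₁ = −κ₁S; μ₂ = 9 + λ₂S, ε₂ = +κ₂S). At S = 0 the
mixture is a single symmetric bell centred at 9; as S grows it skews
toward the OS end and, past a critical pressure S*, a second mode
appears at the SS end — categorical-looking orientation groups emerge
from a continuous population under pressure.

Because the underlying survey data are not publicly archived, the
package ships a synthetic-cohort generator that reproduces the
statistical structure the analyses assume (latent SPT mixture, feasible
SOR, item-level responses that re-score to the latent values,
overlapping labels, Gaussian-copula rank correlations, cleaning-rule
violations), so every pipeline stage is testable end to end.

## Worked example

```python
from esoikit import (CohortConfig, PressureMixture, SPTModel, apply_pressure,
                     clean_records, count_modes, critical_pressure,
                     generate_cohort, score_table)
from esoikit.stats import group_tests, moment_skew_kurtosis

cfg = CohortConfig(n=20_000, seed=7)           # survey-calibrated defaults
raw, manifest = generate_cohort(cfg)
cleaned, report = clean_records(raw)
scored = score_table(cleaned)

base = PressureMixture()
res = SPTModel.from_scores(scored["mso"].to_numpy(),
                           free=("mu1", "sigma1", "eps1", "mix_rate")).fit()
```

Output of the full script (see the docstrings for the intermediate
print statements):

```
rows in: 22600  removed: 1200/800/600 (incomplete/fluency/duplicate)  retained: 20000
MSO mean=8.51 sd=3.28 Skp=0.040 kurtosis=2.69
straight deviation~distress Spearman rho=0.31 (n=2009)
modes at S=0: 1   at S=2.5: 2
critical pressure S* = 1.604
fitted mu1=8.42 sigma1=3.29 eps1=0.020 pi=0.001 (loglik=-52159, converged=True)
```

Reading this: the generator injected 2,600 dirty rows and cleaning
removed exactly those, leaving the 20,000 clean respondents. Their MSO
distribution sits at mean 8.5 (the generator's configured latent
location) and is nearly symmetric. Among self-labeled straights,
deviation from the label anchor rank-correlates with reported distress
at ρ ≈ 0.3, the configured set-point. The default pressure model is
unimodal at S = 0 and bimodal by S = 2.5, with the transition bracketed
at S* ≈ 1.60. Refitting the mixture to the scored histogram recovers
the generating location and scale.

The same pipeline is available from a shell:

```
esoikit simulate --config cohort.json --seed 7 --out cohort.csv
esoikit clean-score --input cohort.csv --out scored.csv
esoikit analyze --input scored.csv --outdir reports/
esoikit sweep --config sweep.json --out densities.tsv
esoikit fit --input scored.csv --out fit.json
```

## Layout

| module | contents |
| --- | --- |
| `esoikit.sas` | sinh-arcsinh density, CDF, quantiles, sampling |
| `esoikit.model` | `PressureMixture`, pressure deformation, mode counting, critical pressure, `SPTModel`/`SPTResults` binned ML fit |
| `esoikit.scoring` | cleaning rules, subscale/MSO/SOR/sex-drive/deviation scoring |
| `esoikit.cohort` | `CohortConfig`, synthetic cohort generator, contamination injection |
| `esoikit.stats` | histograms, moments, deviation curves, nonparametric tests, raking, subgroup skew reports |
| `esoikit.cli` | `esoikit` command-line pipeline |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
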