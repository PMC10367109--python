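# Methods

## Scoring model

Each ESOI item is a 4-point ordinal response 0–3 (the response scale is
an assumption of this implementation; any bounded ordinal scale
normalizes identically, so all contracts are stated in normalized
[0, 1] item space). Items are weighted equally. With `o` and `s` the
normalized OS and SS subscale sums on [0, 9], the derived scores are
the affine forms

    MSO = 9 + s − o,   SOR = o + s,   sex drive = 10 · mean item level.

These are the unique affine definitions consistent with all published
anchor values of the instrument: a fully silent (asexual-pattern)
respondent scores MSO 9, SOR 0 and sex drive 0; exclusive OS and SS
patterns score MSO 0 and 18; SOR spans 0–18 and is maximal for
balanced-and-strong (bisexual-pattern) inclinations. The interior
behaviour of the official scoring sheet is not published, so interior
values may differ from the instrument's own arithmetic; every printed
anchor is reproduced exactly and is asserted in the tests. A subscale
with missing items is mean-imputed by rescaling with 9/answered; an
entirely missing subscale scores 0 with a warning, because distinct
inclinations genuinely scored 0 and "not measured" cannot be separated
at that point.

Deviation is defined only for the two label groups with a continuum
anchor: straight (expected MSO 0) and gay/lesbian (expected 18). All
other labels return NaN rather than a silent 0.

**Cleaning** applies three rules in a fixed order — (1) fewer than 9 of
18 items answered, (2) English fluency below 6 of 10 (a missing rating
fails the rule and is counted separately in the report), (3) same user
key on the same calendar date keeps only the earliest timestamp — and
reports per-rule removals. Order matters for attribution only (a record
failing two rules is counted under the first); the retained set is
order-invariant and cleaning is idempotent.

## Pressure mixture

The population MSO density is a two-component sinh-arcsinh mixture.
The sinh-arcsinh family uses the sign convention
`T(z) = sinh(δ·asinh(z) − ε)` with density
`f(x) = δ/(σ√2π) · cosh(·)/√(1+z²) · exp(−T²/2)`, so positive ε skews
mass toward larger x; ε = 0, δ = 1 collapses to Normal(μ, σ) exactly,
which the tests exploit as a closed-form oracle (agreement to 1e−12).

Social pressure S deforms a symmetric base (both components at the
continuum centre 9) linearly:

| parameter | meaning | default | units |
| --- | --- | --- | --- |
| σ | component scale | 3.0 | MSO points |
| δ | tail weight | 1.0 | – |
| π | SS (pressure-resistant) component weight | 0.07 | probability |
| λ₁, κ₁ | non-SS location shift / skew per unit S | 2.0, 0.4 | points, – |
| λ₂, κ₂ | SS location shift / skew per unit S | 1.5, 0.3 | points, – |

The mapping of S onto component parameters is this package's concrete
instantiation of the theory, which specifies the mixture family and the
qualitative effect of pressure but not a functional form for the
deformation; the defaults were chosen so that sweeping S
from 0 reproduces the documented qualitative sequence — symmetric bell,
then OS-ward skew, then a bimodal density with a minor SS-end mode —
and every coefficient is configurable. The construction makes S ↔ −S an
exact mirror about 9, which is asserted as an identity. With the
defaults the unimodal→bimodal transition sits at S* ≈ 1.6 (computed by
bisection at tolerance 1e−3; the suite asserts the transition occurs
exactly once on [0, 3]).

Densities live on the whole real line; histogram binning uses 19 unit
bins centred at 0…18 with the tails folded into the end bins, which
preserves normalization rather than truncating. Moments are computed by
adaptive quadrature between the 1e−13 component quantiles (heavy-tailed
δ < 1 settings extend far beyond any fixed multiple of σ); kurtosis is
reported non-excess (normal = 3), the convention used in survey
psychometrics. Mode counting evaluates the density on a 0.01 grid over
[0, 18], collapses plateaus, and counts strict local maxima including
the endpoints — a grid is more robust than root-finding when the second
mode emerges as a shoulder.

**Fitting** maximizes the multinomial log-likelihood of the 19 bin
counts with bin probabilities from CDF differences. Optimization is
bounded Nelder–Mead (σ, δ ∈ [0.1, 20], π ∈ [0.001, 0.5], μ ∈ [0, 18],
ε ∈ [−5, 5]) with x/f tolerances of 1e−8; the free-parameter set is
caller-chosen (default μ₁, σ₁, ε₁, π), remaining parameters stay at
their start values. Non-convergence returns the best point found with
`converged=False`; a histogram with all mass in one bin is flagged
degenerate without optimizing. Parameter recovery on simulated counts
(n = 10⁵) is asserted at ±0.1 on μ and σ and ±0.02 on π.

## Synthetic cohorts

The generator's defaults are calibrated to the survey conditions the
analyses assume: latent MSO location 8.5 with scale 3.4 (the full-sample
mean and SD), label prior weights at the sample's label proportions,
deviation–distress Spearman targets 0.29 (straight) and 0.10
(gay/lesbian), distress–uncertainty target 0.63, demographic margins at
the sample's gender/race/education proportions with a banded age margin
reproducing median 18 and mean ≈ 22, and contamination rates
(6% incomplete, 4% low-fluency, 3% same-day duplicates) totalling
roughly the fraction the real cleaning removed. Where the source
reports no value (softmax temperature 3, changed-SO logistic slope 0.3
and intercept −1, Beta(2, 2) SOR law), a single realistic choice was
made and documented here.

Steps worth flagging:

- **SOR feasibility.** Given MSO = m, the range r must satisfy
  |m − 9| ≤ r ≤ 18 − |m − 9| for the implied (o, s) to stay in [0, 9]².
  r is drawn as a Beta(2, 2) rescaled to that interval — smooth,
  symmetric, and zero mass at the degenerate endpoints — so
  infeasibility is impossible by construction (still asserted).
- **Item expansion.** round(3o) raw points are spread over 9 items by
  largest-remainder allocation (equal quotas, remainder to random
  items) plus one point-preserving random swap. Totals are preserved
  exactly, so re-scoring recovers o and s to within the rounding error
  of 1/6 — comfortably inside the ±0.5 contract asserted per row.
- **Copulas.** Spearman targets are converted to latent Gaussian
  correlations by ρ_p = 2·sin(πρ_s/6); distress couples to the normal
  scores of the within-label deviation ranks, uncertainty to the latent
  (pre-discretization) distress. Discretizing to the 1–10 scale
  attenuates the observed rank correlation by under 1%, well inside the
  ±0.02 recovery tolerance the suite asserts at n = 5·10⁴.
- **Truncation.** The latent mixture is rejection-sampled into [0, 18].
  With the default location 8.5 the asymmetric truncation shifts the
  realized mean by about +0.03 and adds a small positive skew — real
  bounded-scale artifacts, left in deliberately.
- **Contamination.** Dirty rows are cloned from clean rows and then
  broken (13 items blanked; fluency 1–5; duplicate timestamp one hour
  later, with clean timestamps capped at 22:00 so the duplicate never
  crosses midnight). The manifest of injected ids lets tests assert
  that cleaning removes exactly the injected rows.

What the generator does **not** emulate: any joint demographic
structure (margins are independent), within-label differences among the
four centre labels beyond prior weight, country-specific distribution
shapes, age- or cohort-dependent MSO structure, item-level response
styles (acquiescence, straight-lining), or repeat participation beyond
same-day duplicates. Tests passing on these cohorts therefore validate
the pipeline's arithmetic and its recovery of configured structure —
not claims about real populations.

## Analysis battery

Nonparametric tests (Kruskal–Wallis H, Mann–Whitney U, two-sample
Kolmogorov–Smirnov D, Spearman ρ) use mid-ranks with tie correction and
two-sided p-values; Cohen's d uses the pooled SD. Tiny-roster
brute-force enumerations (pairwise U counting, the rank-sum H formula)
serve as oracles in the tests. The distress/uncertainty subgroup split
is high ≥ 8, low < 4 with the 4–7 band excluded — a literal reading of
the "8 or over" versus "under 4" cut-offs. Demographic matching rakes case weights to the
target margins by iterative proportional fitting (tolerance 1e−6, max
100 iterations, unattainable margins reported by name) and then draws
the subsample by systematic probability-proportional-to-size sampling
over a cell-sorted ordering — sequential weighted draws without
replacement would bias the achieved margins back toward the sample's
own composition, while the systematic pass hits each cell's share to
within one record.

## Problem sizes and runtime

The suite generates cohorts of 10⁵ (distribution recovery), 5·10⁴
(correlation recovery) and smaller rosters throughout; the full test
run takes a few seconds on one core, and the acceptance script —
which regenerates the 10⁵ and 5·10⁴ cohorts from scratch — under ten.
These sizes put Monte-Carlo error well inside every asserted tolerance
(e.g. SE of the mean ≈ 0.011 MSO points at n = 10⁵).

## Known limitations

- Interior scoring may deviate from the unpublished official scoring
  sheet (anchors are exact; see above).
- The S-mapping is one concrete member of the family of deformations
  consistent with the theory's qualitative statement; fitted values of
  S are therefore not comparable across different deformation
  coefficients.
- The binned likelihood discards within-bin information; with 19 bins
  this is negligible for location/scale but limits precision on δ.
- Raking matches margins only; it cannot correct joint-distribution
  bias, and empty target cells abort rather than extrapolate.
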