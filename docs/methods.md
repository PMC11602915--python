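# Methods

This note documents the models, defaults and numerical choices behind
`urbanpoverty`, and what the synthetic study conditions do and do not show
about real survey data.

## Survey model and weighted primitives

A city is a household table plus a person roster linked by `household_id`.
All prevalence estimation is the weighted ratio Σwᵢxᵢ/Σwᵢ over the requested
subset, with listwise exclusion per indicator: a household missing the
indicator leaves both sums. The unweighted count of contributing households
(effective n) is always reported next to the point estimate. An empty
domain raises rather than returning 0, since a 0% prevalence and "nobody to
estimate on" are different findings. Design-based (Taylor-linearised)
variance estimation is intentionally out of scope; the package reports
point estimates and group sizes only.

Percentile ranks use the midpoint cumulative-weight rule:
rank(h) = (W(score < s_h) + ½·W(score = s_h)) / W(total). This makes ranks
invariant to weight rescaling, monotone in the score, deterministic under
row permutation, and puts a tie block at its centre of mass, so cut-off
classification of ties never depends on input order. Ranks are computed
from household weights only; a `rank_weighting` extension to
weight-times-members was considered and left out because the household is
the analysis unit throughout.

## Wealth index

The score is the first principal component of the standardised indicator
matrix (binary assets plus derived electricity / improved-water /
improved-sanitation / clean-fuel / durable floor, wall, roof indicators).
The covariance used is weighted by household sampling weights; since the
indicators are standardised by their weighted SDs this is PCA on the
weighted correlation matrix, as in the DHS wealth-index tradition. The
leading eigenvector is taken from a symmetric eigendecomposition
(`numpy.linalg.eigh`), and the sign is oriented so the score correlates
positively with the raw count of assets owned. Zero-variance indicators are
dropped with a warning; fewer than two usable indicators is an error.
Missing indicator cells are imputed to the variable mode (logged) — they
only feed the PCA, never the outcome classifiers.

When a survey ships its own wealth score, the pipeline computes the Pearson
correlation between the re-computed and provided scores, flips sign if they
are oppositely oriented, and uses the provided score when r ≥ 0.95
(configurable, recorded per city in `wealth_validation.csv`).

## Predicted-income poverty line

The within-city income distribution is taken lognormal. For a lognormal,
Gini = 2Φ(σ/√2) − 1, so σ = √2·Φ⁻¹((G+1)/2); the round trip is analytic
and exact to machine precision. The city mean income per capita defaults to
GDP per capita × (household final-consumption share / total
final-consumption share); an alternative `hh_share_of_gdp` mode
(GDP pc × household share/100) is provided because the exact combination of
the two World Bank consumption series is a modelling choice. A household at
wealth rank r gets income exp(μ + σΦ⁻¹(r)) with μ = ln(mean) − σ²/2; ranks
at 0 or 1 are clamped to [1/(2n), 1 − 1/(2n)] and logged.

Division by household size: the default (`division="household"`) treats the
prediction as household income and divides by `n_members` before the
÷365.25 daily conversion. If the model mean is read as already per capita
this double-counts size, so a `percapita` mode skips the division; both are
exposed and the choice is recorded in the run manifest. Poverty is strict
`daily < 1.9`, with a 1e-12 relative tolerance so that an income placed
exactly on the line by construction is classified not-poor despite
floating-point round trips (exp∘log is not the identity in floats). No PPP
conversion is applied: the line is a plain threshold in model currency
units.

## SDS and slum

SDS uses nested equal weights: two education deprivations at 1/4 each, six
living-standards deprivations at 1/12 each, deprived when the score
≥ 1/3. The living-standards set is electricity, improved water, adequate
sanitation, durable housing, clean cooking fuel, and asset poverty (owns at
most one of radio/TV/fridge/phone/computer/bicycle/motorcycle and no car).
Clean cooking fuel completes the six-indicator living-standards dimension
following the MPI convention from which SDS derives. Weights and threshold
are constructor arguments and are validated to sum to 1.

The slum classification fails a household that lacks any of: durable floor,
wall *and* roof; ≤ 3 persons per habitable room; an improved water source
within a 30-minute round trip (threshold inclusive); improved, unshared
sanitation. Security of tenure is not measurable in these surveys and is
excluded. A household with a missing criterion input is excluded from the
classification (logged) rather than defaulted to deprived — defaulting
would inflate slum prevalence exactly where data quality is worst.

All improved/durable/clean code lists live in a versioned YAML variable
dictionary shipped with the package and aligned with the WHO/UNICEF JMP
ladders; classifiers take a dictionary argument so a study can override it.

## Outcomes

Five household outcomes: school-age child (default ages 6–14) out of
school; low education; no electricity; no improved water (unimproved
source, or improved but ≥ 30 minutes round trip — a missing time on an
improved source counts as near, logged); no improved sanitation
(unimproved, none, or improved-but-shared; a missing shared flag on an
improved facility makes the outcome missing). Households with no school-age
children are *not deprived* on the schooling outcome (they stay in
denominators), following MPI practice.

Low education is stated two ways in common usage — "no member aged 10+
with at least six years" versus "any member older than 10 with under six
years" — which disagree on mixed households. The default is the first
(household-level) reading, consistent with the SDS education indicator; the
`any_member` mode implements the second. Both are pure functions of the
roster and the choice is recorded in the manifest.

## Measure evaluation and selection

Observed agreement between two measures is the share of households given
the same label, unweighted by default (a weighted mode exists): agreement
is a property of the classification exercise, not a population estimate.
Across-city summaries (sample-size medians/IQRs, agreement medians, gap
medians) weight each city once, regardless of its sample size.

The selection rule is deliberately frozen: (1) eligible measures need a
median poorest-group count ≥ 100 across cities; (2) among eligible
*relative* measures, keep those whose median agreement with **every**
absolute measure is ≥ 0.60; (3) of the survivors take the largest mean
absolute median gap over the five outcomes, ties toward the smaller
cut-off (a smaller poorest group at equal discrimination is the sharper
instrument). Both thresholds are parameters, and the decision record lists
every criterion value for every measure so a reader can audit (or overrule)
the choice. No survivors is an explicit no-selection result.

## Performance classes and context correlations

Prevalence bands: low < 5%, intermediate 5–15% (both edges inclusive),
high > 15%. Inequality: low when the rich−poor gap is within ±5 pp
(inclusive). Classes: (low, low) good; (intermediate, low) and (low, high)
intermediate; everything else worse. The (high prevalence, low inequality)
cell is not covered by the verbal rule the bands come from; it maps to
*worse* here because a uniformly high burden cannot be good performance.
The quadrant uses the overall city prevalence by default
(`prevalence_basis="poor"` switches to the poor-group prevalence).

Correlations are Pearson r per outcome × statistic (prev_poor, prev_rich,
gap) × index (HDI, health, education, income), with 95% CIs from the
Fisher z-transform, tanh(atanh r ± 1.96/√(n−3)), and the per-cell n
reported. Cells with under 4 cities or an exactly constant variable are
flagged undefined instead of raising. No multiplicity adjustment is
applied across the cells.

## Synthetic study conditions

The generator emulates the latent structure the analysis assumes: each city
c has a mean socioeconomic level m_c ~ N(0, 0.6²) (`city_ses_spread`), each
household a latent SES z ~ N(m_c, 1.2²). Binary assets and service
indicators are Bernoulli with logit linear in z; the intercepts give
realistic urban ownership levels (e.g. phones common, cars rare) and the
loadings (≈ 0.7–1.6) give the strong socioeconomic gradients urban service
access actually shows. Rosters of size 1–15 (mode 4) carry an adult head;
education years follow a logistic fraction of the age-feasible maximum with
gradient `education_gradient`·z, and school attendance has its own
gradient. Weights are uniform on [0.5, 2] normalised to mean 1 per city;
clusters are contiguous blocks of 20. City context: Gini and GDP per capita
are drawn within configured ranges with mild negative / positive
correlation to m_c; the three HDI sub-indices are 0.30 + 0.40·Φ(m_c/spread)
plus N(0, `hdi_noise_sd`²) noise, clipped to [0, 1], and HDI is their mean.
The defaults (38 cities of 500–2,000 households, Gini 0.35–0.65, GDP pc
800–8,000) define the standard test scenario; the full default scenario
(~48k households) generates in under a second and the complete pipeline
runs in roughly ten seconds, so tests and the acceptance script use it at
full size.

The hidden latent SES is written only to the `latent_ses_diag` column,
which no analysis stage reads; tests use it to measure parameter recovery
(the PCA wealth score correlates ≈ 0.83–0.95 with it per city under the
defaults).

What the generator does **not** emulate: real multi-stage sample designs
(weights are i.i.d. noise, clusters carry no intra-class correlation),
item missingness patterns, measurement error in asset reporting,
country-specific asset lists, or any relationship between household size
and SES. Passing tests therefore demonstrate correctness of the estimators
and classifiers under the assumed latent structure — not robustness to the
messiness of real DHS/MICS recode files, which enter through the column
mapping and variable dictionary instead.

## Determinism

All randomness flows through `numpy.random.default_rng([seed, city_index,
stream])`, so any city regenerates independently and a scenario is
bit-for-bit reproducible from its manifest. Pipeline outputs are plain
CSV/JSON with sorted keys and stable sorts; running twice from the same
manifest produces byte-identical files (tested).

## Known limitations

- The lognormal income assumption is a modelling convenience; heavy-tailed
  or mixed distributions would change the poverty-line headcount at fixed
  Gini.
- Agreement is raw concordance, not chance-corrected; with very unbalanced
  measures (e.g. slum ≈ 90% poor) high agreement with `w60` is partly
  mechanical.
- The selection rule linearises a judgement call; the decision record, not
  the single selected id, is the primary output.
- Point estimates only: no CIs on prevalences or gaps.
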