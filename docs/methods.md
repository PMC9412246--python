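# Methods

## Scope and data model

The pipeline takes three inputs: a survey table (one row per survey with
site, wave exposure `sheltered|exposed`, and censused area in m²), an
observation table (one row per survey × species × length with a count), and
a species table of energetic traits (length–weight coefficients `a`, `b`;
maximum length `Lmax`; standardized growth coefficient `Kmax`; optional
fixed mortality `m_per_yr`) plus a diel-habit classification
(`diurnal|nocturnal|both`). Facultative and crepuscular species (`both`)
are pooled with the nocturnal group before analysis, because they are able
to exploit night-time resources; the evidence level behind each label
(literature, reference work, genus/family-typical, expert) is carried as
provenance only and never consumed by the pipeline. Species missing from
the trait or diel tables are dropped with a per-species report by default
(strict mode aborts instead), so partially curated trait tables remain
usable.

## Individual energetics

Growth follows a von Bertalanffy curve through the origin with asymptote
`Lmax` and coefficient `Kmax` (year⁻¹): parameterizing by the species
maximum rather than the asymptotic length of a particular population makes
the growth model a species trait, usable without local otolith data.
`t0` is deliberately not a free parameter. The implied age of a fish of
length `L` is `t = −ln(1 − L/Lmax)/Kmax`; advancing `t` by one day and
converting both lengths to mass via `W = a L^b` yields the one-day somatic
gain ΔW ≥ 0. Observed lengths at or above `Lmax` (possible when literature
maxima are exceeded in the field) are clamped to `Lmax·(1 − 10⁻³)` with a
warning; such fish get ΔW ≈ 0 rather than NaN.

Natural mortality uses the length-based estimator
`ln M = 0.55 − 1.61 ln L + 1.44 ln Lmax + ln Kmax` (Gislason-type: smaller
fish of a given species die faster, and fast-growing species die faster at
any size). A finite `m_per_yr` trait overrides the model unchanged. Daily
survival converts the instantaneous annual rate with a 365-day year,
`p = exp(−M/365)`.

## Stochastic productivity simulation

Each individual survives the day with probability `p` and contributes ΔW if
it survives. Identical individuals (same survey, species, length, stratum)
are aggregated and their joint fate drawn from a Binomial(count, p), which
is distributionally identical to independent Bernoulli fates; aggregation
also makes the output bit-for-bit invariant to how counts were split across
input rows. The simulation is repeated `n_iter = 1000` times per survey and
summarized by its mean and SD alongside the closed-form expectation
Σ count·ΔW·p, which the Monte-Carlo mean must match within sampling error
(tested over many seeds). Productivity is the growth of survivors; dead
individuals contribute zero. A `subtract_dead_mass` flag implements the
alternative net-balance reading in which the body mass of fish that die is
subtracted, allowing negative daily production; it is off by default
because the survivors-growth formulation is the operational definition the
simulation expresses.

Fates are drawn once per survey and aggregated to both the diel-group and
the family stratum, so family rows sum to their group row exactly, not just
in expectation. Surveys receive independent child seeds from a root seed in
sorted survey order, making every output reproducible and independent of
input row order.

Units: standing biomass is Σ count·W divided by censused area, reported as
t ha⁻¹ (1 g m⁻² = 0.01 t ha⁻¹); productivity is reported as
g 100 m⁻² day⁻¹. An optional per-observation area override supports census
designs in which different species groups are counted over different
effective areas.

## Hierarchical contrasts

Per-survey diel-group responses (biomass or productivity) are modelled as
Gamma(shape α, mean μ) with `log μ = θ[habit, exposure] + u[site] +
v[survey]`. The cell-means parameterization makes every contrast of
interest a simple difference of θ's. The survey intercept `v` (nested in
site) absorbs the correlation between the diurnal and the nocturnal row of
the same survey; the site intercept `u` absorbs persistent between-site
differences. A lognormal likelihood is available (`likelihood =
"lognormal"`). Gamma support excludes zero, so surveys with an empty diel
group are offset to half the minimum positive response by default (count
and magnitude logged in the run report); `drop` and `error` alternatives
exist.

Priors are weakly informative and logged with every run: Normal(0, 2.5) on
cell effects (log scale), half-Normal(0, 1) on both random-effect scales,
Normal(0, 1.5) on the log gamma shape. Posteriors are drawn with an
adaptive Metropolis-within-Gibbs sampler written for this model: the cell,
site and survey blocks partition the observations, so each block is
updated with vectorized independent random-walk proposals; proposal scales
adapt toward ~35% acceptance during burn-in (Robbins–Monro) and are frozen
afterwards. Two likelihood-invariant "ridge" moves — shifting a cell block
against the site intercepts sharing its rows, and each site intercept
against its surveys' intercepts — are accepted on the prior ratio alone and
remove the slow mixing otherwise caused by the intercept/cell-mean
non-identifiability. Defaults are 4 chains × 5000 iterations with a 50%
burn-in; split-R̂ and effective sample size are computed with ArviZ and any
R̂ > 1.05 is flagged in the run report. Parameter-recovery experiments
(generator truth known) validate interval calibration end to end.

Contrasts are per-draw ratios `exp(θnum − θden)` summarized by mean,
median, the 95% highest-posterior-density interval (narrowest contiguous
window over sorted draws; ties break to the left-most window), and
P(ratio > 1) as the fraction of draws strictly above 1 (an identity
contrast therefore reports 0). Cell summaries back-transform `exp(θ)`,
i.e. the cell mean conditional on average site and survey effects.

## Family composition

Site × family matrices hold the mean over a site's surveys of family-level
nocturnal biomass or productivity, counting surveys where a family is
absent as zero. Standardization is square-root first, then Wisconsin double
standardization (each family column divided by its maximum, then each site
row by its total); all-zero rows and columns pass through as zeros.
Bray–Curtis dissimilarity `d = Σ|x−y| / Σ(x+y)` is computed directly; a
pair of all-zero rows is returned as d = 0 with a warning so degenerate
inputs do not crash the ordination.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of the
configuration distances on the rank order of the observed dissimilarities
with a backtracking gradient step, from 20 starts (first start: classical
metric scaling; rest random), returning the lowest-stress solution
centered and rotated to principal axes. Stress-1 divides by the sum of
squared configuration distances, which avoids the degenerate
cluster-collapse solutions that raw-stress/normalized-SMACOF minimizers
can produce; on test fixtures the achieved stress matches or beats
vegan's `monoMDS`. Ordination is descriptive — no PERMANOVA/ANOSIM is
performed. Family rankings report each family's share of the diel group's
grand total across all surveys.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 75 surveys
(7 sheltered + 8 exposed sites × 5 surveys, 250 m² each), ~45 species in
~16 reef-fish families of realistic sizes and diel mixes, including a
small-bodied, fast-growing (high `Kmax`, high `M`), purely nocturnal
cardinalfish-like family (Apogonidae). Trait draws are lognormal with a
negative `Lmax`–`Kmax` correlation (`Kmax ∝ Lmax^−0.6`).

Effect sizes are encoded where they act:

- nocturnal standing-biomass densities per exposure (defaults 1.10 and
  0.45 t ha⁻¹) and diurnal:nocturnal biomass ratios per exposure (defaults
  2.04 sheltered, 3.71 exposed) fix the four cell means;
- nocturnal family productivity-share weights at sheltered sites (default
  apogonid weight 0.64) and the apogonid sheltered:exposed productivity
  ratio (default 14) shape the family decomposition, yielding an overall
  apogonid share of nocturnal productivity near 54%;
- diurnal families are allocated by biomass weights.

Family budgets convert between biomass and productivity through per-species
expected turnover `E[ΔW·p]/E[W]`, computed by Gauss–Hermite quadrature over
the logit-normal length distribution with the same growth and mortality
models the engine applies. Counts per survey × species are
negative-binomial (dispersion 3) around target biomass / expected
individual mass, scaled by mean-preserving lognormal site (sd 0.35) and
survey (sd 0.20) effects shared by all species in a survey — so every
configured ratio holds in expectation and site effects cancel within
diel contrasts of the same site, mirroring the model's random-effect
structure. Lengths are `Lmax` × logit-normal fraction (guaranteeing
`L < Lmax` without rejection) binned to 0.5 cm. `GroundTruth` records the
expected cell means, ratios and family shares implied by the drawn traits
for every recovery test.

What the generator does not emulate: observer detectability and the
mechanics of multi-transect censuses, immigration/emigration/recruitment,
within-site habitat gradients, species-level diel misclassification, and
diel-group-specific site heterogeneity (site effects multiply both groups
equally, so diel contrasts are less uncertain in synthetic data than in
field data). Passing recovery tests therefore demonstrate the estimator
chain is consistent under the assumed data-generating process, not that
field estimates carry these uncertainties.

Absolute productivity magnitudes emerge from the trait and size-structure
choices rather than being dialled; the ratio contrasts and family shares
are the quantities the defaults encode. With the default traits the
synthetic assemblages turn over ~0.1–0.3% of biomass per day, which sits
within the range trait-based reef-fish growth models produce for small to
mid-sized fishes.

## Numerical choices and problem sizes

- Lengths ≥ `Lmax` clamp to `Lmax(1 − 10⁻³)`; VBGF uses `log1p` for
  accuracy near zero length.
- HPD windows need ≥ 2 finite draws; window width ⌈mass·n⌉ draws.
- NMDS: k = 2, 20 starts, 200 iterations max, stop when stress improves by
  < 10⁻⁷; pairwise distances floored at 10⁻⁶ in gradients.
- MCMC chains get independent `SeedSequence` children of the run seed; all
  outputs are bit-for-bit reproducible given (inputs, seed).
- The test suite exercises reduced problem sizes chosen to keep the full
  suite around a minute while leaving every statistical check
  well-powered: 2–4 sites per exposure, 100–300 mortality iterations, 2
  MCMC chains × 1200–2000 iterations, 20 recovery replicates. The
  acceptance script runs the full default scenario (75 surveys, 1000
  iterations, 4 × 5000 MCMC).

## Known limitations

- The mortality model is a documented stand-in of the Gislason lineage;
  analyses with species-specific mortality estimates should use the
  `m_per_yr` override.
- Cell summaries are conditional means (`exp(θ)`), not marginal means over
  random effects; contrasts are unaffected because random effects cancel
  in ratios.
- The gamma zero-offset is pragmatic; with many empty diel strata a hurdle
  model would be more faithful than any of the offered zero-handling
  options.
- NMDS with very few sites (< 6) can reach zero stress without the
  configuration being informative; stress and the start-stress list are
  reported so users can judge.
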