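# reefprod

Quantitative comparison of **diurnal versus nocturnal coral-reef fish
assemblages**: standing biomass and daily biomass production estimated from
underwater visual-census (UVC) counts, contrasted across diel groups and
wave-exposure regimes with a Bayesian hierarchical model, and decomposed by
family with Bray–Curtis/NMDS ordination.

The package is for reef-fish community ecologists who have per-survey counts
of fishes by species and length and want functional metrics — how much fish
biomass is standing on a reef, how much new biomass it produces per day, and
how those quantities partition between day- and night-active fishes.

## The model

Every counted fish of total length *L* (cm) is pushed through a chain of
trait-based models:

- mass: *W = aL^b* (g), with species-specific length–weight coefficients;
- implied age from the inverse von Bertalanffy growth function (VBGF)
  standardized to the species maximum length:
  *t(L) = −ln(1 − L/L<sub>max</sub>)/K<sub>max</sub>*;
- length after one day: *L′ = L<sub>max</sub>(1 − e^(−K<sub>max</sub>(t + 1/365)))*,
  giving a one-day somatic gain ΔW = aL′^b − aL^b;
- instantaneous natural mortality from a length-based (Gislason-type) model,
  ln *M* = 0.55 − 1.61 ln *L* + 1.44 ln *L*<sub>max</sub> + ln *K*<sub>max</sub>,
  overridable per species;
- one-day survival *p = e^(−M/365)*.

Each individual survives the day as a Bernoulli trial with probability *p*;
survey productivity is the summed ΔW of survivors, averaged over 1000
stochastic iterations (identical individuals are aggregated into binomial
draws, which is exactly equivalent). Biomass is reported in t ha⁻¹ and
productivity in g 100 m⁻² day⁻¹.

Per-survey diel-group totals are then modelled with a gamma GLMM (log link):
cell means for the four habit × exposure cells, site and survey-within-site
random intercepts, sampled by an adaptive Metropolis-within-Gibbs scheme
(4 chains × 5000 iterations, 50% burn-in, split-R̂/ESS diagnostics via ArviZ).
Contrasts are per-draw ratios β = exp(θ₁ − θ₂) summarized by their median,
95% highest-posterior-density (HPD) interval, and P(β > 1). Family-level
nocturnal composition is square-root transformed, Wisconsin
double-standardized, converted to Bray–Curtis dissimilarities, and ordinated
by non-metric multidimensional scaling (Kruskal stress-1, best of 20 starts).

Species classified as facultatively nocturnal ("both", incl. crepuscular) are
pooled with the nocturnal group.

## Worked example

```sh
reefprod all --out run1 --seed 1
```

generates a synthetic 75-survey dataset (15 sites × 5 surveys, sheltered and
exposed, ~45 species in ~16 families with a cardinalfish-like family
dominating sheltered nocturnal productivity), estimates per-survey biomass
and productivity, fits the hierarchical contrasts, and ordinates nocturnal
family composition. `run1/contrasts.csv` then holds, for the biomass
response (seed 1):

```
label  ratio_mean  ratio_median  hpd_low  hpd_high  prob_gt_1
DS/NS       1.997         1.994    1.768     2.235      1.000
DE/NE       4.075         4.067    3.614     4.541      1.000
DS/DE       1.085         1.075    0.785     1.398      0.706
NS/NE       2.213         2.198    1.621     2.855      1.000
```

DS/NS is the diurnal:nocturnal biomass ratio at sheltered sites — here the
posterior median says diurnal fishes carry roughly twice the nocturnal
standing biomass, and the generator's encoded truth (2.04) falls inside the
95% HPD. DE/NE is the same contrast at exposed sites, DS/DE and NS/NE are
the exposure contrasts within each diel group. `family_shares.csv` ranks
nocturnal families by their share of total nocturnal productivity
(Apogonidae ≈ 0.53 in this run), and `ordination.csv` holds the NMDS site
scores and stress. Same library calls:
`reefprod.generate_dataset`, `reefprod.survey_summaries`,
`reefprod.fit_hierarchical_model`, `reefprod.standard_contrasts`,
`reefprod.nmds`, `reefprod.top_families`.

To analyse real data instead, provide four CSVs with the documented schemas
(`traits.csv`, `diel.csv`, `surveys.csv`, `observations.csv`) and run the
`estimate`, `infer` and `compose` subcommands on them.

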