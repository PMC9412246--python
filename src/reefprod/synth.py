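"""Synthetic survey, trait and diel tables with known ground truth.

The generator emulates the shape of the study system: 75 visual
censuses (15 sites x 5 surveys) split between sheltered and exposed
reef, ~45 species in ~16 families, with a small-bodied, fast-growing,
purely nocturnal cardinalfish-like family (Apogonidae) that dominates
nocturnal productivity at sheltered sites.

Effect sizes are encoded as expected standing-biomass densities per
habit x exposure cell: the nocturnal cell densities are set directly
and the diurnal cells via configurable diurnal:nocturnal ratios
(defaults 2.04 sheltered, 3.71 exposed).  Within the nocturnal budget,
families are allocated by target productivity shares at sheltered
sites; at exposed sites the apogonid productivity density is divided by
a configurable sheltered:exposed ratio (default 14).  Diurnal families
are allocated by biomass weights.

Counts per (survey x species) are negative-binomial around the species'
expected count (target biomass / expected individual mass), modulated
by mean-preserving lognormal site and survey effects shared by all
species in the survey, so that every configured cell ratio holds in
expectation.  Lengths are drawn as Lmax times a logit-normal fraction,
guaranteeing L < Lmax without rejection.

``GroundTruth`` records the expected cell means, contrast ratios and
family productivity shares implied by the drawn traits, computed by
Gauss-Hermite quadrature over the length distribution with the same
growth and mortality models the estimation engine applies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .productivity import daily_growth_mass, daily_survival, natural_mortality, weight_from_length
from .traits import pool_diel

T_HA_TO_G_M2 = 100.0  # 1 t/ha = 100 g/m^2


@dataclass
class FamilySpec:
    name: str
    n_species: int
    p_diurnal: float
    p_nocturnal: float
    p_both: float
    lmax_median_cm: float
    kmax_mult: float = 1.0        # growth multiplier relative to the Lmax scaling law
    frac_logit_mean: float = 0.4  # logit of typical length as a fraction of Lmax
    frac_logit_sd: float = 0.5
    lmax_sd_log: float = 0.15


def default_families() -> list[FamilySpec]:
    """A reef-fish family pool with realistic sizes and diel mixes."""
    return [
        # nocturnal / facultative families
        FamilySpec("Apogonidae", 6, 0.0, 1.0, 0.0, 7.0, kmax_mult=3.0,
                   frac_logit_mean=0.0),
        FamilySpec("Holocentridae", 3, 0.0, 0.7, 0.3, 22.0, frac_logit_mean=0.6),
        FamilySpec("Haemulidae", 2, 0.0, 0.4, 0.6, 50.0, frac_logit_mean=1.0),
        FamilySpec("Lutjanidae", 3, 0.0, 0.4, 0.6, 45.0, frac_logit_mean=1.0),
        FamilySpec("Lethrinidae", 2, 0.0, 0.4, 0.6, 45.0, frac_logit_mean=1.0),
        FamilySpec("Priacanthidae", 1, 0.0, 1.0, 0.0, 30.0, frac_logit_mean=0.8),
        FamilySpec("Siganidae", 2, 0.0, 0.0, 1.0, 30.0, frac_logit_mean=0.8),
        FamilySpec("Epinephelidae", 2, 0.0, 0.3, 0.7, 40.0, frac_logit_mean=1.0),
        FamilySpec("Pempheridae", 2, 0.0, 1.0, 0.0, 14.0, kmax_mult=1.5,
                   frac_logit_mean=0.2),
        # mostly diurnal families (some facultative surgeonfishes)
        FamilySpec("Acanthuridae", 4, 0.7, 0.0, 0.3, 30.0, frac_logit_mean=0.8),
        FamilySpec("Pomacentridae", 6, 1.0, 0.0, 0.0, 9.0, kmax_mult=1.5,
                   frac_logit_mean=0.2),
        FamilySpec("Labridae", 5, 1.0, 0.0, 0.0, 20.0, frac_logit_mean=0.5),
        FamilySpec("Scaridae", 3, 1.0, 0.0, 0.0, 35.0, frac_logit_mean=0.8),
        FamilySpec("Chaetodontidae", 2, 1.0, 0.0, 0.0, 15.0, frac_logit_mean=0.5),
        FamilySpec("Caesionidae", 2, 1.0, 0.0, 0.0, 25.0, frac_logit_mean=0.5),
    ]


def default_noct_prod_shares() -> dict[str, float]:
    """Target nocturnal family productivity shares at sheltered sites."""
    return {
        "Apogonidae": 0.64,
        "Holocentridae": 0.04,
        "Haemulidae": 0.08,
        "Lutjanidae": 0.07,
        "Lethrinidae": 0.05,
        "Siganidae": 0.04,
        "Epinephelidae": 0.03,
        "Priacanthidae": 0.01,
        "Pempheridae": 0.01,
        "Acanthuridae": 0.03,
    }


def default_diur_biomass_weights() -> dict[str, float]:
    return {
        "Acanthuridae": 0.25,
        "Pomacentridae": 0.20,
        "Labridae": 0.15,
        "Scaridae": 0.23,
        "Chaetodontidae": 0.07,
        "Caesionidae": 0.10,
    }


@dataclass
class SynthConfig:
    n_sites_sheltered: int = 7
    n_sites_exposed: int = 8
    surveys_per_site: int = 5
    area_m2: float = 250.0
    biomass_noct_sheltered_t_ha: float = 1.10
    biomass_noct_exposed_t_ha: float = 0.45
    ratio_ds_ns: float = 2.04     # diurnal:nocturnal biomass, sheltered
    ratio_de_ne: float = 3.71     # diurnal:nocturnal biomass, exposed
    apogonid_se_prod_ratio: float = 14.0
    apogonid_family: str = "Apogonidae"
    site_sd_log: float = 0.35
    survey_sd_log: float = 0.20
    nb_dispersion: float = 3.0    # negative-binomial size parameter
    families: list[FamilySpec] = field(default_factory=default_families)
    noct_prod_shares: dict[str, float] = field(default_factory=default_noct_prod_shares)
    diur_biomass_weights: dict[str, float] = field(default_factory=default_diur_biomass_weights)
    lw_a_median: float = 0.015
    lw_a_sd_log: float = 0.3
    lw_b_mean: float = 3.0
    lw_b_sd: float = 0.08
    kmax_sd_log: float = 0.15

    def __post_init__(self) -> None:
        if min(self.n_sites_sheltered, self.n_sites_exposed, self.surveys_per_site) < 1:
            raise ValueError("site and survey counts must be >= 1")
        if min(self.ratio_ds_ns, self.ratio_de_ne, self.apogonid_se_prod_ratio) <= 0:
            raise ValueError("effect-size ratios must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class GroundTruth:
    """Expected values implied by the drawn traits and configuration."""

    cell_biomass_t_ha: dict[str, float]
    cell_prod_g_100m2_d: dict[str, float]
    biomass_ratios: dict[str, float]
    prod_ratios: dict[str, float]
    noct_family_prod_shares: dict[str, dict[str, float]]
    apogonid_overall_prod_share: float
    apogonid_se_prod_ratio: float
    species_biomass_t_ha: dict[str, dict[str, float]]
    site_effects: dict[str, float]
    survey_effects: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def generate_traits(config: SynthConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw species trait and diel-classification tables (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    trait_rows, diel_rows = [], []
    evidence_levels = ["literature", "reference-work", "genus/family-typical", "expert"]
    for fam in config.families:
        for i in range(fam.n_species):
            sid = f"{fam.name}_sp{i + 1:02d}"
            lmax = fam.lmax_median_cm * np.exp(rng.normal(0.0, fam.lmax_sd_log))
            # growth declines with maximum size (negative Lmax-Kmax correlation)
            kmax = (
                0.8 * fam.kmax_mult * (lmax / 10.0) ** -0.6
                * np.exp(rng.normal(0.0, config.kmax_sd_log))
            )
            lw_a = config.lw_a_median * np.exp(rng.normal(0.0, config.lw_a_sd_log))
            lw_b = float(np.clip(rng.normal(config.lw_b_mean, config.lw_b_sd), 2.5, 3.5))
            trait_rows.append(
                {"species_id": sid, "family": fam.name, "lw_a": lw_a, "lw_b": lw_b,
                 "l_max_cm": lmax, "k_max_per_yr": kmax}
            )
            diel = rng.choice(
                ["diurnal", "nocturnal", "both"],
                p=[fam.p_diurnal, fam.p_nocturnal, fam.p_both],
            )
            diel_rows.append(
                {"species_id": sid, "diel_raw": diel,
                 "evidence": evidence_levels[int(rng.integers(0, 4))]}
            )
    return pd.DataFrame(trait_rows), pd.DataFrame(diel_rows)


def _frac_nodes(fam: FamilySpec, n_nodes: int = 40) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z = fam.frac_logit_mean + np.sqrt(2.0) * fam.frac_logit_sd * x
    frac = 1.0 / (1.0 + np.exp(-z))
    return frac, w / np.sqrt(np.pi)


def species_energetics(traits: pd.DataFrame, families: list[FamilySpec]) -> pd.DataFrame:
    """Per-species expected individual mass and daily production.

    Expectations over the logit-normal length distribution via
    Gauss-Hermite quadrature, using the same growth/mortality models as
    the estimation engine.  ``q_per_day`` is production per unit biomass.
    """
    fam_map = {f.name: f for f in families}
    rows = []
    for t in traits.itertuples():
        fam = fam_map[t.family]
        frac, w = _frac_nodes(fam)
        L = np.maximum(t.l_max_cm * frac, 1e-6)
        W = weight_from_length(L, t.lw_a, t.lw_b)
        dW = daily_growth_mass(L, t.lw_a, t.lw_b, t.l_max_cm, t.k_max_per_yr)
        p = daily_survival(natural_mortality(L, t.l_max_cm, t.k_max_per_yr))
        ew = float(np.sum(w * W))
        ep = float(np.sum(w * dW * p))
        rows.append({"species_id": t.species_id, "family": t.family,
                     "e_weight_g": ew, "e_prod_g_d": ep, "q_per_day": ep / ew})
    return pd.DataFrame(rows)


def _allocate_budgets(config: SynthConfig, traits: pd.DataFrame,
                      diel_group: pd.Series, energ: pd.DataFrame) -> pd.DataFrame:
    """Expected per-species biomass density (t/ha) per exposure."""
    df = energ.merge(
        pd.DataFrame({"species_id": traits["species_id"], "diel_group": diel_group}),
        on="species_id",
    )
    b_n = {"sheltered": config.biomass_noct_sheltered_t_ha,
           "exposed": config.biomass_noct_exposed_t_ha}
    b_d = {"sheltered": b_n["sheltered"] * config.ratio_ds_ns,
           "exposed": b_n["exposed"] * config.ratio_de_ne}

    noct = df[df["diel_group"] == "nocturnal"]
    fam_q = noct.groupby("family")["q_per_day"].mean()
    shares = {f: s for f, s in config.noct_prod_shares.items() if f in fam_q.index}
    tot = sum(shares.values())
    shares = {f: s / tot for f, s in shares.items()}
    denom = sum(s / fam_q[f] for f, s in shares.items())
    fam_b_shelt = {f: b_n["sheltered"] * (s / fam_q[f]) / denom for f, s in shares.items()}
    fam_p_shelt = {f: fam_b_shelt[f] * fam_q[f] for f in shares}

    apo = config.apogonid_family
    fam_b_exp: dict[str, float] = {}
    if apo in fam_b_shelt:
        p_apo_exposed = fam_p_shelt[apo] / config.apogonid_se_prod_ratio
        fam_b_exp[apo] = p_apo_exposed / fam_q[apo]
    others = {f: b for f, b in fam_b_shelt.items() if f != apo}
    if others:
        rest_budget = b_n["exposed"] - fam_b_exp.get(apo, 0.0)
        if rest_budget <= 0:
            raise ValueError(
                "apogonid exposed biomass exceeds the exposed nocturnal budget"
            )
        other_tot = sum(others.values())
        for f, b in others.items():
            fam_b_exp[f] = rest_budget * b / other_tot
    # with no other nocturnal families the apogonid S:E ratio takes
    # precedence over the configured exposed nocturnal total

    diur = df[df["diel_group"] == "diurnal"]
    dweights = {f: w for f, w in config.diur_biomass_weights.items()
                if f in set(diur["family"])}
    dtot = sum(dweights.values())
    dweights = {f: w / dtot for f, w in dweights.items()}

    out = []
    for exposure in ("sheltered", "exposed"):
        fam_b_noct = fam_b_shelt if exposure == "sheltered" else fam_b_exp
        for t in df.itertuples():
            if t.diel_group == "nocturnal":
                fam_total = fam_b_noct.get(t.family, 0.0)
                n_in = int((noct["family"] == t.family).sum())
            else:
                fam_total = b_d[exposure] * dweights.get(t.family, 0.0)
                n_in = int((diur["family"] == t.family).sum())
            out.append({"species_id": t.species_id, "family": t.family,
                        "diel_group": t.diel_group, "exposure": exposure,
                        "biomass_t_ha": fam_total / n_in if n_in else 0.0})
    return pd.DataFrame(out)


def generate_surveys(
    config: SynthConfig, traits: pd.DataFrame, diel: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw survey and observation tables plus their ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    fam_map = {f.name: f for f in config.families}
    groups = pool_diel(diel).set_index("species_id")["diel_group"]
    energ = species_energetics(traits, config.families)
    alloc = _allocate_budgets(config, traits, groups.reindex(traits["species_id"]).reset_index(drop=True), energ)
    alloc = alloc.merge(energ[["species_id", "e_weight_g", "q_per_day"]], on="species_id")

    site_rows, survey_rows = [], []
    site_effects: dict[str, float] = {}
    survey_effects: dict[str, float] = {}
    n_sites = config.n_sites_sheltered + config.n_sites_exposed
    exposures = ["sheltered"] * config.n_sites_sheltered + ["exposed"] * config.n_sites_exposed
    for i in range(n_sites):
        site_id = f"site{i + 1:02d}"
        g = float(np.exp(rng.normal(-config.site_sd_log**2 / 2, config.site_sd_log)))
        site_effects[site_id] = g
        for j in range(config.surveys_per_site):
            sid = f"{site_id}_s{j + 1}"
            h = float(np.exp(rng.normal(-config.survey_sd_log**2 / 2, config.survey_sd_log)))
            survey_effects[sid] = h
            site_rows.append((site_id, exposures[i]))
            survey_rows.append({"survey_id": sid, "site_id": site_id,
                                "exposure": exposures[i], "area_m2": config.area_m2})
    surveys = pd.DataFrame(survey_rows)

    traits_idx = traits.set_index("species_id")
    obs_rows = []
    k = config.nb_dispersion
    for srow in surveys.itertuples():
        mult = site_effects[srow.site_id] * survey_effects[srow.survey_id]
        sub = alloc[alloc["exposure"] == srow.exposure]
        for sp in sub.itertuples():
            if sp.biomass_t_ha <= 0:
                continue
            target_g = sp.biomass_t_ha * T_HA_TO_G_M2 * srow.area_m2 * mult
            lam = target_g / sp.e_weight_g
            count = int(rng.negative_binomial(k, k / (k + lam))) if lam > 0 else 0
            if count == 0:
                continue
            fam = fam_map[traits_idx.loc[sp.species_id, "family"]]
            z = rng.normal(fam.frac_logit_mean, fam.frac_logit_sd, size=count)
            frac = 1.0 / (1.0 + np.exp(-z))
            lengths = traits_idx.loc[sp.species_id, "l_max_cm"] * frac
            lengths = np.maximum(np.round(lengths * 2.0) / 2.0, 0.5)  # 0.5 cm bins
            binned = pd.Series(lengths).value_counts().sort_index()
            for length, cnt in binned.items():
                obs_rows.append({"survey_id": srow.survey_id, "species_id": sp.species_id,
                                 "length_cm": float(length), "count": int(cnt)})
    obs = pd.DataFrame(obs_rows, columns=["survey_id", "species_id", "length_cm", "count"])

    truth = _ground_truth(config, alloc, site_effects, survey_effects)
    return surveys, obs, truth


def _ground_truth(config: SynthConfig, alloc: pd.DataFrame,
                  site_effects: dict, survey_effects: dict) -> GroundTruth:
    cell_b, cell_p = {}, {}
    fam_shares: dict[str, dict[str, float]] = {}
    for exposure in ("sheltered", "exposed"):
        tag = "S" if exposure == "sheltered" else "E"
        sub = alloc[alloc["exposure"] == exposure]
        for dg, letter in (("diurnal", "D"), ("nocturnal", "N")):
            rows = sub[sub["diel_group"] == dg]
            b = float(rows["biomass_t_ha"].sum())
            # t/ha * (per-day turnover) -> g/100 m^2/day: 1 t/ha = 1e4 g/100 m^2
            p = float((rows["biomass_t_ha"] * rows["q_per_day"]).sum()) * 1e4
            cell_b[f"{letter}{tag}"] = b
            cell_p[f"{letter}{tag}"] = p
        noct = sub[sub["diel_group"] == "nocturnal"]
        fam_p = noct.groupby("family").apply(
            lambda d: float((d["biomass_t_ha"] * d["q_per_day"]).sum()) * 1e4,
            include_groups=False,
        )
        fam_shares[exposure] = (fam_p / fam_p.sum()).to_dict()

    n_s = config.n_sites_sheltered * config.surveys_per_site
    n_e = config.n_sites_exposed * config.surveys_per_site
    apo = config.apogonid_family
    apo_total = (n_s * fam_shares["sheltered"].get(apo, 0.0) * cell_p["NS"]
                 + n_e * fam_shares["exposed"].get(apo, 0.0) * cell_p["NE"])
    noct_total = n_s * cell_p["NS"] + n_e * cell_p["NE"]

    species_b = {
        exposure: dict(zip(sub["species_id"], sub["biomass_t_ha"]))
        for exposure, sub in alloc.groupby("exposure")
    }
    return GroundTruth(
        cell_biomass_t_ha=cell_b,
        cell_prod_g_100m2_d=cell_p,
        biomass_ratios={"DS/NS": cell_b["DS"] / cell_b["NS"],
                        "DE/NE": cell_b["DE"] / cell_b["NE"],
                        "DS/DE": cell_b["DS"] / cell_b["DE"],
                        "NS/NE": cell_b["NS"] / cell_b["NE"]},
        prod_ratios={"DS/NS": cell_p["DS"] / cell_p["NS"],
                     "DE/NE": cell_p["DE"] / cell_p["NE"],
                     "DS/DE": cell_p["DS"] / cell_p["DE"],
                     "NS/NE": cell_p["NS"] / cell_p["NE"]},
        noct_family_prod_shares=fam_shares,
        apogonid_overall_prod_share=apo_total / noct_total,
        apogonid_se_prod_ratio=config.apogonid_se_prod_ratio,
        species_biomass_t_ha=species_b,
        site_effects=site_effects,
        survey_effects=survey_effects,
    )


def generate_dataset(config: SynthConfig, seed: int):
    """Convenience wrapper: traits, diel, surveys, observations, truth."""
    traits, diel = generate_traits(config, seed)
    surveys, obs, truth = generate_surveys(config, traits, diel, seed)
    return traits, diel, surveys, obs, truth
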