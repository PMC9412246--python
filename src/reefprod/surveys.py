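"""Data model and I/O for underwater visual-census surveys.

A survey is one diver census of a known area (m^2) at a site that is
either sheltered from or exposed to prevailing wind and wave action.
Observations record, per survey and species, the number of individuals
seen at a given total length (cm).  An optional per-observation
``area_m2`` override supports census designs where different species
groups are counted over different effective areas; it defaults to the
survey-level area.
"""

from __future__ import annotations

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError
from .traits import _coerce_numeric, _require_columns

SURVEY_COLUMNS = ["survey_id", "site_id", "exposure", "area_m2"]
OBS_COLUMNS = ["survey_id", "species_id", "length_cm", "count"]
EXPOSURES = frozenset({"sheltered", "exposed"})


def validate_surveys(surveys: pd.DataFrame) -> pd.DataFrame:
    _require_columns(surveys, SURVEY_COLUMNS, "surveys")
    surveys = _coerce_numeric(surveys, ["area_m2"], "surveys")
    dup = surveys["survey_id"][surveys["survey_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            "duplicate survey_id: " + ", ".join(sorted(set(dup.astype(str))))
        )
    bad_exp = ~surveys["exposure"].isin(EXPOSURES)
    if bad_exp.any():
        vals = sorted(set(surveys.loc[bad_exp, "exposure"].astype(str)))
        raise ValidationError(f"exposure must be sheltered|exposed, got: {vals}")
    if not (surveys["area_m2"] > 0).all():
        idx = int((~(surveys["area_m2"] > 0)).idxmax())
        raise ValidationError(f"area_m2 must be > 0 (row {idx})")
    return surveys.reset_index(drop=True)


def validate_observations(
    obs: pd.DataFrame, surveys: pd.DataFrame
) -> pd.DataFrame:
    _require_columns(obs, OBS_COLUMNS, "observations")
    obs = _coerce_numeric(obs, ["length_cm", "count"], "observations")
    if "area_m2" in obs.columns:
        obs = _coerce_numeric(obs, ["area_m2"], "observations")
    if not (obs["length_cm"] > 0).all():
        idx = int((~(obs["length_cm"] > 0)).idxmax())
        raise ValidationError(f"length_cm must be > 0 (row {idx})")
    counts = obs["count"]
    if not ((counts >= 1) & (counts == counts.round())).all():
        idx = int((~((counts >= 1) & (counts == counts.round()))).idxmax())
        raise ValidationError(f"count must be an integer >= 1 (row {idx})")
    obs = obs.copy()
    obs["count"] = obs["count"].astype(int)
    known = set(surveys["survey_id"])
    orphan = ~obs["survey_id"].isin(known)
    if orphan.any():
        idx = int(orphan.idxmax())
        raise IntegrityError(
            f"observation row {idx} references unknown survey_id "
            f"{obs.loc[idx, 'survey_id']!r}"
        )
    return obs.reset_index(drop=True)


def read_surveys(surveys_path, obs_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the survey and observation CSV pair."""
    surveys = validate_surveys(pd.read_csv(surveys_path))
    obs = validate_observations(pd.read_csv(obs_path), surveys)
    return surveys, obs


def write_surveys(surveys: pd.DataFrame, obs: pd.DataFrame, surveys_path, obs_path) -> None:
    surveys.to_csv(surveys_path, index=False)
    obs.to_csv(obs_path, index=False)


def expand_to_individuals(obs: pd.DataFrame) -> pd.DataFrame:
    """Expand count-aggregated rows to one row per individual fish.

    Equivalent information to the aggregated form; the stochastic
    mortality simulation operates on the aggregated rows via binomial
    draws, which is distributionally identical to per-individual
    Bernoulli fates.
    """
    expanded = obs.loc[obs.index.repeat(obs["count"])].copy()
    expanded["count"] = 1
    return expanded.reset_index(drop=True)
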