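"""Species trait and diel-habit tables.

Each species carries the energetic parameters the productivity engine
needs: length-weight coefficients ``a`` and ``b`` (so mass in grams is
``a * L**b`` for total length ``L`` in cm), the species maximum length
``Lmax`` (cm), and the growth coefficient ``Kmax`` (year^-1) of a
von Bertalanffy curve standardized to ``Lmax``.  An optional
``m_per_yr`` column supplies a fixed instantaneous natural mortality
that overrides the default length-based mortality model.

Diel habit is recorded per species as one of ``diurnal``, ``nocturnal``
or ``both`` (facultative/crepuscular).  For analysis the three levels
are pooled into two: facultative species are treated as part of the
nocturnal assemblage, since they can be active at night.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassificationError, SchemaError, StrictJoinError, ValidationError

TRAIT_COLUMNS = ["species_id", "family", "lw_a", "lw_b", "l_max_cm", "k_max_per_yr"]
TRAIT_NUMERIC = ["lw_a", "lw_b", "l_max_cm", "k_max_per_yr"]
DIEL_COLUMNS = ["species_id", "diel_raw", "evidence"]
DIEL_LEVELS = frozenset({"diurnal", "nocturnal", "both"})


@dataclass
class LoadReport:
    """Per-row rejection report produced while validating a trait table."""

    n_read: int = 0
    n_valid: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)
    # (row index in file order, species_id, reason)

    def summary(self) -> str:
        lines = [f"read {self.n_read} rows, kept {self.n_valid}"]
        for idx, sp, reason in self.rejected:
            lines.append(f"  row {idx} ({sp}): {reason}")
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, cols: list[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{what} column '{col}' is non-numeric at row {idx} "
                f"(value {df[col].iloc[idx]!r})"
            )
        df[col] = coerced
    return df


def validate_traits(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Validate a raw trait table, rejecting rows that break invariants.

    Returns the valid rows plus a :class:`LoadReport` listing each
    rejected row with the invariant it violated.  Duplicate species ids
    are an error (the table is a keyed lookup), as is a missing column.
    """
    _require_columns(df, TRAIT_COLUMNS, "traits")
    df = _coerce_numeric(df, TRAIT_NUMERIC, "traits")
    if "m_per_yr" in df.columns:
        df = _coerce_numeric(df, ["m_per_yr"], "traits")

    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            "duplicate species_id in traits table: " + ", ".join(sorted(set(dup)))
        )

    report = LoadReport(n_read=len(df))
    reasons = pd.Series("", index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        reasons = reasons.where(~(mask & (reasons == "")), reason)

    flag(~(df["lw_a"] > 0), "lw_a must be > 0")
    flag(~((df["lw_b"] > 1) & (df["lw_b"] < 5)), "lw_b must lie in (1, 5)")
    flag(~(df["l_max_cm"] > 0), "l_max_cm must be > 0")
    flag(~(df["k_max_per_yr"] > 0), "k_max_per_yr must be > 0")
    if "m_per_yr" in df.columns:
        flag(df["m_per_yr"].notna() & ~(df["m_per_yr"] > 0), "m_per_yr must be > 0")

    bad = reasons != ""
    for pos, (idx, reason) in enumerate(reasons.items()):
        if reason:
            report.rejected.append((pos, str(df.loc[idx, "species_id"]), reason))
    valid = df.loc[~bad].reset_index(drop=True)
    report.n_valid = len(valid)
    return valid, report


def load_traits(path) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate a traits CSV (UTF-8, '.' decimal, header required)."""
    raw = pd.read_csv(path)
    return validate_traits(raw)


def load_diel(path) -> pd.DataFrame:
    """Read and validate a diel-classification CSV."""
    df = pd.read_csv(path)
    _require_columns(df, DIEL_COLUMNS, "diel")
    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            "duplicate species_id in diel table: " + ", ".join(sorted(set(dup)))
        )
    bad = ~df["diel_raw"].isin(DIEL_LEVELS)
    if bad.any():
        rows = df.loc[bad, ["species_id", "diel_raw"]]
        detail = "; ".join(f"{r.species_id}={r.diel_raw!r}" for r in rows.itertuples())
        raise ClassificationError(f"unknown diel_raw level(s): {detail}")
    return df.reset_index(drop=True)


def pool_diel(diel: pd.DataFrame) -> pd.DataFrame:
    """Collapse the three-level diel habit into the two analysis groups.

    ``diurnal`` stays diurnal; ``nocturnal`` stays nocturnal; ``both``
    (facultative nocturnal, incl. crepuscular) is pooled with the
    nocturnal group because such species can exploit night-time
    resources.  The output covers exactly the input species.
    """
    _require_columns(diel, ["species_id", "diel_raw"], "diel")
    bad = ~diel["diel_raw"].isin(DIEL_LEVELS)
    if bad.any():
        rows = diel.loc[bad, ["species_id", "diel_raw"]]
        detail = "; ".join(f"{r.species_id}={r.diel_raw!r}" for r in rows.itertuples())
        raise ClassificationError(f"unknown diel_raw level(s): {detail}")
    group = diel["diel_raw"].map(
        {"diurnal": "diurnal", "nocturnal": "nocturnal", "both": "nocturnal"}
    )
    return pd.DataFrame({"species_id": diel["species_id"], "diel_group": group})


def join_observations(
    obs: pd.DataFrame,
    traits: pd.DataFrame,
    diel_groups: pd.DataFrame,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach traits and diel group to every observation row.

    Species missing from either lookup are dropped with a report by
    default; with ``strict=True`` any unmatched species aborts the run
    listing every missing id.

    Returns ``(enriched, dropped)`` where ``dropped`` has one row per
    dropped observation with a ``missing_from`` column.
    """
    trait_ids = set(traits["species_id"])
    diel_ids = set(diel_groups["species_id"])
    missing_traits = ~obs["species_id"].isin(trait_ids)
    missing_diel = ~obs["species_id"].isin(diel_ids)
    unmatched = missing_traits | missing_diel

    if strict and unmatched.any():
        ids = sorted(set(obs.loc[unmatched, "species_id"]))
        raise StrictJoinError(
            "species missing from traits or diel tables: " + ", ".join(ids)
        )

    dropped = obs.loc[unmatched].copy()
    dropped["missing_from"] = np.select(
        [missing_traits[unmatched] & missing_diel[unmatched], missing_traits[unmatched]],
        ["traits+diel", "traits"],
        default="diel",
    )

    enriched = (
        obs.loc[~unmatched]
        .merge(traits, on="species_id", how="left")
        .merge(diel_groups, on="species_id", how="left")
        .reset_index(drop=True)
    )
    return enriched, dropped.reset_index(drop=True)
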