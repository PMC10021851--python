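"""CSV readers/writers for the pipeline's table schemas.

The same readers ingest synthetic fixtures and real extracts shaped to the
documented schemas:

districts.csv
    district_id, state_id, live_births, maternal_deaths, infant_deaths,
    female_pop_15_49, plus one column per covariate.
states.csv
    state_id, ref_mmr (may be empty), ref_imr (may be empty).
adjacency.csv
    district_id, neighbor_id — symmetric edge list.
truth.csv
    district_id, true_mmr[, true_imr] (synthetic systems only).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mmrcal.exceptions import ValidationError

DISTRICT_COUNT_COLUMNS = (
    "live_births",
    "maternal_deaths",
    "infant_deaths",
    "female_pop_15_49",
)
DISTRICT_REQUIRED = ("district_id", "state_id") + DISTRICT_COUNT_COLUMNS


def _require(df: pd.DataFrame, columns: tuple[str, ...], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing required columns {missing}")


def read_districts(path: str | Path) -> pd.DataFrame:
    """Read and validate a district table; extra columns are covariates."""
    df = pd.read_csv(path, dtype={"district_id": str, "state_id": str})
    _require(df, DISTRICT_REQUIRED, "districts")
    if df["district_id"].duplicated().any():
        dupes = df.loc[df["district_id"].duplicated(), "district_id"].tolist()
        raise ValidationError(f"districts: duplicated district_id {dupes}")
    for col in DISTRICT_COUNT_COLUMNS:
        if (df[col] < 0).any():
            raise ValidationError(f"districts: negative values in {col}")
    if (df["maternal_deaths"] > df["live_births"]).any():
        bad = df.loc[df["maternal_deaths"] > df["live_births"], "district_id"].tolist()
        raise ValidationError(f"districts: maternal_deaths > live_births for {bad}")
    if (df["infant_deaths"] > df["live_births"]).any():
        bad = df.loc[df["infant_deaths"] > df["live_births"], "district_id"].tolist()
        raise ValidationError(f"districts: infant_deaths > live_births for {bad}")
    return df


def read_states(path: str | Path) -> pd.DataFrame:
    """Read the state reference table (gold-standard MMR/IMR, possibly missing)."""
    df = pd.read_csv(path, dtype={"state_id": str})
    _require(df, ("state_id", "ref_mmr", "ref_imr"), "states")
    if df["state_id"].duplicated().any():
        raise ValidationError("states: duplicated state_id")
    both_missing = df["ref_mmr"].isna() & df["ref_imr"].isna()
    if both_missing.any():
        bad = df.loc[both_missing, "state_id"].tolist()
        raise ValidationError(f"states: both ref_mmr and ref_imr missing for {bad}")
    return df


def read_adjacency(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ("district_id", "neighbor_id"), "adjacency")
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"district_id": str})
    _require(df, ("district_id", "true_mmr"), "truth")
    return df


def covariate_columns(districts: pd.DataFrame) -> list[str]:
    """Columns of a district table that are covariates (everything non-core)."""
    return [c for c in districts.columns if c not in DISTRICT_REQUIRED]
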