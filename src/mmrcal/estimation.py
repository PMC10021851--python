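"""Raw MMR, state calibration factors, district adjustment, state aggregation.

The estimation chain:

1. raw district MMR = maternal deaths / live births x 100,000;
2. per-state calibration factor ``cf`` = reference (gold-standard) state MMR
   over the pooled facility-system state MMR — or, where the reference MMR is
   missing, the same ratio of infant mortality rates as a proxy;
3. adjusted district MMR = raw district MMR x cf of its state;
4. adjusted state MMR = sum of adjusted district MMRs weighted by the
   district share of the state's female population aged 15-49;
5. SDG-3.1 classification into [0,70), [70,140), [140,210), [210, inf).

Districts with zero live births have undefined MMR: they are flagged,
excluded from classification and aggregation, and listed in the drop report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmrcal.exceptions import (
    DegenerateCalibrationError,
    UndefinedRateError,
    ValidationError,
)

MMR_SCALE = 100_000.0
IMR_SCALE = 1_000.0

SDG_BIN_EDGES = (70.0, 140.0, 210.0)
SDG_LABELS = ("below_70", "70_139", "140_209", "ge_210")

__all__ = [
    "MMR_SCALE",
    "IMR_SCALE",
    "SDG_BIN_EDGES",
    "SDG_LABELS",
    "CalibrationFactor",
    "compute_mmr",
    "compute_imr",
    "state_hmis_rate",
    "calibration_factor",
    "calibration_table",
    "adjust_districts",
    "population_weights",
    "aggregate_states",
    "classify_sdg",
    "classify_sdg_series",
    "completeness",
    "estimate",
]


@dataclass(frozen=True)
class CalibrationFactor:
    """Per-state multiplier applied to raw district MMRs, with provenance."""

    state_id: str
    cf: float
    source: str  # "mmr_based" | "imr_proxy"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cf) or self.cf <= 0:
            raise ValidationError(f"cf: must be a positive finite real, got {self.cf}")
        if self.source not in ("mmr_based", "imr_proxy"):
            raise ValidationError(f"source: unknown calibration source {self.source!r}")


def _rate(deaths: float, births: float, scale: float, what: str) -> float:
    if births < 0 or deaths < 0:
        raise ValidationError(f"{what}: counts must be non-negative")
    if deaths > births:
        raise ValidationError(f"{what}: deaths ({deaths}) exceed live births ({births})")
    if births == 0:
        raise UndefinedRateError(f"{what}: undefined for zero live births")
    return deaths / births * scale


def compute_mmr(maternal_deaths: float, live_births: float) -> float:
    """Maternal deaths per 100,000 live births."""
    return _rate(maternal_deaths, live_births, MMR_SCALE, "mmr")


def compute_imr(infant_deaths: float, live_births: float) -> float:
    """Infant deaths per 1,000 live births."""
    return _rate(infant_deaths, live_births, IMR_SCALE, "imr")


def state_hmis_rate(districts: pd.DataFrame, which: str = "mmr") -> pd.Series:
    """Pooled facility-system state rate from summed counts.

    The state rate is total deaths over total births (never the unweighted
    mean of district rates, which would mis-weight small districts).
    """
    if which == "mmr":
        numerator, scale = "maternal_deaths", MMR_SCALE
    elif which == "imr":
        numerator, scale = "infant_deaths", IMR_SCALE
    else:
        raise ValidationError(f"which: expected 'mmr' or 'imr', got {which!r}")
    grouped = districts.groupby("state_id")[[numerator, "live_births"]].sum()
    zero = grouped["live_births"] == 0
    if zero.any():
        raise UndefinedRateError(
            f"state {which} undefined for states with zero births: "
            f"{grouped.index[zero].tolist()}"
        )
    rate = grouped[numerator] / grouped["live_births"] * scale
    rate.name = f"hmis_{which}"
    return rate


def calibration_factor(
    state_id: str,
    ref_mmr: float | None,
    ref_imr: float | None,
    hmis_mmr_state: float,
    hmis_imr_state: float,
    allow_imr_fallback_on_degenerate: bool = False,
) -> CalibrationFactor:
    """Calibration factor for one state.

    The reference MMR path always wins when the reference MMR is present;
    the IMR-proxy path is used only when it is missing. A zero facility-system
    rate on the chosen path makes the ratio infinite and raises
    :class:`DegenerateCalibrationError`, unless
    ``allow_imr_fallback_on_degenerate`` permits switching a degenerate MMR
    path to the IMR proxy.
    """
    ref_mmr_present = ref_mmr is not None and np.isfinite(ref_mmr)
    ref_imr_present = ref_imr is not None and np.isfinite(ref_imr)
    if not ref_mmr_present and not ref_imr_present:
        raise ValidationError(
            f"state {state_id}: both reference MMR and reference IMR are missing"
        )
    if ref_mmr_present:
        if hmis_mmr_state > 0:
            return CalibrationFactor(state_id, ref_mmr / hmis_mmr_state, "mmr_based")
        if allow_imr_fallback_on_degenerate and ref_imr_present and hmis_imr_state > 0:
            return CalibrationFactor(state_id, ref_imr / hmis_imr_state, "imr_proxy")
        raise DegenerateCalibrationError(
            f"state {state_id}: facility-system MMR is 0 with positive reference MMR"
        )
    if hmis_imr_state <= 0:
        raise DegenerateCalibrationError(
            f"state {state_id}: facility-system IMR is 0 on the IMR-proxy path"
        )
    return CalibrationFactor(state_id, ref_imr / hmis_imr_state, "imr_proxy")


def calibration_table(
    districts: pd.DataFrame,
    states: pd.DataFrame,
    allow_imr_fallback_on_degenerate: bool = False,
) -> pd.DataFrame:
    """Calibration factors for every state, indexed by state_id."""
    hmis_mmr = state_hmis_rate(districts, "mmr")
    hmis_imr = state_hmis_rate(districts, "imr")
    missing = set(districts["state_id"]) - set(states["state_id"])
    if missing:
        raise ValidationError(f"states: no reference row for states {sorted(missing)}")
    rows = []
    for rec in states.itertuples(index=False):
        if rec.state_id not in hmis_mmr.index:
            continue  # reference rows for states without districts are ignored
        cf = calibration_factor(
            rec.state_id,
            rec.ref_mmr,
            rec.ref_imr,
            hmis_mmr.loc[rec.state_id],
            hmis_imr.loc[rec.state_id],
            allow_imr_fallback_on_degenerate,
        )
        rows.append(
            {
                "state_id": cf.state_id,
                "cf": cf.cf,
                "cf_source": cf.source,
                "hmis_mmr": hmis_mmr.loc[rec.state_id],
                "hmis_imr": hmis_imr.loc[rec.state_id],
            }
        )
    return pd.DataFrame(rows).set_index("state_id")


def adjust_districts(districts: pd.DataFrame, cf_table: pd.DataFrame) -> pd.DataFrame:
    """Raw and calibrated district MMR; zero-birth districts get NaN MMR."""
    missing = set(districts["state_id"]) - set(cf_table.index)
    if missing:
        raise ValidationError(f"cf_table: no calibration factor for states {sorted(missing)}")
    births = districts["live_births"].to_numpy(dtype=float)
    deaths = districts["maternal_deaths"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(births > 0, deaths / np.maximum(births, 1.0) * MMR_SCALE, np.nan)
    cf = cf_table["cf"].reindex(districts["state_id"]).to_numpy()
    out = districts[["district_id", "state_id"]].copy()
    out["mmr_unadjusted"] = raw
    out["mmr_adjusted"] = raw * cf
    return out


def population_weights(districts: pd.DataFrame) -> pd.Series:
    """District share of its state's female population aged 15-49."""
    pop = districts.set_index("district_id")["female_pop_15_49"].astype(float)
    state = districts.set_index("district_id")["state_id"]
    totals = pop.groupby(state).transform("sum")
    if (totals <= 0).any():
        bad = sorted(state[totals <= 0].unique())
        raise ValidationError(f"female_pop_15_49: zero state total for states {bad}")
    pw = pop / totals
    pw.name = "pw"
    return pw


def aggregate_states(adjusted: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Population-weighted state MMR from adjusted district MMRs.

    Districts with undefined (NaN) MMR are excluded and the remaining weights
    renormalised within the state, so each state estimate stays a convex
    combination of its defined district estimates.
    """
    if not set(adjusted["district_id"]) <= set(weights.index):
        raise ValidationError("weights: missing population weight for some districts")
    w = weights.reindex(adjusted["district_id"]).to_numpy()
    m = adjusted["mmr_adjusted"].to_numpy()
    df = pd.DataFrame(
        {"state_id": adjusted["state_id"].to_numpy(), "w": w, "wm": w * m}
    )
    defined = ~np.isnan(m)
    df = df[defined]
    grouped = df.groupby("state_id").sum()
    if (grouped["w"] <= 0).any():
        bad = grouped.index[grouped["w"] <= 0].tolist()
        raise ValidationError(f"aggregate: no defined-MMR weight in states {bad}")
    state_mmr = grouped["wm"] / grouped["w"]
    state_mmr.name = "mmr_adjusted"
    return state_mmr


def classify_sdg(mmr: float) -> str:
    """SDG-3.1 category of a single MMR value (half-open bins)."""
    if mmr is None or not np.isfinite(mmr):
        raise ValidationError(f"mmr: cannot classify non-finite value {mmr!r}")
    if mmr < 0:
        raise ValidationError(f"mmr: cannot classify negative value {mmr}")
    for edge, label in zip(SDG_BIN_EDGES, SDG_LABELS):
        if mmr < edge:
            return label
    return SDG_LABELS[-1]


def classify_sdg_series(mmr: pd.Series) -> pd.Series:
    """Vectorised SDG classification; NaN stays NaN (undefined MMR)."""
    if (mmr.dropna() < 0).any():
        raise ValidationError("mmr: cannot classify negative values")
    bins = [0.0, *SDG_BIN_EDGES, np.inf]
    return pd.cut(mmr, bins=bins, labels=SDG_LABELS, right=False, include_lowest=True).astype(object)


def completeness(reported_births: float, estimated_births: float) -> float:
    """Registration completeness: reported births as % of estimated births."""
    if estimated_births <= 0:
        raise ValidationError("estimated_births: must be > 0")
    if reported_births < 0:
        raise ValidationError("reported_births: must be >= 0")
    return 100.0 * reported_births / estimated_births


def estimate(
    districts: pd.DataFrame,
    states: pd.DataFrame,
    allow_imr_fallback_on_degenerate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run the full estimation chain.

    Returns ``(adjusted_districts, adjusted_states, drop_report)`` where
    adjusted_districts has columns district_id, state_id, mmr_unadjusted,
    mmr_adjusted, pw, sdg_category and adjusted_states has state_id (index),
    cf, cf_source, hmis_mmr, hmis_imr, mmr_adjusted, sdg_category.
    """
    cf_table = calibration_table(districts, states, allow_imr_fallback_on_degenerate)
    adjusted = adjust_districts(districts, cf_table)
    pw = population_weights(districts)
    adjusted["pw"] = pw.reindex(adjusted["district_id"]).to_numpy()
    adjusted["sdg_category"] = classify_sdg_series(adjusted["mmr_adjusted"])
    drop_report = [
        {"district_id": rec.district_id, "reason": "zero live births: MMR undefined"}
        for rec in adjusted[adjusted["mmr_adjusted"].isna()].itertuples(index=False)
    ]
    state_mmr = aggregate_states(adjusted, pw)
    adjusted_states = cf_table.join(state_mmr)
    adjusted_states["sdg_category"] = classify_sdg_series(adjusted_states["mmr_adjusted"])
    return adjusted, adjusted_states, drop_report
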