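"""Health Infrastructure Index (HII).

Each facility/personnel indicator (district hospitals, CHCs, PHCs,
sub-centres, doctors, nurses, ANMs, ASHAs, AWWs — per 1,000 population) is
min-max normalised into an HDI-style dimension index on [0, 1]; the indices
are aggregated (arithmetic mean by default, geometric optional) into a raw
HII; and the raw index is blended with an urban component fixed at the upper
goalpost, weighted by the district's urban population share — a convention
for giving weight to (largely private, unenumerated) urban infrastructure.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from mmrcal.exceptions import ValidationError

__all__ = ["dimension_index", "aggregate_hii", "urban_adjust", "compute_hii"]


def dimension_index(value, goal_min: float, goal_max: float):
    """Min-max dimension index (value - min)/(max - min), clamped to [0, 1]."""
    if goal_max <= goal_min:
        raise ValidationError(
            f"goalposts: goal_max ({goal_max}) must exceed goal_min ({goal_min})"
        )
    scaled = (np.asarray(value, dtype=float) - goal_min) / (goal_max - goal_min)
    clipped = np.clip(scaled, 0.0, 1.0)
    return float(clipped) if np.isscalar(value) else clipped


def aggregate_hii(indices: Sequence[float] | np.ndarray, method: str = "arithmetic") -> float:
    """Aggregate dimension indices into one number."""
    arr = np.asarray(indices, dtype=float)
    if arr.size == 0:
        raise ValidationError("indices: need at least one dimension index")
    if method == "arithmetic":
        return float(arr.mean())
    if method == "geometric":
        # zeros annihilate a geometric mean; standard practice floors them
        return float(np.exp(np.log(np.maximum(arr, 1e-12)).mean()))
    raise ValidationError(f"method: expected 'arithmetic' or 'geometric', got {method!r}")


def urban_adjust(raw_hii, urban_share):
    """Convex combination of raw HII with an urban component at the upper goalpost.

    adjusted = (1 - urban_share) * raw + urban_share * 1.0; monotone
    non-decreasing in both arguments, and never below the raw index.
    """
    share = np.asarray(urban_share, dtype=float)
    if np.any((share < 0) | (share > 1)):
        raise ValidationError("urban_share: must lie in [0, 1]")
    raw = np.asarray(raw_hii, dtype=float)
    adjusted = (1.0 - share) * raw + share
    return float(adjusted) if np.isscalar(raw_hii) else adjusted


def compute_hii(
    inputs: pd.DataFrame,
    goalposts: pd.DataFrame | None = None,
    aggregation: str = "arithmetic",
) -> pd.DataFrame:
    """Compute per-district raw and urban-adjusted HII.

    Parameters
    ----------
    inputs
        Table with district_id, urban_share (in [0, 1]) and one column per
        per-1,000-population indicator.
    goalposts
        Optional table indexed by indicator with columns goal_min/goal_max.
        Defaults to the observed cross-district min/max of each indicator.
    aggregation
        'arithmetic' (default) or 'geometric'.

    Returns a frame with district_id, one ``idx_<indicator>`` column per
    indicator, raw_hii and adjusted_hii.
    """
    if "district_id" not in inputs.columns or "urban_share" not in inputs.columns:
        raise ValidationError("hii inputs: need district_id and urban_share columns")
    indicator_cols = [c for c in inputs.columns if c not in ("district_id", "urban_share")]
    if not indicator_cols:
        raise ValidationError("hii inputs: no indicator columns found")
    for col in indicator_cols:
        if (inputs[col] < 0).any():
            raise ValidationError(f"hii inputs: negative values in indicator {col}")

    out = pd.DataFrame({"district_id": inputs["district_id"]})
    index_matrix = np.empty((len(inputs), len(indicator_cols)))
    for k, col in enumerate(indicator_cols):
        if goalposts is not None:
            if col not in goalposts.index:
                raise ValidationError(f"goalposts: no row for indicator {col}")
            lo = float(goalposts.loc[col, "goal_min"])
            hi = float(goalposts.loc[col, "goal_max"])
        else:
            lo = float(inputs[col].min())
            hi = float(inputs[col].max())
        index_matrix[:, k] = dimension_index(inputs[col].to_numpy(), lo, hi)
        out[f"idx_{col}"] = index_matrix[:, k]
    out["raw_hii"] = [aggregate_hii(row, aggregation) for row in index_matrix]
    out["adjusted_hii"] = urban_adjust(
        out["raw_hii"].to_numpy(), inputs["urban_share"].to_numpy()
    )
    return out
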