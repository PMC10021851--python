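"""Ecological log-linear OLS models of district MMR.

Models regress log district MMR on health-infrastructure, maternal-care,
demographic and socioeconomic covariates (each log- or identity-transformed)
with heteroskedasticity-robust (sandwich) standard errors. A pairwise Pearson
correlation screen keeps highly collinear covariates (|r| > 0.60 by default)
out of the same model. Zero-MMR districts have no log outcome: they are
dropped by default (and reported), or shifted by a configurable offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mmrcal.exceptions import ValidationError

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "CollinearityScreen",
    "prepare_outcome",
    "screen_collinearity",
    "fit_ols",
    "model_suite",
]

ROBUST_FLAVOURS = ("HC0", "HC1", "HC2", "HC3")


@dataclass(frozen=True)
class ModelSpec:
    """One model: ordered covariates with per-covariate transforms.

    ``covariates`` maps covariate name -> 'log' | 'identity'.
    ``include_state_fe`` adds state fixed effects (the area-dummy option).
    """

    label: str
    covariates: dict[str, str]
    include_state_fe: bool = False

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValidationError(f"model {self.label}: no covariates")
        bad = {t for t in self.covariates.values()} - {"log", "identity"}
        if bad:
            raise ValidationError(
                f"model {self.label}: unknown transforms {sorted(bad)}"
            )


@dataclass(frozen=True)
class CollinearityScreen:
    """Pairwise Pearson correlations with the flagged high-|r| pairs."""

    matrix: pd.DataFrame
    flagged_pairs: tuple[tuple[str, str, float], ...]
    threshold: float
    constant_columns: tuple[str, ...] = ()

    def validate_spec(self, spec: ModelSpec, override: bool = False) -> None:
        """Fail if a model contains a flagged pair (unless overridden)."""
        if override:
            return
        names = set(spec.covariates)
        for a, b, r in self.flagged_pairs:
            if a in names and b in names:
                raise ValidationError(
                    f"model {spec.label}: covariates ({a}, {b}) are collinear "
                    f"(|r| = {abs(r):.3f} > {self.threshold})"
                )


@dataclass(frozen=True)
class RegressionFit:
    """OLS estimates with robust standard errors and a dropped-row report."""

    label: str
    params: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    residuals: pd.Series
    r_squared: float
    nobs: int
    dropped: tuple[dict, ...]
    robust_flavour: str
    classical_se: pd.Series = field(repr=False, default=None)


def prepare_outcome(
    mmr: pd.Series, zero_policy: str = "drop", offset: float = 1.0
) -> tuple[pd.Series, list[dict]]:
    """log(MMR) outcome with explicit zero handling.

    ``drop`` removes zero/undefined-MMR rows (listed in the report);
    ``offset`` uses log(MMR + offset) and keeps all finite rows.
    """
    if (mmr.dropna() < 0).any():
        raise ValidationError("mmr: negative values cannot be log-transformed")
    if zero_policy not in ("drop", "offset"):
        raise ValidationError(f"zero_policy: expected 'drop' or 'offset', got {zero_policy!r}")
    report = [
        {"district_id": i, "reason": "undefined MMR (zero births)"}
        for i in mmr.index[mmr.isna()]
    ]
    kept = mmr.dropna()
    if zero_policy == "drop":
        report += [
            {"district_id": i, "reason": "zero MMR dropped under log transform"}
            for i in kept.index[kept == 0]
        ]
        kept = kept[kept > 0]
        return np.log(kept), report
    if offset <= 0:
        raise ValidationError("offset: must be > 0 under the offset policy")
    return np.log(kept + offset), report


def screen_collinearity(
    covariates: pd.DataFrame, threshold: float = 0.60
) -> CollinearityScreen:
    """Pairwise Pearson correlation screen on complete cases."""
    if covariates.shape[1] < 2:
        raise ValidationError("covariates: need at least 2 columns to screen")
    if len(covariates) < 3:
        raise ValidationError("covariates: need at least 3 rows to screen")
    complete = covariates.dropna()
    stds = complete.std(ddof=0)
    constant = tuple(stds.index[stds == 0])
    usable = complete.drop(columns=list(constant))
    matrix = usable.corr(method="pearson")
    flagged = []
    for a, b in itertools.combinations(matrix.columns, 2):
        r = float(matrix.loc[a, b])
        if abs(r) > threshold:
            flagged.append((a, b, r))
    return CollinearityScreen(
        matrix=matrix,
        flagged_pairs=tuple(flagged),
        threshold=threshold,
        constant_columns=constant,
    )


def _design_matrix(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    missing_cols = [c for c in spec.covariates if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"model {spec.label}: covariates not in data {missing_cols}")
    cols = {}
    dropped_mask = pd.Series(False, index=data.index)
    reasons: dict = {}
    for name, transform in spec.covariates.items():
        col = data[name].astype(float)
        na = col.isna()
        for i in data.index[na & ~dropped_mask]:
            reasons[i] = f"missing {name}"
        dropped_mask |= na
        if transform == "log":
            nonpos = (col <= 0) & ~na
            for i in data.index[nonpos & ~dropped_mask]:
                reasons[i] = f"non-positive {name} under log transform"
            dropped_mask |= nonpos
            with np.errstate(divide="ignore", invalid="ignore"):
                col = np.log(col.where(col > 0))
            cols[f"log_{name}"] = col
        else:
            cols[name] = col
    x = pd.DataFrame(cols, index=data.index)
    if spec.include_state_fe:
        if "state_id" not in data.columns:
            raise ValidationError(f"model {spec.label}: state fixed effects need state_id")
        dummies = pd.get_dummies(data["state_id"], prefix="state", drop_first=True)
        x = pd.concat([x, dummies.astype(float)], axis=1)
    x = x[~dropped_mask]
    report = [{"district_id": i, "reason": r} for i, r in reasons.items()]
    return sm.add_constant(x), report


def fit_ols(
    spec: ModelSpec,
    data: pd.DataFrame,
    outcome: str = "log_mmr",
    robust: str = "HC1",
) -> RegressionFit:
    """Least squares with sandwich standard errors and listwise deletion.

    ``data`` must carry the (already log-transformed) outcome column plus raw
    covariate columns; rows missing any model field are dropped and reported.
    """
    if robust not in ROBUST_FLAVOURS:
        raise ValidationError(f"robust: expected one of {ROBUST_FLAVOURS}, got {robust!r}")
    if outcome not in data.columns:
        raise ValidationError(f"outcome: column {outcome!r} not in data")
    y = data[outcome].astype(float)
    y_na = y.isna()
    x, report = _design_matrix(spec, data)
    report += [
        {"district_id": i, "reason": "missing outcome"}
        for i in data.index[y_na]
        if i in x.index
    ]
    rows = x.index[~y_na.reindex(x.index, fill_value=True)]
    x = x.loc[rows]
    y = y.loc[rows]
    n, k = x.shape
    if n <= k:
        raise ValidationError(f"model {spec.label}: {n} rows for {k} parameters")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < k:
        raise ValidationError(
            f"model {spec.label}: design matrix is rank deficient "
            f"(rank {rank} < {k}); check for linearly dependent covariates"
        )
    model = sm.OLS(y, x)
    res_robust = model.fit(cov_type=robust)
    res_classical = model.fit()
    return RegressionFit(
        label=spec.label,
        params=res_robust.params,
        robust_se=res_robust.bse,
        pvalues=res_robust.pvalues,
        residuals=res_robust.resid,
        r_squared=float(res_robust.rsquared),
        nobs=int(res_robust.nobs),
        dropped=tuple(report),
        robust_flavour=robust,
        classical_se=res_classical.bse,
    )


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def model_suite(
    data: pd.DataFrame,
    models: list[ModelSpec],
    outcome: str = "log_mmr",
    robust: str = "HC1",
    univariate: bool = True,
    screen: CollinearityScreen | None = None,
) -> pd.DataFrame:
    """Run a family of models and emit a long-format results table.

    With ``univariate=True`` a one-covariate model is first fitted for every
    covariate appearing anywhere in the suite (the "model 1" column of a
    correlates table). Columns: model, term, estimate, robust_se, p_stars,
    n, r2.
    """
    rows = []
    fits: dict[str, RegressionFit] = {}
    if univariate:
        seen: dict[str, str] = {}
        for spec in models:
            for name, transform in spec.covariates.items():
                seen.setdefault(name, transform)
        for name, transform in seen.items():
            fit = fit_ols(
                ModelSpec(label=f"univariate:{name}", covariates={name: transform}),
                data,
                outcome=outcome,
                robust=robust,
            )
            fits[fit.label] = fit
    for spec in models:
        if screen is not None:
            screen.validate_spec(spec)
        fit = fit_ols(spec, data, outcome=outcome, robust=robust)
        fits[fit.label] = fit
    for label, fit in fits.items():
        for term in fit.params.index:
            if term.startswith("state_"):
                continue
            rows.append(
                {
                    "model": label,
                    "term": term,
                    "estimate": float(fit.params[term]),
                    "robust_se": float(fit.robust_se[term]),
                    "p_stars": _stars(float(fit.pvalues[term])),
                    "n": fit.nobs,
                    "r2": fit.r_squared,
                }
            )
    return pd.DataFrame(rows)
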