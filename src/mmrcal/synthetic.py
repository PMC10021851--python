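"""Synthetic multi-state district system with known ground truth.

Emulates the statistical structure of the real inputs to a district-level
maternal-mortality calibration study: states containing districts laid out on
a rectangular lattice, a true MMR surface with spatial autocorrelation,
binomially sampled maternal and infant deaths, state-level multiplicative
under-reporting of deaths, a gold-standard state reference table with some
reference MMRs withheld (forcing the IMR-proxy calibration path), and
covariates linked to log-MMR through known coefficients.

Every quantity that downstream stages estimate is recorded in
:class:`SyntheticTruth`, so calibration recovery, spatial clustering and
regression recovery can all be tested against a known answer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

from mmrcal.exceptions import ValidationError

__all__ = [
    "COVARIATE_SCALES",
    "DEFAULT_COVARIATE_EFFECTS",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_system",
    "write_fixture",
    "write_lattice_geojson",
]

# Plausible cross-district mean/sd/bounds per covariate for an Indian-style
# district system (percent scales bounded at [0, 100]).
COVARIATE_SCALES: dict[str, tuple[float, float, float, float]] = {
    # name: (mean, sd, lower, upper)
    "anc4_pct": (52.5, 26.0, 0.0, 100.0),
    "pnc_pct": (62.7, 17.7, 0.0, 100.0),
    "institutional_delivery_pct": (80.3, 16.6, 0.0, 100.0),
    "contraception_pct": (50.8, 17.2, 0.0, 100.0),
    "bmi": (17.6, 8.8, 1.0, 45.0),
    "anaemia_pct": (51.6, 12.1, 0.0, 100.0),
    "age_at_marriage": (18.6, 1.4, 14.0, 30.0),
    "age_at_first_birth": (20.6, 1.0, 15.0, 35.0),
    "children_ever_born": (2.46, 0.44, 1.0, 6.0),
    "schooling_10plus_pct": (28.1, 14.3, 0.0, 100.0),
    "sex_ratio_at_birth": (925.0, 111.0, 500.0, 1600.0),
    "household_size": (5.68, 0.76, 2.0, 12.0),
    "sc_st_pct": (38.2, 23.3, 0.0, 100.0),
    "urban_pct": (27.3, 21.7, 0.0, 100.0),
    "poor_household_pct": (40.7, 25.7, 0.0, 100.0),
}

# Coefficients on log true MMR per 1 SD of the covariate; signs follow the
# direction maternal-health ecology reports (more antenatal/postnatal care and
# schooling lower mortality; higher parity and poverty raise it).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "anc4_pct": -0.10,
    "pnc_pct": -0.10,
    "children_ever_born": 0.20,
    "schooling_10plus_pct": -0.15,
    "poor_household_pct": 0.10,
}

#: Female population aged 15-49 per cumulative live birth of the analysis
#: window (three years of births at ~35/1000 women/year inverts to ~8-10).
_FEMALE_POP_PER_BIRTH = 8.0

#: Base infant mortality (per 1,000 live births) around which the true IMR
#: surface is centred; its log co-moves with log MMR at slope 1/2 so that the
#: two mortality surfaces are positively correlated, as observed nationally.
_IMR_BASE = 30.0
_IMR_MMR_ELASTICITY = 0.5


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic district system.

    Defaults describe a 640-district, 32-state country on a 32 x 20 lattice:
    state base MMR log-uniform on [60, 300] deaths per 100,000 (bracketing
    the observed Indian state range), ~100k cumulative live births per
    district over a three-year window, and death reporting fractions between
    0.5 and 1.0 by state.
    """

    n_states: int = 32
    districts_per_state: int = 20
    lattice_rows: int = 32
    lattice_cols: int = 20
    base_mmr_range: tuple[float, float] = (60.0, 300.0)
    spatial_rho: float = 0.6
    reporting_fraction_range: tuple[float, float] = (0.5, 1.0)
    births_per_district_range: tuple[int, int] = (60_000, 180_000)
    missing_reference_fraction: float = 0.25
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = 0.15
    underreport_births: bool = False
    reference_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_states >= 1, "n_states", "must be >= 1")
        _check(self.districts_per_state >= 1, "districts_per_state", "must be >= 1")
        _check(
            self.lattice_rows * self.lattice_cols
            == self.n_states * self.districts_per_state,
            "lattice_rows/lattice_cols",
            "lattice size must equal n_states * districts_per_state",
        )
        lo, hi = self.base_mmr_range
        _check(0 < lo <= hi, "base_mmr_range", "must be a non-empty positive interval")
        _check(0.0 <= self.spatial_rho < 1.0, "spatial_rho", "must lie in [0, 1)")
        rlo, rhi = self.reporting_fraction_range
        _check(0 < rlo <= rhi <= 1.0, "reporting_fraction_range", "must lie in (0, 1]")
        blo, bhi = self.births_per_district_range
        _check(0 < blo <= bhi, "births_per_district_range", "must be a non-empty positive interval")
        _check(
            0.0 <= self.missing_reference_fraction <= 1.0,
            "missing_reference_fraction",
            "must lie in [0, 1]",
        )
        _check(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _check(self.reference_noise_sd >= 0.0, "reference_noise_sd", "must be >= 0")
        unknown = set(self.covariate_effects) - set(COVARIATE_SCALES)
        _check(not unknown, "covariate_effects", f"unknown covariates {sorted(unknown)}")

    @property
    def n_districts(self) -> int:
        return self.n_states * self.districts_per_state


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside a generated system."""

    district_true_mmr: pd.Series
    district_true_imr: pd.Series
    state_true_mmr: pd.Series
    state_true_imr: pd.Series
    state_reporting_fraction: pd.Series
    covariate_effects: dict[str, float]
    covariate_scales: dict[str, tuple[float, float]]
    intercept_by_state: pd.Series

    def __post_init__(self) -> None:
        if (self.district_true_mmr < 0).any():
            raise ValidationError("district_true_mmr: true MMR must be >= 0")


def _queen_edges(rows: int, cols: int) -> list[tuple[int, int]]:
    """Queen-contiguity edge list for a rows x cols lattice, row-major ids."""
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        j = rr * cols + cc
                        if i < j:
                            edges.append((i, j))
    return edges


def _spatial_field(
    edges: list[tuple[int, int]], n: int, rho: float, eta: np.ndarray
) -> np.ndarray:
    """Solve the simultaneous autoregressive fixed point (I - rho W*) f = eta."""
    if rho == 0.0 or not edges:
        return eta
    rows = [i for i, j in edges] + [j for i, j in edges]
    cols = [j for i, j in edges] + [i for i, j in edges]
    w = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(w.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    w_star = scipy.sparse.diags(inv) @ w
    a = scipy.sparse.eye(n, format="csc") - rho * w_star.tocsc()
    return scipy.sparse.linalg.spsolve(a, eta)


def generate_system(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (district table, state reference table, adjacency, truth).

    The true log-MMR surface is a per-state base effect plus covariate
    contributions plus a spatially autocorrelated noise field; observed
    maternal (infant) deaths are binomial draws of the true rates thinned by
    the state reporting fraction. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_districts
    width = max(3, len(str(n)))
    district_ids = np.array([f"d{i:0{width}d}" for i in range(n)])
    state_width = max(2, len(str(config.n_states)))
    state_ids = np.array([f"s{i:0{state_width}d}" for i in range(config.n_states)])
    district_state = np.repeat(state_ids, config.districts_per_state)

    # State base effects: log-uniform over the configured MMR interval.
    lo, hi = config.base_mmr_range
    log_base = rng.uniform(math.log(lo), math.log(hi), size=config.n_states)
    state_effect = np.repeat(log_base, config.districts_per_state)

    # Covariates: truncated-normal draws; the linear predictor uses the
    # z-score of the *stored* (clipped) value so the covariate link is exact.
    cov_values: dict[str, np.ndarray] = {}
    cov_z: dict[str, np.ndarray] = {}
    for name, (mu, sd, lower, upper) in COVARIATE_SCALES.items():
        raw = rng.normal(mu, sd, size=n)
        x = np.clip(raw, lower, upper)
        cov_values[name] = x
        cov_z[name] = (x - mu) / sd
    effects = dict(config.covariate_effects)
    cov_term = np.zeros(n)
    for name, beta in effects.items():
        cov_term += beta * cov_z[name]

    edges = _queen_edges(config.lattice_rows, config.lattice_cols)
    eta = rng.normal(0.0, config.noise_sd, size=n)
    noise_field = _spatial_field(edges, n, config.spatial_rho, eta)

    log_mmr = state_effect + cov_term + noise_field
    true_mmr = np.minimum(np.exp(log_mmr), 99_000.0)
    true_imr = np.minimum(
        _IMR_BASE * np.exp(_IMR_MMR_ELASTICITY * (log_mmr - log_mmr.mean())), 990.0
    )

    births = rng.integers(
        config.births_per_district_range[0],
        config.births_per_district_range[1] + 1,
        size=n,
    )
    female_pop = np.round(_FEMALE_POP_PER_BIRTH * births).astype(np.int64)

    rlo, rhi = config.reporting_fraction_range
    state_r = rng.uniform(rlo, rhi, size=config.n_states)
    district_r = np.repeat(state_r, config.districts_per_state)

    true_maternal = rng.binomial(births, true_mmr / 1e5)
    true_infant = rng.binomial(births, true_imr / 1e3)
    obs_maternal = rng.binomial(true_maternal, district_r)
    obs_infant = rng.binomial(true_infant, district_r)
    if config.underreport_births:
        # Reported deaths can only come from reported births.
        obs_births = np.maximum(
            rng.binomial(births, district_r), np.maximum(obs_maternal, obs_infant)
        )
    else:
        obs_births = births

    districts = pd.DataFrame(
        {
            "district_id": district_ids,
            "state_id": district_state,
            "live_births": obs_births,
            "maternal_deaths": obs_maternal,
            "infant_deaths": obs_infant,
            "female_pop_15_49": female_pop,
            **cov_values,
        }
    )

    # True state rates are true-birth-weighted means of the district truths.
    bser = pd.Series(births, index=district_ids, dtype=float)
    sser = pd.Series(district_state, index=district_ids)
    t_mmr = pd.Series(true_mmr, index=district_ids, name="true_mmr")
    t_imr = pd.Series(true_imr, index=district_ids, name="true_imr")
    state_births = bser.groupby(sser).sum()
    state_true_mmr = (t_mmr * bser).groupby(sser).sum() / state_births
    state_true_imr = (t_imr * bser).groupby(sser).sum() / state_births

    ref_mmr = state_true_mmr.reindex(state_ids).to_numpy(dtype=float)
    ref_imr = state_true_imr.reindex(state_ids).to_numpy(dtype=float)
    if config.reference_noise_sd > 0:
        ref_mmr = ref_mmr * np.exp(rng.normal(0, config.reference_noise_sd, config.n_states))
        ref_imr = ref_imr * np.exp(rng.normal(0, config.reference_noise_sd, config.n_states))
    n_missing = int(config.missing_reference_fraction * config.n_states)
    missing_idx = rng.choice(config.n_states, size=n_missing, replace=False)
    ref_mmr[missing_idx] = np.nan

    states = pd.DataFrame(
        {"state_id": state_ids, "ref_mmr": ref_mmr, "ref_imr": ref_imr}
    )

    adjacency = pd.DataFrame(
        {
            "district_id": [district_ids[i] for i, j in edges],
            "neighbor_id": [district_ids[j] for i, j in edges],
        }
    )

    truth = SyntheticTruth(
        district_true_mmr=t_mmr,
        district_true_imr=t_imr,
        state_true_mmr=state_true_mmr.reindex(state_ids),
        state_true_imr=state_true_imr.reindex(state_ids),
        state_reporting_fraction=pd.Series(state_r, index=state_ids, name="reporting_fraction"),
        covariate_effects=effects,
        covariate_scales={k: (v[0], v[1]) for k, v in COVARIATE_SCALES.items()},
        intercept_by_state=pd.Series(log_base, index=state_ids, name="log_base_mmr"),
    )
    return districts, states, adjacency, truth


def write_fixture(
    districts: pd.DataFrame,
    states: pd.DataFrame,
    adjacency: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write districts.csv, states.csv, adjacency.csv and truth.csv.

    Floats are written with shortest round-trip repr, so reading the files
    back reproduces the in-memory tables exactly.
    """
    if len(districts) == 0:
        raise ValidationError("districts: refusing to write an empty district table")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "districts": directory / "districts.csv",
        "states": directory / "states.csv",
        "adjacency": directory / "adjacency.csv",
        "truth": directory / "truth.csv",
    }
    districts.to_csv(paths["districts"], index=False)
    states.to_csv(paths["states"], index=False)
    adjacency.to_csv(paths["adjacency"], index=False)
    truth_df = pd.DataFrame(
        {
            "district_id": truth.district_true_mmr.index,
            "true_mmr": truth.district_true_mmr.to_numpy(),
            "true_imr": truth.district_true_imr.to_numpy(),
        }
    )
    truth_df.to_csv(paths["truth"], index=False)
    return paths


def write_lattice_geojson(
    rows: int, cols: int, district_ids: list[str] | np.ndarray, path: str | Path
) -> Path:
    """Write unit-square polygons of the lattice as GeoJSON (row-major ids).

    Useful for exercising polygon-based queen-contiguity construction: cells
    that share an edge or a corner must come out as neighbours.
    """
    if rows * cols != len(district_ids):
        raise ValidationError("district_ids: length must equal rows * cols")
    features = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            ring = [
                [c, r],
                [c + 1, r],
                [c + 1, r + 1],
                [c, r + 1],
                [c, r],
            ]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"district_id": str(district_ids[i])},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
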