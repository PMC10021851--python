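"""Pipeline orchestration, SDG classification summaries, source comparison."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

import mmrcal
from mmrcal import estimation, hii as hii_mod, io as io_mod, regression, spatial, synthetic
from mmrcal.exceptions import ValidationError

__all__ = ["ClassificationSummary", "RunConfig", "summarize_classification", "compare_sources", "run_pipeline"]

logger = logging.getLogger("mmrcal")

ALL_STAGES = ("estimate", "hii", "spatial", "regress", "report")

# Default covariate groupings for the correlates model suite; the combined
# model adds state fixed effects (the area-dummy interpretation).
DEFAULT_SUITE_GROUPS: dict[str, list[str]] = {
    "care": ["anc4_pct", "pnc_pct", "institutional_delivery_pct"],
    "demographic": [
        "age_at_marriage",
        "age_at_first_birth",
        "contraception_pct",
        "children_ever_born",
        "bmi",
        "anaemia_pct",
    ],
    "socioeconomic": [
        "schooling_10plus_pct",
        "sex_ratio_at_birth",
        "sc_st_pct",
        "urban_pct",
        "poor_household_pct",
    ],
}


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts of districts/states per SDG bin, with the extreme units."""

    district_counts: dict
    state_counts: dict
    n_districts_defined: int
    n_districts_undefined: int
    max_district: tuple
    min_district: tuple
    max_state: tuple | None
    min_state: tuple | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flags > file > defaults)."""

    districts: str | None = None
    states: str | None = None
    adjacency: str | None = None
    hii_inputs: str | None = None
    out_dir: str = "mmrcal_out"
    seed: int = 0
    n_permutations: int = 999
    alpha: float = 0.05
    sdg_bin_edges: tuple[float, ...] = estimation.SDG_BIN_EDGES
    zero_policy: str = "drop"
    robust: str = "HC1"
    spatial_variable: str = "mmr_adjusted"
    allow_imr_fallback_on_degenerate: bool = False
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        edges = tuple(self.sdg_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])) or not edges:
            raise ValidationError("sdg_bin_edges: must be non-empty and strictly increasing")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha: must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"stages: unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("sdg_bin_edges", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _bin_labels(edges: tuple[float, ...]) -> list[str]:
    if tuple(edges) == tuple(estimation.SDG_BIN_EDGES):
        return list(estimation.SDG_LABELS)
    labels = [f"below_{edges[0]:g}"]
    labels += [f"{a:g}_{b:g}" for a, b in zip(edges, edges[1:])]
    labels.append(f"ge_{edges[-1]:g}")
    return labels


def _classify(values: pd.Series, edges: tuple[float, ...]) -> pd.Series:
    labels = _bin_labels(edges)
    bins = [0.0, *edges, np.inf]
    return pd.cut(values, bins=bins, labels=labels, right=False, include_lowest=True).astype(object)


def summarize_classification(
    adjusted_districts: pd.DataFrame,
    adjusted_states: pd.DataFrame | None = None,
    bin_edges: tuple[float, ...] = estimation.SDG_BIN_EDGES,
) -> ClassificationSummary:
    """Per-bin counts and extremes for districts (and optionally states).

    Districts with undefined MMR are counted separately; the bin counts
    always partition the defined-MMR districts.
    """
    labels = _bin_labels(tuple(bin_edges))
    mmr = adjusted_districts.set_index("district_id")["mmr_adjusted"]
    defined = mmr.dropna()
    if defined.empty:
        raise ValidationError("classification: no district has a defined MMR")
    cats = _classify(defined, tuple(bin_edges))
    district_counts = {lab: int((cats == lab).sum()) for lab in labels}
    max_district = (str(defined.idxmax()), float(defined.max()))
    min_district = (str(defined.idxmin()), float(defined.min()))
    state_counts: dict = {}
    max_state = min_state = None
    if adjusted_states is not None:
        smmr = adjusted_states["mmr_adjusted"].dropna()
        scats = _classify(smmr, tuple(bin_edges))
        state_counts = {lab: int((scats == lab).sum()) for lab in labels}
        max_state = (str(smmr.idxmax()), float(smmr.max()))
        min_state = (str(smmr.idxmin()), float(smmr.min()))
    return ClassificationSummary(
        district_counts=district_counts,
        state_counts=state_counts,
        n_districts_defined=int(defined.size),
        n_districts_undefined=int(mmr.isna().sum()),
        max_district=max_district,
        min_district=min_district,
        max_state=max_state,
        min_state=min_state,
    )


def compare_sources(a: pd.Series, b: pd.Series) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between two rate series over their common units."""
    paired = pd.DataFrame({"a": a, "b": b}).dropna()
    if len(paired) < 3:
        raise ValidationError(f"compare_sources: need >= 3 paired units, got {len(paired)}")
    if paired["a"].std(ddof=0) == 0 or paired["b"].std(ddof=0) == 0:
        raise ValidationError("compare_sources: a series is constant; correlation undefined")
    r = float(scipy.stats.pearsonr(paired["a"], paired["b"]).statistic)
    return r, paired


def _default_suite(districts: pd.DataFrame) -> list[regression.ModelSpec]:
    """Grouped models over whichever default covariates the table carries.

    A covariate is log-transformed when strictly positive in the data,
    otherwise entered untransformed.
    """
    def transform(col: str) -> str:
        return "log" if (districts[col] > 0).all() else "identity"

    specs = []
    present_union: dict[str, str] = {}
    for label, cols in DEFAULT_SUITE_GROUPS.items():
        present = {c: transform(c) for c in cols if c in districts.columns}
        if present:
            specs.append(regression.ModelSpec(label=label, covariates=present))
            present_union.update(present)
    if present_union:
        specs.append(
            regression.ModelSpec(
                label="combined_state_fe",
                covariates=present_union,
                include_state_fe=True,
            )
        )
    return specs


def _prune_collinear(
    spec: regression.ModelSpec, screen: regression.CollinearityScreen
) -> regression.ModelSpec:
    """Drop the later member of each flagged pair from a model."""
    kept = dict(spec.covariates)
    for a, b, _ in screen.flagged_pairs:
        if a in kept and b in kept:
            del kept[b]
    return regression.ModelSpec(
        label=spec.label, covariates=kept, include_state_fe=spec.include_state_fe
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the toggled stages and write all artifacts to the out dir.

    Without input paths a default synthetic system is generated (seeded by
    ``config.seed``) and written under ``<out_dir>/inputs``. Stage seeds are
    derived from the master seed (spatial permutations use seed + 1) so that
    stages can be rerun independently yet reproducibly. Idempotent: the same
    config writes byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata: dict = {
        "package_version": mmrcal.__version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "drop_reports": {},
    }

    t0 = time.perf_counter()
    if config.districts is None:
        syn_cfg = synthetic.SyntheticConfig(seed=config.seed)
        districts, states, adjacency, truth = synthetic.generate_system(syn_cfg)
        paths = synthetic.write_fixture(districts, states, adjacency, truth, out / "inputs")
        metadata["stages"]["simulate"] = {
            "n_districts": len(districts),
            "inputs_dir": str(out / "inputs"),
        }
        logger.info("simulate: %d districts in %.2fs", len(districts), time.perf_counter() - t0)
    else:
        if config.states is None:
            raise ValidationError("states: required when districts is given")
        districts = io_mod.read_districts(config.districts)
        states = io_mod.read_states(config.states)
        adjacency = io_mod.read_adjacency(config.adjacency) if config.adjacency else None

    adjusted = adjusted_states = None
    if "estimate" in config.stages:
        t = time.perf_counter()
        adjusted, adjusted_states, drops = estimation.estimate(
            districts, states, config.allow_imr_fallback_on_degenerate
        )
        adjusted.to_csv(out / "adjusted_districts.csv", index=False)
        adjusted_states.to_csv(out / "adjusted_states.csv")
        metadata["stages"]["estimate"] = {
            "n_districts": len(adjusted),
            "n_states": len(adjusted_states),
        }
        metadata["drop_reports"]["estimate"] = drops
        logger.info("estimate: %d districts in %.2fs", len(adjusted), time.perf_counter() - t)

    if "hii" in config.stages and config.hii_inputs:
        t = time.perf_counter()
        hii_inputs = pd.read_csv(config.hii_inputs, dtype={"district_id": str})
        hii_table = hii_mod.compute_hii(hii_inputs)
        hii_table.to_csv(out / "hii.csv", index=False)
        metadata["stages"]["hii"] = {"n_districts": len(hii_table)}
        logger.info("hii: %d districts in %.2fs", len(hii_table), time.perf_counter() - t)

    if "spatial" in config.stages and adjacency is not None and adjusted is not None:
        t = time.perf_counter()
        w = spatial.build_weights(edges=adjacency, ids=adjusted["district_id"].tolist())
        values = adjusted.set_index("district_id")[config.spatial_variable].dropna()
        # islands and undefined-MMR districts are excluded up front
        keep = values.index
        if len(keep) < w.n:
            w = spatial.build_weights(
                edges=adjacency[
                    adjacency["district_id"].isin(keep)
                    & adjacency["neighbor_id"].isin(keep)
                ],
                ids=list(keep),
            )
        spatial_seed = (config.seed + 1) % 2**31
        moran = spatial.moran_permutation_p(
            values, w, n_permutations=config.n_permutations, seed=spatial_seed
        )
        pd.DataFrame(
            [
                {
                    "I": moran.I,
                    "expected_I": moran.expected_I,
                    "pseudo_p": moran.pseudo_p,
                    "n_perm": moran.n_permutations,
                    "seed": moran.seed,
                    "n_units": moran.n,
                }
            ]
        ).to_csv(out / "moran_global.csv", index=False)
        lisa = spatial.lisa_permutation(
            values,
            w,
            n_permutations=config.n_permutations,
            seed=spatial_seed,
            alpha=config.alpha,
        )
        lisa.to_csv(out / "lisa.csv")
        metadata["stages"]["spatial"] = {
            "global_moran_i": moran.I,
            "pseudo_p": moran.pseudo_p,
            "n_islands": len(w.islands),
        }
        logger.info("spatial: I=%.4f p=%.4f in %.2fs", moran.I, moran.pseudo_p, time.perf_counter() - t)

    if "regress" in config.stages and adjusted is not None:
        t = time.perf_counter()
        covars = io_mod.covariate_columns(districts)
        merged = districts.merge(
            adjusted[["district_id", "mmr_adjusted"]], on="district_id"
        ).set_index("district_id")
        log_mmr, drop_report = regression.prepare_outcome(
            merged["mmr_adjusted"], zero_policy=config.zero_policy
        )
        merged["log_mmr"] = log_mmr
        suite = _default_suite(districts)
        if suite and covars:
            screen = regression.screen_collinearity(merged[covars])
            suite = [_prune_collinear(s, screen) for s in suite]
            table = regression.model_suite(
                merged, suite, outcome="log_mmr", robust=config.robust, screen=screen
            )
            table.to_csv(out / "regression_table.csv", index=False)
            metadata["stages"]["regress"] = {
                "n_models": int(table["model"].nunique()),
                "flagged_pairs": [
                    [a, b, round(r, 4)] for a, b, r in screen.flagged_pairs
                ],
            }
            metadata["drop_reports"]["regress"] = drop_report
            logger.info("regress: %d models in %.2fs", table["model"].nunique(), time.perf_counter() - t)

    if "report" in config.stages and adjusted is not None:
        summary = summarize_classification(
            adjusted, adjusted_states, bin_edges=tuple(config.sdg_bin_edges)
        )
        (out / "classification_summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True)
        )
        # Source comparison: reference IMR vs facility-system state MMR.
        if adjusted_states is not None and "ref_imr" in states.columns:
            ref_imr = states.set_index("state_id")["ref_imr"]
            try:
                r, paired = compare_sources(ref_imr, adjusted_states["hmis_mmr"])
                paired.rename(columns={"a": "ref_imr", "b": "hmis_mmr"}).to_csv(
                    out / "source_comparison.csv"
                )
                metadata["stages"]["report"] = {"imr_mmr_correlation": r}
            except ValidationError:
                metadata["stages"]["report"] = {"imr_mmr_correlation": None}

    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return out
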