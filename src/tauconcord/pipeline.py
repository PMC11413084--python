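"""End-to-end orchestration: simulate -> quantify -> petcalc -> analyze -> report.

A run is driven by a single :class:`RunConfig` (YAML-serializable). Every
stage is deterministic given the config and its seed; tables are written as
long-format CSVs keyed by subject_id and region, and the report JSON records
provenance (config hash, seed, package version) next to every result table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ihc import GraphCutParams, quantify_cohort_fields
from .pet import compute_suvr, load_meta_roi, meta_roi_table
from .stats import (
    EmptySubsetError,
    assign_sextiles,
    classify_part,
    concordance_accuracy,
    fit_gamma_glm,
    linear_vs_polynomial,
    spearman_corr,
    subgroup_spearman,
    youden_detection_threshold,
)
from .synthetic import (
    Cohort,
    CohortConfig,
    OFF_TARGET_REGIONS,
    SchemaError,
    TEMPORAL_META_MEMBERS,
    generate_cohort,
    load_fixture_set,
    write_fixture_set,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "ConfigError",
    "DataError",
    "run_pipeline",
    "load_cohort_tables",
]

log = logging.getLogger("tauconcord")

ALL_ANALYSES = ("correlations", "thresholds", "concordance", "linearity", "glm", "subgroups")

_ROMAN_BRAAK = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6}


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    The global seed is fanned out to the stages through the cohort config;
    PET positivity cut-offs default to 1.36 (temporal composite) and 1.19
    (cortical composite).
    """

    seed: int = 0
    output_dir: str = "tauconcord_out"
    simulate: bool = True
    input_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    quantify: bool = False
    quantify_method: str = "threshold"  # threshold | graphcut | both
    quantify_image_size: int = 128
    quantify_max_subjects: int | None = None
    quantify_regions: tuple[str, ...] | None = TEMPORAL_META_MEMBERS
    cutoff_temporal: float = 1.36
    cutoff_cortical: float = 1.19
    analyses: tuple[str, ...] = ALL_ANALYSES
    degree: int = 2
    glm_link: str = "log"
    figures: bool = True
    write_fixtures: bool = False

    def __post_init__(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ConfigError("either enable simulation or provide input_dir")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")
        if self.quantify_method not in ("threshold", "graphcut", "both"):
            raise ConfigError(f"unknown quantify method {self.quantify_method!r}")
        if self.glm_link not in ("log", "identity"):
            raise ConfigError(f"unknown GLM link {self.glm_link!r}")
        # the pipeline seed overrides the cohort block's seed so one value
        # controls the whole run
        if self.cohort.seed != self.seed:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["analyses"] = list(self.analyses)
        if self.quantify_regions is not None:
            d["quantify_regions"] = list(self.quantify_regions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        if d.get("quantify_regions") is not None:
            d["quantify_regions"] = tuple(d["quantify_regions"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    provenance: dict
    tables: dict[str, pd.DataFrame]
    summary: dict
    output_dir: Path


def _validate_stage_column(df: pd.DataFrame, column: str, low: int, high: int) -> None:
    for i, v in df[column].items():
        if isinstance(v, str):
            if column == "braak_stage" and v in _ROMAN_BRAAK:
                v = _ROMAN_BRAAK[v]
            else:
                try:
                    v = int(v)
                except ValueError:
                    raise DataError(
                        f"{column} value {v!r} in row {i} is not a valid stage"
                    ) from None
        if not low <= int(v) <= high:
            raise DataError(f"{column} value {v!r} in row {i} outside range {low}..{high}")


def load_cohort_tables(directory: str | Path) -> Cohort:
    """Load and validate cohort tables from a fixture directory.

    Checks the long-format schema, stage ranges (Braak 0-VI, Thal 0-5,
    neuritic plaque score 0-3, ADNC 0-3), region names against the config's
    region list, and subject x region uniqueness.
    """
    try:
        cohort = load_fixture_set(directory)
    except FileNotFoundError as exc:
        raise DataError(f"missing input file: {exc}") from exc
    except SchemaError as exc:
        raise DataError(str(exc)) from exc
    subj = cohort.subjects
    _validate_stage_column(subj, "braak_stage", 0, 6)
    _validate_stage_column(subj, "thal_phase", 0, 5)
    _validate_stage_column(subj, "plaque_score", 0, 3)
    _validate_stage_column(subj, "adnc", 0, 3)
    if subj["braak_stage"].dtype == object:
        cohort.subjects["braak_stage"] = (
            subj["braak_stage"].map(lambda v: _ROMAN_BRAAK.get(str(v), v)).astype(int)
        )
    known = set(cohort.config.region_list)
    unknown = set(cohort.regional["region"]) - known
    if unknown:
        raise DataError(f"unknown region name(s): {sorted(unknown)}")
    dup = cohort.regional.duplicated(subset=["subject_id", "region"])
    if dup.any():
        rows = cohort.regional.loc[dup, ["subject_id", "region"]].head(5)
        raise DataError(f"duplicated subject x region rows, e.g.\n{rows}")
    return cohort


def _composite_pathology(pathology: pd.DataFrame, members: tuple[str, ...]) -> pd.Series:
    wide = pathology.pivot_table(index="subject_id", columns="region", values="pct_at8")
    missing = [m for m in members if m not in wide.columns]
    if missing:
        raise DataError(f"pathology table missing meta-ROI member(s): {missing}")
    return wide[list(members)].mean(axis=1)


def _corr_row(name: str, r) -> dict:
    return {"analysis": name, "rho": r.rho, "p_value": r.p_value, "n": r.n}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every enabled stage; identical config + seed gives identical
    outputs. Returns the in-memory report after writing CSV/JSON artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {}

    # --- simulate / load ---------------------------------------------------
    if config.simulate:
        cohort = generate_cohort(config.cohort)
        log.info("simulated cohort: %d subjects x %d regions",
                 len(cohort.subjects), len(config.cohort.region_list))
        if config.write_fixtures:
            write_fixture_set(cohort, outdir / "fixtures", images=False)
    else:
        cohort = load_cohort_tables(config.input_dir)
        log.info("loaded cohort from %s (%d regional rows)",
                 config.input_dir, len(cohort.regional))

    regional = cohort.regional.copy()
    subjects = cohort.subjects.copy()

    # --- quantify ----------------------------------------------------------
    # pathology per subject x region: measured from images where the
    # quantification stage ran, otherwise the generated burden itself
    pathology = regional[["subject_id", "region", "burden_pct"]].rename(
        columns={"burden_pct": "pct_at8"}
    )
    pathology["method"] = "generator"
    if config.quantify:
        subj_ids = list(subjects["subject_id"])
        if config.quantify_max_subjects:
            subj_ids = subj_ids[: config.quantify_max_subjects]
        methods = (
            ["threshold", "graphcut"]
            if config.quantify_method == "both"
            else [config.quantify_method]
        )
        measured_frames = []
        fields = list(
            cohort.iter_histology_fields(
                subjects=subj_ids,
                regions=config.quantify_regions,
                image_size=config.quantify_image_size,
            )
        )
        for method in methods:
            per_image, per_region = quantify_cohort_fields(
                fields, method=method, graphcut_params=GraphCutParams()
            )
            tables[f"quantification_{method}"] = per_image
            measured_frames.append(per_region)
        measured = measured_frames[0][["subject_id", "region", "pct_at8"]].copy()
        measured["method"] = methods[0]
        key = pathology.set_index(["subject_id", "region"])
        upd = measured.set_index(["subject_id", "region"])
        key.loc[upd.index, ["pct_at8", "method"]] = upd[["pct_at8", "method"]]
        pathology = key.reset_index()
        log.info("quantified %d fields with method(s) %s", len(fields), methods)

    # --- petcalc -----------------------------------------------------------
    regional["suvr_check"] = compute_suvr(regional["roi_mean"], regional["ref_mean"])
    temporal_def = load_meta_roi("temporal")
    cortical_def = load_meta_roi("cortical")
    temporal_def = dataclasses.replace(temporal_def, cutoff=config.cutoff_temporal)
    cortical_def = dataclasses.replace(cortical_def, cutoff=config.cutoff_cortical)
    meta = meta_roi_table(regional, [temporal_def, cortical_def], suvr_col="suvr_check")
    meta["temporal_path_pct"] = _composite_pathology(pathology, temporal_def.members).values
    meta["cortical_path_pct"] = _composite_pathology(pathology, cortical_def.members).values
    meta = meta.merge(subjects, on="subject_id")
    tables["meta_roi"] = meta

    merged = regional.merge(pathology, on=["subject_id", "region"]).merge(
        subjects, on="subject_id"
    )
    tables["regional"] = merged

    # --- analyses ----------------------------------------------------------
    if "correlations" in config.analyses:
        rows = []
        on_target = merged[merged["region_class"] == "on_target"]
        for region, g in on_target.groupby("region"):
            r = spearman_corr(g["pct_at8"], g["suvr"])
            rows.append({"analysis": f"region:{region}", **vars(r)})
        rows.append(
            {"analysis": "meta:temporal",
             **vars(spearman_corr(meta["temporal_path_pct"], meta["temporal_suvr"]))}
        )
        rows.append(
            {"analysis": "meta:cortical",
             **vars(spearman_corr(meta["cortical_path_pct"], meta["cortical_suvr"]))}
        )
        tables["correlations"] = pd.DataFrame(rows)

    thresholds: dict[str, float] = {}
    if "thresholds" in config.analyses or "concordance" in config.analyses:
        rows = []
        for name in ("temporal", "cortical"):
            res = youden_detection_threshold(
                meta[f"{name}_path_pct"], meta[f"{name}_positive"]
            )
            thresholds[name] = res.pathology_threshold_pct
            rows.append({"meta_roi": name, **vars(res)})
        tables["detection_thresholds"] = pd.DataFrame(rows)
        summary["detection_thresholds"] = thresholds

    if "concordance" in config.analyses:
        rows = []
        for name in ("temporal", "cortical"):
            path_pos = meta[f"{name}_path_pct"] >= thresholds[name]
            res = concordance_accuracy(path_pos, meta[f"{name}_positive"])
            rows.append({"meta_roi": name, "n": res.n, **vars(res)})
        tables["concordance"] = pd.DataFrame(rows)

    if "linearity" in config.analyses:
        rows = []
        staged = meta[meta["braak_stage"] >= 1]
        if len(staged) > config.degree + 1 and staged["braak_stage"].nunique() > 1:
            res = linear_vs_polynomial(
                staged["braak_stage"], staged["temporal_suvr"], config.degree
            )
            rows.append({"coding": "braak", **vars(res)})
        sext = assign_sextiles(meta["temporal_path_pct"].to_numpy())
        res = linear_vs_polynomial(sext, meta["temporal_suvr"], config.degree)
        rows.append({"coding": "sextile", **vars(res)})
        tables["linearity"] = pd.DataFrame(rows)

    if "glm" in config.analyses:
        frames = []
        for name in ("temporal", "cortical"):
            predictors = pd.DataFrame(
                {
                    "tau_pct": meta[f"{name}_path_pct"],
                    "age": meta["age"],
                    "sex_male": meta["sex_male"],
                    "interval_months": meta["pm_interval_months"],
                }
            )
            res = fit_gamma_glm(meta[f"{name}_suvr"], predictors, link=config.glm_link)
            t = res.table.reset_index(names="predictor")
            t.insert(0, "meta_roi", name)
            frames.append(t)
        tables["glm"] = pd.concat(frames, ignore_index=True)

    if "subgroups" in config.analyses:
        rows = []
        part = [
            classify_part(t, b).category
            for t, b in zip(meta["thal_phase"], meta["braak_stage"])
        ]
        meta["part_category"] = part

        def _try(name: str, fn) -> None:
            try:
                res = fn()
            except (EmptySubsetError, ValueError) as exc:
                rows.append({"analysis": name, "note": str(exc)})
                return
            if isinstance(res, dict):
                for key, r in res.items():
                    rows.append({"analysis": f"{name}:{key}", **vars(r)})
            else:
                rows.append({"analysis": name, **vars(res)})

        _try(
            "braak_I_IV",
            lambda: spearman_corr(
                meta.query("1 <= braak_stage <= 4")["temporal_path_pct"],
                meta.query("1 <= braak_stage <= 4")["temporal_suvr"],
            ),
        )
        _try(
            "part",
            lambda: spearman_corr(
                meta.query("part_category != 'none'")["temporal_path_pct"],
                meta.query("part_category != 'none'")["temporal_suvr"],
            ),
        )
        for region in OFF_TARGET_REGIONS:
            _try(
                f"off_target:{region}",
                lambda region=region: subgroup_spearman(
                    merged, "pct_at8", "suvr", query=f"region == '{region}'"
                )["all"],
            )
        _try(
            "plaque_vs_suvr",
            lambda: spearman_corr(meta["plaque_score"], meta["temporal_suvr"]),
        )
        _try(
            "tdp_vs_suvr",
            lambda: spearman_corr(meta["tdp_stage"], meta["temporal_suvr"]),
        )
        tables["subgroups"] = pd.DataFrame(rows)

    # --- report ------------------------------------------------------------
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": int(len(subjects)),
        "n_regions": int(regional["region"].nunique()),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, lineterminator="\n")
    report = {"provenance": provenance, "summary": summary,
              "tables": sorted(tables)}
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")

    if config.figures and "thresholds" in config.analyses:
        _write_figures(meta, thresholds, config, outdir)

    return RunReport(provenance=provenance, tables=tables, summary=summary, output_dir=outdir)


def _write_figures(meta: pd.DataFrame, thresholds: dict, config: RunConfig, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, name, cutoff in (
        (axes[0], "temporal", config.cutoff_temporal),
        (axes[1], "cortical", config.cutoff_cortical),
    ):
        ax.scatter(
            meta[f"{name}_suvr"], meta[f"{name}_path_pct"],
            c=meta["braak_stage"], cmap="viridis", s=18
        )
        ax.axvline(cutoff, ls="--", c="k", lw=0.8)
        if name in thresholds:
            ax.axhline(thresholds[name], ls="--", c="k", lw=0.8)
        ax.set_xlabel(f"{name} meta-ROI SUVR")
        ax.set_ylabel("% AT8-positive area")
        ax.set_title(f"{name} composite")
    fig.tight_layout()
    fig.savefig(outdir / "meta_roi_scatter.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    staged = meta[meta["braak_stage"] >= 1]
    axes[0].scatter(staged["braak_stage"], staged["temporal_suvr"], s=18)
    axes[0].set_xlabel("Braak stage")
    sext = assign_sextiles(meta["temporal_path_pct"].to_numpy())
    axes[1].scatter(sext, meta["temporal_suvr"], s=18)
    axes[1].set_xlabel("pathology sextile")
    for ax in axes:
        ax.axhline(config.cutoff_temporal, ls="--", c="k", lw=0.8)
        ax.set_ylabel("temporal meta-ROI SUVR")
    fig.tight_layout()
    fig.savefig(outdir / "stage_sextile.png", dpi=120)
    plt.close(fig)
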