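"""End-to-end orchestration: cohort in, report bundle out.

``run_pipeline`` chains the stages in analysis order — follow-up
selection, complete-injury exclusion, ceiling filter, correlation screen
and regression battery, subgroup discovery (PCA / Ward / elbow / ROC) and
the stratified reanalysis below the discovered cut-point — and returns a
bundle whose every number is a stage output (the renderer never
recomputes).  The bundle also carries a provenance block (config hash,
package/library versions, seed) and, when an output directory is given,
is written out as CSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import discover_subgroups, stratified_reanalysis
from .filters import CEILING, ceiling_filter, exclude_complete_injury, select_followup
from .regression import ALPHA, LIMB_COLUMNS, limb_battery
from .synthetic import CohortSpec, make_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cst_recovery")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    limb: str = "UE"
    injury_threshold: float = 0.05
    n_subsections: int = 16
    ceiling_ue: int = CEILING["UE"]
    ceiling_le: int = CEILING["LE"]
    followup_target_days: int = 60
    alpha: float = ALPHA
    k_max: int = 8
    seed: int = 0
    n_patients: int = 67
    cohort_csv: str | None = None
    assessments_csv: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.limb not in ("UE", "LE"):
            raise ValueError("limb must be 'UE' or 'LE'")
        if not 0 < self.injury_threshold <= 1:
            raise ValueError("injury_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.ceiling_ue <= 66 or not 0 <= self.ceiling_le <= 34:
            raise ValueError("ceiling cuts outside the FMA score ranges")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _demographics(cohort: pd.DataFrame) -> dict:
    return {
        "n": len(cohort),
        "sex_male": int((cohort["sex"] == "M").sum()),
        "sex_female": int((cohort["sex"] == "F").sum()),
        "age_mean": float(cohort["age"].mean()),
        "age_sd": float(cohort["age"].std(ddof=1)),
        "location_cortical": int((cohort["lesion_location"] == "cortical").sum()),
        "location_subcortical": int((cohort["lesion_location"] == "subcortical").sum()),
        "side_right": int((cohort["lesion_side"] == "right").sum()),
        "side_left": int((cohort["lesion_side"] == "left").sum()),
        "followup_day_mean": float(cohort["followup_day"].mean()),
        "cst_injury_mean": float(cohort["cst_injury"].mean()),
    }


def _report_to_jsonable(report) -> dict | None:
    if report is None:
        return None
    return {
        "predictors": list(report.predictors),
        "beta": report.beta,
        "p_values": report.p_values,
        "partial": report.partial,
        "part": report.part,
        "unique_contribution": report.unique_contribution,
        "r2": report.r2,
        "adj_r2": report.adj_r2,
        "n": report.n,
    }


def _battery_to_jsonable(battery: dict) -> dict:
    out = {
        "limb": battery["limb"],
        "n": battery["n"],
        "screen": battery["screen"].table.to_dict(orient="records"),
        "simple_injury": _report_to_jsonable(battery["simple_injury"]),
        "multiple": _report_to_jsonable(battery["multiple"]),
    }
    col = battery["collinearity"]
    if col is not None:
        out["collinearity"] = {"r": col.r, "p": col.p, "verdict": col.verdict}
    else:
        out["collinearity"] = None
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report bundle.

    With no cohort CSV configured, a synthetic cohort with the default
    study structure is generated from ``config.seed``.  Deterministic given
    config + seed.
    """
    t0 = time.perf_counter()
    stage = "load_cohort"
    try:
        if config.cohort_csv is not None:
            patients = pd.read_csv(config.cohort_csv)
            assessments = (
                pd.read_csv(config.assessments_csv) if config.assessments_csv else None
            )
        else:
            cohort = make_cohort(
                CohortSpec(n_patients=config.n_patients, seed=config.seed)
            )
            patients, assessments = cohort.patients, cohort.assessments
        log.info("stage %s: %d patients (%.2fs)", stage, len(patients), time.perf_counter() - t0)

        audits = []
        stage = "followup_selection"
        if assessments is not None:
            selected, audit = select_followup(
                assessments, target_days=config.followup_target_days
            )
            audits.append(audit)
            keep_cols = [c for c in patients.columns if c not in selected.columns or c == "patient_id"]
            patients = patients[keep_cols].merge(selected, on="patient_id", how="inner")

        stage = "complete_injury_filter"
        patients, audit = exclude_complete_injury(patients)
        audits.append(audit)

        stage = "ceiling_filter"
        ceiling = config.ceiling_ue if config.limb == "UE" else config.ceiling_le
        analysis_cohort, audit = ceiling_filter(patients, config.limb, ceiling=ceiling)
        audits.append(audit)
        log.info("stage %s: %d patients in %s analysis", stage, len(analysis_cohort), config.limb)

        stage = "regression_battery"
        battery = limb_battery(analysis_cohort, config.limb, alpha=config.alpha)

        stage = "subgroup_discovery"
        init_col, follow_col = LIMB_COLUMNS[config.limb]
        subgroups = discover_subgroups(
            analysis_cohort[init_col].to_numpy(float),
            analysis_cohort[follow_col].to_numpy(float),
            k_max=config.k_max,
        )

        stage = "stratified_reanalysis"
        strata = stratified_reanalysis(
            analysis_cohort, subgroups.cutpoint.threshold, config.limb, alpha=config.alpha
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    labels_df = pd.DataFrame(
        {
            "patient_id": analysis_cohort["patient_id"],
            "cluster": subgroups.solution.labels,
            "high_cluster": subgroups.solution.labels == subgroups.high_cluster_label,
        }
    )
    bundle = {
        "config": dataclasses.asdict(config),
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        },
        "audits": [a.to_dict() for a in audits],
        "demographics": _demographics(analysis_cohort),
        "battery_full": _battery_to_jsonable(strata["full"]),
        "battery_severe": _battery_to_jsonable(strata["severe"]),
        "cluster": {
            "chosen_k": subgroups.solution.chosen_k,
            "wss": subgroups.solution.wss[: config.k_max].tolist(),
            "explained_shares": subgroups.pca.explained_shares.tolist(),
            "high_cluster_label": subgroups.high_cluster_label,
            "cutpoint": subgroups.cutpoint.threshold,
            "youden_j": subgroups.cutpoint.youden_j,
            "n_severe": strata["n_severe"],
            "n_high": strata["n_high"],
        },
    }

    if config.output_dir is not None:
        stage = "write_outputs"
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        analysis_cohort.to_csv(out / "analysis_cohort.csv", index=False)
        labels_df.to_csv(out / "cluster_labels.csv", index=False)
        subgroups.cutpoint.table.to_csv(out / "roc_table.csv", index=False)
        pd.DataFrame({"k": np.arange(1, config.k_max + 1),
                      "wss": subgroups.solution.wss[: config.k_max]}).to_csv(
            out / "wss_profile.csv", index=False
        )
        battery["screen"].table.to_csv(out / "correlation_screen.csv", index=False)
        if strata["severe"]["multiple"] is not None:
            strata["severe"]["multiple"].to_frame().to_csv(
                out / "multiple_regression_severe.csv", index=False
            )
        (out / "report.json").write_text(json.dumps(bundle, indent=2, default=str))
        log.info("outputs written to %s", out)

    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return bundle
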