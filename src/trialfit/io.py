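"""Readers, writers, configuration files and radar-figure data export.

CSV dialect: comma-separated, UTF-8, header row required; missing cell =
empty string or any missing-policy designation.  Percentages are
serialized at full precision; round only for human-readable display.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .demographics import Feature, MissingPolicy, PatientRecord
from .errors import ConfigError, EmptyCohortError, SchemaError
from .metrics import SuitabilityResult, WeightConfig
from .simulation import CohortSamplingConfig, PopulationSpec
from .validation import ScenarioResult

logger = logging.getLogger("trialfit")

DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "age": "age",
    "gender": "gender",
    "ethnicity": "ethnicity",
    "weight": "weight",
    "language": "language",
    "religion": "religion",
    "marital_status": "marital_status",
}


def read_demographics_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[PatientRecord]:
    """Read a one-row-per-patient demographics CSV into PatientRecords.

    ``column_map`` maps canonical field names to the file's column names.
    Unparseable numeric cells become missing values; a warning with the
    count is logged.  A missing required column raises :class:`SchemaError`.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise EmptyCohortError(f"{path}: file is empty") from exc
    if df.empty:
        raise EmptyCohortError(f"{path}: no data rows")
    for canonical, name in cols.items():
        if name not in df.columns:
            raise SchemaError(f"{path}: required column {name!r} ({canonical}) not found")

    bad_numeric = 0

    def _num(cell: str) -> float | None:
        nonlocal bad_numeric
        cell = cell.strip()
        if cell == "":
            return None
        try:
            return float(cell)
        except ValueError:
            bad_numeric += 1
            return None

    def _txt(cell: str) -> str | None:
        return cell if cell.strip() else None

    records = [
        PatientRecord(
            patient_id=row[cols["patient_id"]].strip(),
            age=_num(row[cols["age"]]),
            gender=_txt(row[cols["gender"]]),
            ethnicity=_txt(row[cols["ethnicity"]]),
            weight=_num(row[cols["weight"]]),
            language=_txt(row[cols["language"]]),
            religion=_txt(row[cols["religion"]]),
            marital_status=_txt(row[cols["marital_status"]]),
        )
        for _, row in df.iterrows()
    ]
    if bad_numeric:
        logger.warning("%s: %d unparseable numeric cell(s) treated as missing", path, bad_numeric)
    return records


def write_demographics_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write PatientRecords in the same CSV dialect the reader accepts."""
    rows = [
        {
            "patient_id": r.patient_id,
            "age": "" if r.age is None else r.age,
            "gender": r.gender or "",
            "ethnicity": r.ethnicity or "",
            "weight": "" if r.weight is None else r.weight,
            "language": r.language or "",
            "religion": r.religion or "",
            "marital_status": r.marital_status or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------- configs


def load_weight_config(path: str | Path) -> WeightConfig:
    """Load a WeightConfig from YAML/JSON.

    Keys: ``feature_weights`` (feature name -> weight), ``coverage_weight``,
    ``completeness_weight``, ``epsilon``, ``log_base``; absent keys take the
    defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "feature_weights" in raw:
        try:
            kwargs["feature_weights"] = {Feature(k): float(v) for k, v in raw["feature_weights"].items()}
        except ValueError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    for key in ("coverage_weight", "completeness_weight", "epsilon", "log_base"):
        if key in raw:
            kwargs[key] = float(raw[key])
    return WeightConfig(**kwargs)


def load_population_spec(path: str | Path) -> PopulationSpec:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("age_mixture", "weight_mixture"):
        if key in raw:
            raw[key] = tuple(tuple(float(x) for x in comp) for comp in raw[key])
    for key in ("age_range", "weight_range"):
        if key in raw:
            raw[key] = tuple(float(x) for x in raw[key])
    return PopulationSpec(**raw)


def load_sampling_config(path: str | Path) -> CohortSamplingConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return CohortSamplingConfig(**raw)


def load_scenarios(path: str | Path) -> dict[str, WeightConfig]:
    """Load named weight scenarios from a YAML mapping scenario -> config."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, WeightConfig] = {}
    for name, cfg in raw.items():
        kwargs = {}
        if "feature_weights" in cfg:
            kwargs["feature_weights"] = {Feature(k): float(v) for k, v in cfg["feature_weights"].items()}
        for key in ("coverage_weight", "completeness_weight", "epsilon", "log_base"):
            if key in cfg:
                kwargs[key] = float(cfg[key])
        out[str(name)] = WeightConfig(**kwargs)
    return out


# ---------------------------------------------------------------- results


def results_to_frame(results: Sequence[SuitabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def write_results(results: Sequence[SuitabilityResult], out_dir: str | Path) -> None:
    """Write per-cohort scores as CSV and JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = results_to_frame(results)
    frame.to_csv(out / "cohort_scores.csv", index=False)
    with open(out / "cohort_scores.json", "w", encoding="utf-8") as fh:
        json.dump(frame.to_dict(orient="records"), fh, indent=2)


def export_radar_data(
    results: Sequence[SuitabilityResult],
    target_completeness: Mapping[Feature, float],
    weights: WeightConfig | None = None,
) -> pd.DataFrame:
    """Long-format per-feature profile table for radar plots.

    One row per (entity, feature, metric) with metrics coverage,
    completeness and suitability.  The target's coverage is 100 for every
    feature by definition (it is compared with itself); its per-feature
    suitability combines that boundary with its own completeness.
    """
    if len(results) == 0:
        raise EmptyCohortError("no results to export")
    if weights is None:
        weights = WeightConfig()
    rows = []
    for f in Feature:
        tc = float(target_completeness.get(f, 100.0))
        rows.append({"entity": "target", "feature": f.value, "metric": "coverage", "value": 100.0})
        rows.append({"entity": "target", "feature": f.value, "metric": "completeness", "value": tc})
        rows.append(
            {
                "entity": "target",
                "feature": f.value,
                "metric": "suitability",
                "value": weights.coverage_weight * 100.0 + weights.completeness_weight * tc,
            }
        )
    for r in results:
        for f in Feature:
            cov = r.feature_coverage.get(f)
            comp = r.feature_completeness.get(f)
            rows.append({"entity": r.cohort_id, "feature": f.value, "metric": "coverage", "value": cov})
            rows.append(
                {"entity": r.cohort_id, "feature": f.value, "metric": "completeness", "value": comp}
            )
            suit = (
                None
                if cov is None or comp is None
                else weights.coverage_weight * cov + weights.completeness_weight * comp
            )
            rows.append({"entity": r.cohort_id, "feature": f.value, "metric": "suitability", "value": suit})
    return pd.DataFrame(rows, columns=["entity", "feature", "metric", "value"])


def plot_radar(
    radar_data: pd.DataFrame, metric: str, path: str | Path, title: str | None = None
) -> None:
    """Render one radar plot (optional; the data export is the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    sub = radar_data[radar_data["metric"] == metric]
    features = [f.value for f in Feature]
    angles = np.linspace(0, 2 * np.pi, len(features), endpoint=False).tolist()
    angles += angles[:1]
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(6, 6))
    for entity, grp in sub.groupby("entity", sort=False):
        vals = grp.set_index("feature")["value"].reindex(features).tolist()
        vals += vals[:1]
        ax.plot(angles, vals, label=entity)
        ax.fill(angles, vals, alpha=0.08)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(features, fontsize=7)
    ax.set_ylim(0, 100)
    ax.set_title(title or metric)
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def scenario_table_csv(scenario_results: Sequence[ScenarioResult], path: str | Path) -> None:
    from .validation import robustness_table

    robustness_table(scenario_results).to_csv(path, index=False)


def write_manifest(out_dir: str | Path, config: Mapping, seed: int | None) -> Path:
    """Write a run manifest: config echo, its hash, seed and versions."""
    import trialfit

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "trialfit": trialfit.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out / "run_manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path
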