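"""Readers/writers for matrices, manifests and run configurations, and the
end-to-end pipeline driver.

Matrix files are delimited text (tab or comma, auto-detected on read): the
first row and first column carry the 84 atlas labels in canonical order and
values are printed with full float precision so a write/read round trip is
exact.  A cohort manifest is a tab-separated table with columns
``subject_id``, ``group``, ``dominant_side`` and one column per metric
holding the matrix file path (relative to the manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import connectocam

from .atlas import N_NODES, NodeAtlas, default_atlas
from .cohort import CohortDataset, SubjectRecord, weight_cohort
from .core import ConnectomeMatrix
from .errors import ConfigurationError, DataError, ValidationError
from .evaluation import (CVConfig, PooledResult, bonferroni_threshold,
                         delong_paired_test, run_cross_validation)
from .gradcam import attribute_cohort, rank_connections
from .network import ArchitectureSpec, TrainConfig
from .seeds import derive_seed
from .synthetic import CohortConfig, EffectSpec, generate_cohort

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Matrix files
# ---------------------------------------------------------------------------

def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path, atlas: NodeAtlas | None = None, subject_id: str = "",
                metric: str = "") -> ConnectomeMatrix:
    """Parse a labeled 84x84 delimited-text matrix (comma or tab)."""
    atlas = atlas or default_atlas()
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty matrix file")
    delim = _detect_delimiter(lines[0])
    header = lines[0].split(delim)[1:]
    if len(header) != N_NODES:
        raise ValidationError(
            f"{path}: expected {N_NODES} column labels, found {len(header)}")
    if tuple(header) != atlas.labels:
        bad = next(h for h, lab in zip(header, atlas.labels) if h != lab)
        raise ValidationError(f"{path}: column label {bad!r} not in canonical atlas order")
    if len(lines) - 1 != N_NODES:
        raise ValidationError(f"{path}: expected {N_NODES} rows, found {len(lines) - 1}")
    values = np.empty((N_NODES, N_NODES))
    for r, line in enumerate(lines[1:]):
        parts = line.split(delim)
        if parts[0] != atlas.labels[r]:
            raise ValidationError(
                f"{path}: row {r + 2} label {parts[0]!r} does not match atlas "
                f"({atlas.labels[r]!r})")
        if len(parts) - 1 != N_NODES:
            raise ValidationError(f"{path}: row {r + 2} has {len(parts) - 1} values")
        for c, token in enumerate(parts[1:]):
            try:
                values[r, c] = float(token)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {r + 2}, column {c + 2}: "
                    f"{token!r}") from None
    return ConnectomeMatrix(subject_id or path.stem, metric, values)


def write_matrix(m: ConnectomeMatrix, path, atlas: NodeAtlas | None = None,
                 delimiter: str = "\t") -> None:
    atlas = atlas or default_atlas()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(delimiter.join(("",) + atlas.labels) + "\n")
        for r in range(N_NODES):
            row = delimiter.join([atlas.labels[r]]
                                 + [FLOAT_FMT % v for v in m.values[r]])
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Manifests and cohorts on disk
# ---------------------------------------------------------------------------

_MANIFEST_FIXED = ("subject_id", "group", "dominant_side")


def write_cohort(dataset: CohortDataset, outdir, delimiter: str = "\t") -> Path:
    """Write every matrix and a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.subjects:
        row = {"subject_id": rec.subject_id, "group": rec.group,
               "dominant_side": rec.dominant_side}
        for metric, per_subject in dataset.matrices.items():
            fname = f"{rec.subject_id}_{metric}.tsv"
            write_matrix(per_subject[rec.subject_id], outdir / fname,
                         dataset.atlas, delimiter)
            row[metric] = fname
        rows.append(row)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path, metrics: list[str] | None = None,
                atlas: NodeAtlas | None = None) -> CohortDataset:
    """Build a cohort from a manifest, reading the referenced matrix files."""
    atlas = atlas or default_atlas()
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = set(_MANIFEST_FIXED) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest lacks columns: {sorted(missing)}")
    metric_cols = [c for c in df.columns if c not in _MANIFEST_FIXED]
    if metrics is not None:
        absent = set(metrics) - set(metric_cols)
        if absent:
            raise ConfigurationError(
                f"manifest has no matrix column for metrics {sorted(absent)}")
        metric_cols = list(metrics)
    subjects = [SubjectRecord(r.subject_id, r.group, r.dominant_side)
                for r in df.itertuples()]
    matrices: dict[str, dict[str, ConnectomeMatrix]] = {}
    base = manifest_path.parent
    for metric in metric_cols:
        matrices[metric] = {}
        for r in df.itertuples():
            fpath = base / getattr(r, metric)
            if not fpath.exists():
                raise DataError(f"matrix file not found: {fpath}")
            matrices[metric][r.subject_id] = read_matrix(
                fpath, atlas, r.subject_id, metric)
    return CohortDataset(subjects, matrices, atlas)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributionConfig:
    top_k: int = 30
    subgroup: str = "all"
    mode: str = "mean"


@dataclass
class RunConfig:
    """Nested configuration of a full pipeline run.

    Exactly one of ``cohort`` (simulate) or ``manifest`` (load from disk)
    must be provided.  Defaults everywhere are the reference-faithful values.
    """

    seed: int = 0
    outdir: str = "connectocam_run"
    metrics: list[str] = field(default_factory=lambda: ["NOS"])
    cohort: CohortConfig | None = None
    manifest: str | None = None
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    cross_validation: CVConfig = field(default_factory=CVConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        import copy

        raw = copy.deepcopy(raw)

        def build(klass, section, **extra):
            data = raw.pop(section, None)
            if data is None:
                return None if section in ("cohort", "manifest") else klass()
            if not isinstance(data, dict):
                raise ConfigurationError(f"section {section!r} must be a mapping")
            data = {**data, **extra}
            known = set(klass.__dataclass_fields__)
            unknown = set(data) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in {section!r}: {sorted(unknown)}")
            for key in ("conv_channels", "fc_units", "noise_sds", "param_metrics"):
                if key in data and isinstance(data[key], list):
                    data[key] = tuple(data[key])
            return klass(**data)

        cohort_raw = raw.get("cohort")
        if cohort_raw is not None and "effects" in cohort_raw:
            effects = []
            for eff in cohort_raw["effects"]:
                eff = dict(eff)
                if "edges" in eff:
                    eff["edges"] = tuple(tuple(e) for e in eff["edges"])
                effects.append(EffectSpec(**eff))
            cohort_raw["effects"] = tuple(effects)

        cfg = cls(
            seed=int(raw.pop("seed", 0)),
            outdir=str(raw.pop("outdir", "connectocam_run")),
            metrics=list(raw.pop("metrics", ["NOS"])),
            cohort=build(CohortConfig, "cohort"),
            manifest=raw.pop("manifest", None),
            architecture=build(ArchitectureSpec, "architecture"),
            training=build(TrainConfig, "training"),
            cross_validation=build(CVConfig, "cross_validation"),
            attribution=build(AttributionConfig, "attribution"),
        )
        if raw:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(raw)}")
        if cfg.cohort is None and cfg.manifest is None:
            raise ConfigurationError("config must provide either 'cohort' or 'manifest'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _result_payload(metric: str, result: PooledResult) -> dict:
    return {
        "metric": metric,
        "per_fold_auc": result.per_fold_auc,
        "pooled_auc": result.pooled_auc,
        "pooled_auc_ci95": list(result.pooled_ci),
        "sensitivity": result.confusion.sensitivity,
        "specificity": result.confusion.specificity,
        "accuracy": result.confusion.accuracy,
        "confusion_percents": result.confusion.percents(),
        "confusion_counts": {"tp": result.confusion.tp, "fn": result.confusion.fn,
                             "tn": result.confusion.tn, "fp": result.confusion.fp},
        "per_subject": [
            {"subject_id": sid, "group": grp, "patient_score": score}
            for sid, grp, score in result.per_subject
        ],
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate (optional) -> weight -> cross-validate -> evaluate -> Grad-CAM.

    Writes all artifacts under ``cfg.outdir`` and returns the results bundle
    (per-metric cross-validation payloads, pairwise DeLong matrix, ranked
    connections).  Identical config and seed reproduce identical files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if cfg.cohort is not None:
            stage = "simulate"
            cohort_cfg = cfg.cohort
            if cohort_cfg.seed == 0 and cfg.seed != 0:
                from dataclasses import replace as _replace
                cohort_cfg = _replace(cohort_cfg, seed=derive_seed(cfg.seed, "cohort"))
            dataset = generate_cohort(cohort_cfg)
            write_cohort(dataset, outdir / "cohort")
        else:
            stage = "load"
            dataset = load_cohort(cfg.manifest)

        stage = "weight"
        need_weighting = [m for m in cfg.metrics if m not in dataset.matrices]
        if need_weighting:
            dataset = weight_cohort(dataset, need_weighting)

        results: dict[str, PooledResult] = {}
        payloads = {}
        for metric in cfg.metrics:
            stage = f"cross-validate[{metric}]"
            from dataclasses import replace as _replace
            cv_cfg = _replace(cfg.cross_validation,
                              seed=derive_seed(cfg.seed, "cv", metric))
            results[metric] = run_cross_validation(
                dataset, metric, cfg.architecture, cfg.training, cv_cfg)
            payloads[metric] = _result_payload(metric, results[metric])

        stage = "compare"
        comparisons = []
        labels = dataset.labels()
        metric_list = list(cfg.metrics)
        n_pairs = len(metric_list) * (len(metric_list) - 1) // 2
        for i in range(len(metric_list)):
            for j in range(i + 1, len(metric_list)):
                a, b = metric_list[i], metric_list[j]
                sa, _ = results[a].scores_and_labels()
                sb, _ = results[b].scores_and_labels()
                res = delong_paired_test(sa, sb, labels)
                comparisons.append({"metric_a": a, "metric_b": b,
                                    "auc_a": res.auc_a, "auc_b": res.auc_b,
                                    "difference": res.difference,
                                    "p_value": res.p_value})
        compare_payload = {
            "comparisons": comparisons,
            "corrected_alpha": bonferroni_threshold(0.05, n_pairs) if n_pairs else None,
        }

        stage = "gradcam"
        attribution_payload = {}
        for metric in cfg.metrics:
            try:
                pooled, _ = attribute_cohort(dataset, metric, results[metric],
                                             subgroup=cfg.attribution.subgroup,
                                             mode=cfg.attribution.mode)
            except DataError:
                attribution_payload[metric] = {"error": "no correctly classified patients"}
                continue
            gc_dir = outdir / "gradcam"
            gc_dir.mkdir(exist_ok=True)
            pooled_m = ConnectomeMatrix("pooled", metric, pooled.matrix)
            write_matrix(pooled_m, gc_dir / f"{metric}_pooled_attribution.tsv",
                         dataset.atlas)
            ranked = rank_connections(pooled, dataset.atlas, cfg.attribution.top_k)
            pd.DataFrame(
                [(r + 1, a, b, v) for r, (a, b, v) in enumerate(ranked.entries)],
                columns=["rank", "region_a", "region_b", "heat"],
            ).to_csv(gc_dir / f"{metric}_top{cfg.attribution.top_k}.tsv",
                     sep="\t", index=False)
            attribution_payload[metric] = {
                "n_subjects_pooled": pooled.n_subjects_pooled,
                "top_connections": ranked.entries[:cfg.attribution.top_k],
            }

        stage = "report"
        bundle = {"metrics": payloads, "pairwise": compare_payload,
                  "attribution": attribution_payload}
        (outdir / "results.json").write_text(
            json.dumps(bundle, indent=2, default=_jsonable), encoding="utf-8")
        cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=_jsonable)
        run_log = {
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "package_version": connectocam.__version__,
            "numpy_version": np.__version__,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2),
                                             encoding="utf-8")
        return bundle
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
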