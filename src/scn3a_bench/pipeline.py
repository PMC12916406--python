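"""End-to-end pipeline: curation → enrichment → benchmark → calibration.

``run_pipeline`` reads the curated tables, the score matrix, the topology
table and the tool registry, and writes five machine-readable reports plus
a provenance block. Every file is written atomically (temp file + rename);
a stage failure leaves a FAILED marker next to the partial outputs. Reruns
with identical inputs and config produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset import CuratedDataset, load_dataset, summarize_cohort
from .enrichment import EnrichmentError, TabulationInput, build_contingency, fisher_exact
from .metrics import confusion, metrics, rank_tools
from .predictions import coverage_report, load_scores
from .registry import default_registry, load_registry, oriented
from .roc import MIDPOINT, evaluate_all_tools
from .score_statistics import AUTO, compare_scores
from .topology import TRANSMEMBRANE, assign_region, load_default_topology, load_topology

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    patients: Path | None = None
    variants: Path | None = None
    scores: Path | None = None
    topology: Path | None = None
    registry: Path | None = None
    alpha: float = 0.05
    ci_level: float = 0.95
    threshold_convention: str = MIDPOINT
    comparison_policy: str = AUTO
    unit_for_phenotype: str = "patients"
    output_dir: Path = Path("scn3a_bench_out")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("patients", "variants", "scores", "topology", "registry"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.output_dir = Path(self.output_dir)
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise PipelineError("alpha and ci_level must lie in (0, 1)")
        if self.unit_for_phenotype not in ("patients", "variants"):
            raise PipelineError("unit_for_phenotype must be patients|variants")

    def validate_paths(self) -> None:
        for name in ("patients", "variants", "scores", "topology", "registry"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"{name} file not found: {value}")

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


def _round_sig(x, sig: int = 6):
    if isinstance(x, bool) or not isinstance(x, float):
        return x
    if x != x or x in (float("inf"), float("-inf")):
        return x
    return float(f"{x:.{sig}g}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if obj != obj:
            return None
        if obj == float("inf"):
            return "Infinity"
        if obj == float("-inf"):
            return "-Infinity"
        return _round_sig(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def write_json_atomic(path: Path, payload) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv_atomic(path: Path, frame: pd.DataFrame) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_inputs(cfg: RunConfig):
    """Resolve configured inputs, falling back to packaged defaults for the
    topology table and tool registry."""
    cfg.validate_paths()
    dataset: CuratedDataset | None = None
    if cfg.patients is not None:
        dataset = load_dataset(cfg.patients, format="patients")
    if cfg.variants is not None:
        extra = load_dataset(cfg.variants, format="variants")
        dataset = extra if dataset is None else dataset.merge(extra)
    if dataset is None:
        raise PipelineError("at least one of patients/variants is required")
    topo = load_topology(cfg.topology) if cfg.topology else load_default_topology()
    registry = load_registry(cfg.registry) if cfg.registry else default_registry()
    matrix = None
    if cfg.scores is not None:
        matrix = load_scores(
            cfg.scores, registry, variants=[v.change for v in dataset.variants]
        )
    return dataset, topo, registry, matrix


def enrichment_stage(dataset: CuratedDataset, topo, cfg: RunConfig) -> dict:
    """TM-vs-other Fisher tests: pathogenic-vs-benign by unique variants,
    plus phenotype axes (seizures, polymicrogyria) among carriers."""
    out: dict = {}
    items = [
        TabulationInput(
            tm=assign_region(v.change.position, topo).tm_class == TRANSMEMBRANE,
            axis_value=(v.label == "pathogenic"),
        )
        for v in dataset.variants
    ]
    try:
        table, dropped = build_contingency(items, axis="label")
        out["label"] = fisher_exact(
            table, axis="label", unit="variants", n_dropped_missing=dropped
        ).to_dict()
    except EnrichmentError as exc:
        out["label"] = {"error": str(exc)}
    for axis in ("seizures", "polymicrogyria"):
        carriers = [p for p in dataset.patients if p.variant.label == "pathogenic"]
        if cfg.unit_for_phenotype == "variants":
            # one representative patient per unique variant
            seen: dict = {}
            for p in carriers:
                seen.setdefault(p.variant.change, p)
            carriers = list(seen.values())
        items = [
            TabulationInput(
                tm=assign_region(p.variant.change.position, topo).tm_class
                == TRANSMEMBRANE,
                axis_value=getattr(p, axis),
            )
            for p in carriers
        ]
        try:
            table, dropped = build_contingency(items, axis=axis)
            out[axis] = fisher_exact(
                table, axis=axis, unit=cfg.unit_for_phenotype,
                n_dropped_missing=dropped,
            ).to_dict()
        except EnrichmentError as exc:
            out[axis] = {"error": str(exc)}
    return out


def default_metrics_stage(matrix, labels: dict[str, str]) -> pd.DataFrame:
    """Per-tool confusion-matrix metrics at recommended thresholds.

    Categorical calls are used when present, otherwise continuous scores
    thresholded at the recommended cutoff. Variants missing a tool's output
    are excluded listwise for that tool.
    """
    rows = []
    keys = [v.format() for v in matrix.variants]
    results = {}
    for tool in matrix.tools:
        if tool.has_categorical and matrix.labels[tool.name].notna().any():
            calls = matrix.calls_from_labels(tool.name)
        elif tool.has_continuous and tool.recommended_threshold is not None:
            calls = matrix.calls_at_threshold(tool.name)
        else:
            continue
        pairs = [
            (call, labels[k])
            for k, call in zip(keys, calls)
            if call is not None and k in labels
        ]
        if not pairs:
            continue
        cm = confusion([c for c, _ in pairs], [l for _, l in pairs])
        ms = metrics(cm)
        results[tool.name] = ms
        rows.append(
            {
                "tool": tool.name,
                "n": cm.n,
                "tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp,
                "prop_deleterious": (cm.tp + cm.fp) / cm.n,
                "prop_tolerated": (cm.tn + cm.fn) / cm.n,
                **{k: (float("nan") if v is None else v) for k, v in ms.to_dict().items()},
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        ranking = rank_tools(results)
        frame["rank"] = frame["tool"].map({t: i + 1 for i, t in enumerate(ranking)})
        frame = frame.sort_values("rank").reset_index(drop=True)
    return frame


def comparison_stage(matrix, labels: dict[str, str], cfg: RunConfig) -> pd.DataFrame:
    rows = []
    keys = [v.format() for v in matrix.variants]
    for tool in matrix.tools:
        if not tool.has_continuous:
            continue
        s = matrix.scores[tool.name]
        pos = [s.iloc[i] for i, k in enumerate(keys) if labels.get(k) == "pathogenic"]
        neg = [s.iloc[i] for i, k in enumerate(keys) if labels.get(k) == "benign"]
        pos = [x for x in pos if x == x]
        neg = [x for x in neg if x == x]
        if len(pos) < 3 or len(neg) < 3:
            continue
        comp = compare_scores(
            oriented(pos, tool), oriented(neg, tool), tool=tool.name,
            alpha=cfg.alpha, policy=cfg.comparison_policy,
        )
        rows.append(comp.to_dict())
    return pd.DataFrame(rows)


def calibration_stage(matrix, labels: dict[str, str], cfg: RunConfig):
    evaluations, summary = evaluate_all_tools(
        matrix, labels, alpha=cfg.alpha, level=cfg.ci_level,
        convention=cfg.threshold_convention,
        comparison_policy=cfg.comparison_policy,
    )
    rows = []
    for ev in evaluations:
        row: dict = {"tool": ev.tool, "n_pos": ev.n_pos, "n_neg": ev.n_neg}
        if ev.skipped_reason:
            row["skipped_reason"] = ev.skipped_reason
        if ev.auc is not None:
            row.update({
                "auc": ev.auc.auc, "ci_low": ev.auc.ci_low,
                "ci_high": ev.auc.ci_high, "p_vs_half": ev.auc.p_vs_half,
            })
        if ev.calibration is not None:
            row["best_threshold"] = ev.calibration.best_threshold
            row["youden_j"] = ev.calibration.youden_j
            for key, value in ev.calibration.metrics_at_best.to_dict().items():
                row[f"{key}_at_best"] = float("nan") if value is None else value
        rows.append(row)
    return pd.DataFrame(rows), summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to cfg.output_dir.

    Returns a dict with the in-memory reports. Raises PipelineError after
    writing a FAILED marker if any stage errors.
    """
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        dataset, topo, registry, matrix = load_inputs(cfg)
        labels = {v.change.format(): v.label for v in dataset.variants}

        summary = summarize_cohort(dataset)
        write_json_atomic(outdir / "cohort_summary.json", summary)

        enrich = enrichment_stage(dataset, topo, cfg)
        write_json_atomic(outdir / "enrichment.json", enrich)

        reports = {"cohort_summary": summary, "enrichment": enrich}
        if matrix is not None:
            cov = coverage_report(matrix)
            write_json_atomic(outdir / "coverage.json", cov.per_tool)
            default_frame = default_metrics_stage(matrix, labels)
            write_tsv_atomic(outdir / "default_metrics.tsv", default_frame)
            write_json_atomic(
                outdir / "default_metrics.json",
                default_frame.to_dict(orient="records"),
            )
            comp_frame = comparison_stage(matrix, labels, cfg)
            write_tsv_atomic(outdir / "comparisons.tsv", comp_frame)
            write_json_atomic(
                outdir / "comparisons.json", comp_frame.to_dict(orient="records")
            )
            calib_frame, calib_summary = calibration_stage(matrix, labels, cfg)
            write_tsv_atomic(outdir / "calibration.tsv", calib_frame)
            write_json_atomic(
                outdir / "calibration.json",
                {
                    "per_tool": calib_frame.to_dict(orient="records"),
                    "summary": calib_summary,
                },
            )
            reports.update(
                coverage=cov.per_tool,
                default_metrics=default_frame,
                comparisons=comp_frame,
                calibration=calib_frame,
                calibration_summary=calib_summary,
            )
        provenance = {
            "package": "scn3a-bench",
            "version": __version__,
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "inputs": {
                k: str(getattr(cfg, k)) if getattr(cfg, k) else None
                for k in ("patients", "variants", "scores", "topology", "registry")
            },
        }
        write_json_atomic(outdir / "provenance.json", provenance)
        reports["provenance"] = provenance
        return reports
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(str(exc)) from exc
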