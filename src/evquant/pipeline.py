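"""End-to-end orchestration: events -> thresholds -> quadrants -> cohort
statistics -> diagnostics, from a single YAML-able config.

Two input modes are supported and converge on the same cohort table:

* ``samples`` — paths to event-table CSVs with group labels, gated
  against an FL1 negative control and an FL4 antibody-free control;
* ``simulate`` — a cohort-generator block producing per-sample display
  percentages directly.

Every default that shapes the analysis is echoed into the report, so a
report plus its config reproduces the run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from . import __version__
from .events import read_events
from .gating import quadrant, threshold_from_control
from .simulate import CohortConfig, gen_cohort
from .stats import (
    GroupComparison,
    RocCurve,
    auc,
    choose_direction,
    compare_groups,
    optimal_threshold,
    roc_points,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage named in the message."""


@dataclass
class PipelineConfig:
    """Validated run configuration (see module docstring for modes)."""

    seed: int = 0
    positive_group: str = "pregnant"
    negative_group: str = "control"
    fl1_rule: str = "max-of-control"
    fl4_rule: str = "max-of-control"
    alpha: float = 0.05
    # event mode
    control_path: str | None = None
    fl4_control_path: str | None = None
    samples: list[dict] = field(default_factory=list)  # {path, sample_id, group}
    # simulation mode
    simulate: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.control_path is None:
                raise PipelineError("config: event mode requires exactly one FL1 control")
            groups = {s.get("group") for s in self.samples}
            missing = [s for s in self.samples if not s.get("group")]
            if missing or not self.samples:
                raise PipelineError("config: every sample needs a group label")
            if not {self.positive_group, self.negative_group} <= groups:
                raise PipelineError(
                    "config: samples must cover both comparison groups"
                )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "positive_group": self.positive_group,
            "negative_group": self.negative_group,
            "fl1_rule": self.fl1_rule, "fl4_rule": self.fl4_rule,
            "alpha": self.alpha,
            "control_path": self.control_path,
            "fl4_control_path": self.fl4_control_path,
            "samples": self.samples, "simulate": self.simulate,
        }


@dataclass
class RunReport:
    config: dict
    version: str
    thresholds: dict
    per_sample: list[dict]            # sample_id, group, display_pct (replicate mean)
    group_summary: dict
    comparison: GroupComparison | None
    direction: str
    roc: RocCurve
    auc: float
    optimal: dict
    stage_log: list[str]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "thresholds": self.thresholds,
            "per_sample": self.per_sample,
            "group_summary": self.group_summary,
            "comparison": None if self.comparison is None else self.comparison.to_dict(),
            "direction": self.direction,
            "roc": self.roc.to_dict(),
            "auc": self.auc,
            "optimal": self.optimal,
            "stage_log": self.stage_log,
        }


def _cohort_from_events(config: PipelineConfig, log: list[str]) -> tuple[pd.DataFrame, dict]:
    control = read_events(config.control_path)
    log.append(
        f"control: {len(control)} events read "
        f"({control.n_dropped_trigger} dropped at trigger)"
    )
    thr_fl1 = threshold_from_control(control, "fl1", rule=config.fl1_rule)
    fl4_ref = (
        read_events(config.fl4_control_path)
        if config.fl4_control_path
        else control
    )
    thr_fl4 = threshold_from_control(fl4_ref, "fl4", rule=config.fl4_rule)
    log.append(
        f"thresholds: fl1 > {thr_fl1.value:g} (from {thr_fl1.provenance}), "
        f"fl4 > {thr_fl4.value:g} (from {thr_fl4.provenance})"
    )
    rows = []
    for entry in config.samples:
        table = read_events(entry["path"])
        q = quadrant(table, thr_fl1, thr_fl4)
        log.append(
            f"sample {entry.get('sample_id', entry['path'])}: {q.n_total} events, "
            f"{q.n_fl1_pos} FL1+, {q.n_double} double-positive"
        )
        rows.append(
            {
                "sample_id": entry.get("sample_id", Path(entry["path"]).stem),
                "group": entry["group"],
                "replicate": entry.get("replicate", 1),
                "display_pct": q.display_pct,
            }
        )
    cohort = pd.DataFrame(rows)
    thresholds = {
        "fl1": {"value": thr_fl1.value, "rule": thr_fl1.rule,
                "provenance": thr_fl1.provenance},
        "fl4": {"value": thr_fl4.value, "rule": thr_fl4.rule,
                "provenance": thr_fl4.provenance},
    }
    return cohort, thresholds


def _cohort_from_simulation(config: PipelineConfig, log: list[str]) -> pd.DataFrame:
    block = dict(config.simulate or {})
    block.setdefault("seed", config.seed)
    cohort_cfg = CohortConfig(**block)
    log.append(
        f"simulated cohort: n={cohort_cfg.n_per_group}/group, "
        f"{cohort_cfg.replicates} replicates, seed {cohort_cfg.seed}"
    )
    return gen_cohort(cohort_cfg)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic given config + seed."""
    config.validate()
    log: list[str] = []
    thresholds: dict = {}
    try:
        if config.simulate is not None:
            cohort = _cohort_from_simulation(config, log)
        else:
            cohort, thresholds = _cohort_from_events(config, log)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"ingest/gating stage failed: {exc}") from exc

    # technical replicates average to one value per biological sample;
    # undefined display percentages stay missing, never zero
    n_missing = int(cohort["display_pct"].isna().sum())
    if n_missing > len(cohort) / 2:
        raise PipelineError(
            f"gating stage: display_pct undefined for {n_missing}/{len(cohort)} rows"
        )
    per_sample = (
        cohort.dropna(subset=["display_pct"])
        .groupby(["sample_id", "group"], as_index=False)["display_pct"]
        .mean()
    )
    log.append(f"replicate averaging: {len(per_sample)} biological samples")

    pos = per_sample.loc[
        per_sample["group"] == config.positive_group, "display_pct"
    ].to_numpy()
    neg = per_sample.loc[
        per_sample["group"] == config.negative_group, "display_pct"
    ].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise PipelineError("comparison stage: a comparison group is empty")

    summary = {
        config.positive_group: {
            "n": int(pos.size), "mean": float(np.mean(pos)),
            "sd": float(np.std(pos, ddof=1)) if pos.size > 1 else 0.0,
        },
        config.negative_group: {
            "n": int(neg.size), "mean": float(np.mean(neg)),
            "sd": float(np.std(neg, ddof=1)) if neg.size > 1 else 0.0,
        },
    }
    try:
        comparison = compare_groups(pos, neg, alpha=config.alpha)
    except ValueError as exc:
        raise PipelineError(f"comparison stage failed: {exc}") from exc
    log.append(f"comparison: {comparison.test_used}, p = {comparison.p_value:.4g}")

    try:
        direction = choose_direction(float(np.mean(pos)), float(np.mean(neg)))
        curve = roc_points(pos, neg, direction)
        area = auc(curve)
        thr, sens, spec = optimal_threshold(curve)
    except ValueError as exc:
        raise PipelineError(f"roc stage failed: {exc}") from exc
    log.append(f"roc: direction {direction}, AUC {area:.3f}")

    return RunReport(
        config=config.to_dict(), version=__version__,
        thresholds=thresholds,
        per_sample=per_sample.to_dict(orient="records"),
        group_summary=summary, comparison=comparison,
        direction=direction, roc=curve, auc=area,
        optimal={"threshold": thr, "sensitivity": sens, "specificity": spec},
        stage_log=log,
    )


def render_report(report: RunReport, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a report to JSON (lossless) or markdown (human-readable)."""
    if not report.per_sample:
        raise ValueError("refusing to render an empty cohort report")
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    elif fmt == "markdown":
        lines = ["# evquant run report", ""]
        lines.append("| group | n | display % (mean ± SD) |")
        lines.append("|---|---|---|")
        for group, s in report.group_summary.items():
            lines.append(f"| {group} | {s['n']} | {s['mean']:.1f} ± {s['sd']:.1f} |")
        lines.append("")
        if report.comparison is not None:
            c = report.comparison
            lines.append(
                f"Comparison: {c.test_used}, statistic {c.statistic:.3f}, "
                f"p = {c.p_value:.4g}"
            )
        o = report.optimal
        lines.append(
            f"ROC: direction {report.direction}, AUC {report.auc:.3f}; optimal "
            f"threshold {o['threshold']:.2f} (sens {o['sensitivity']:.2f}, "
            f"spec {o['specificity']:.2f})"
        )
        lines.append("")
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
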