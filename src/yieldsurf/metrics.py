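"""Model-comparison statistics (R², RMSE, AAD) and validation bookkeeping.

AAD (average absolute deviation) is reported in both conventions found in
the extraction-optimization literature: absolute (yield-% units, the
default) and relative-% (mean of 100·|o−p|/o).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FitMetrics",
    "ValidationRecord",
    "compute_metrics",
    "validation_record",
    "comparison_report",
    "write_report",
]


@dataclass(frozen=True)
class FitMetrics:
    model_label: str
    r2: float
    rmse: float
    aad: float
    aad_pct: float
    n: int


@dataclass(frozen=True)
class ValidationRecord:
    model_label: str
    optimum_conditions: tuple[float, float, float]
    predicted_yield: float
    actual_yield: float
    relative_error_pct: float
    squared_error: float


def compute_metrics(
    predicted: Sequence[float], observed: Sequence[float], label: str = ""
) -> FitMetrics:
    """R² = 1 − SSE/SST, RMSE = sqrt(SSE/n), AAD = mean |o − p|."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be equal-length 1-D series")
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed series has zero variance: R^2 undefined")
    sse = float(np.sum((o - p) ** 2))
    return FitMetrics(
        model_label=label,
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / n)),
        aad=float(np.mean(np.abs(o - p))),
        aad_pct=float(np.mean(100.0 * np.abs(o - p) / o)),
        n=n,
    )


def validation_record(
    model_label: str,
    optimum: Sequence[float],
    predicted: float,
    actual: float,
) -> ValidationRecord:
    """Single confirmation-experiment record for one model's optimum."""
    if actual <= 0:
        raise ValueError("actual yield must be positive")
    return ValidationRecord(
        model_label=model_label,
        optimum_conditions=tuple(float(v) for v in optimum),
        predicted_yield=float(predicted),
        actual_yield=float(actual),
        relative_error_pct=100.0 * abs(predicted - actual) / actual,
        squared_error=(predicted - actual) ** 2,
    )


def comparison_report(
    metrics: Sequence[FitMetrics],
    validations: Sequence[ValidationRecord] = (),
) -> dict:
    """Rank models by (R² descending, RMSE ascending) and flag the winner."""
    if not metrics:
        raise ValueError("at least one model's metrics required")
    ranked = sorted(metrics, key=lambda m: (-m.r2, m.rmse))
    return {
        "ranking": [m.model_label for m in ranked],
        "winner": ranked[0].model_label,
        "metrics": [vars(m) for m in ranked],
        "validation": [vars(v) for v in validations],
    }


def write_report(report: dict, json_path: str | Path, md_path: str | Path | None = None) -> None:
    """Emit the comparison report as JSON and an optional Markdown table."""
    Path(json_path).write_text(json.dumps(report, indent=1) + "\n")
    if md_path is None:
        return
    lines = [
        "| Model | R² | RMSE | AAD | AAD (%) | n |",
        "|---|---|---|---|---|---|",
    ]
    for m in report["metrics"]:
        lines.append(
            f"| {m['model_label']} | {m['r2']:.4f} | {m['rmse']:.4f} "
            f"| {m['aad']:.4f} | {m['aad_pct']:.2f} | {m['n']} |"
        )
    if report["validation"]:
        lines += [
            "",
            "| Model | pH | Enzyme (%) | Time (min) | Predicted | Actual | Rel. err (%) | Sq. err |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for v in report["validation"]:
            a, b, c = v["optimum_conditions"]
            lines.append(
                f"| {v['model_label']} | {a:.3f} | {b:.3f} | {c:.3f} "
                f"| {v['predicted_yield']:.2f} | {v['actual_yield']:.2f} "
                f"| {v['relative_error_pct']:.2f} | {v['squared_error']:.4f} |"
            )
    lines.append(f"\nBest model: **{report['winner']}**")
    Path(md_path).write_text("\n".join(lines) + "\n")
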