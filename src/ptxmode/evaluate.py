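"""Confusion matrices, the five summary metrics, and replicate aggregation.

Conventions. "Positive" means PTX present everywhere (confusion layout,
metrics, figure labels). A degenerate predictor (e.g. all-negative output on
a domain-shifted test set) makes precision, recall or F1 undefined; those
metrics are reported as *absent* (None / '-'), never coerced to 0, so that
replicate means are not corrupted. Replicates are aggregated as the mean of
per-class percent matrices (each matrix row-normalized by its true-class
count before averaging), and metric means are taken per-model over the
models where the metric is defined. Metrics print with 3 decimals, percent
matrices with 1; CSVs keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "InputError",
    "confusion",
    "metrics",
    "aggregate",
    "percent_matrix",
    "write_report",
    "plot_mean_matrix",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2×2 counts with positive = PTX present."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = true class (positive, negative); cols = predicted."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from two equal-length binary label sequences."""
    yt = np.asarray(labels_true).astype(np.int64)
    yp = np.asarray(labels_pred).astype(np.int64)
    if yt.shape != yp.shape:
        raise InputError(
            f"label lengths differ: {yt.shape} vs {yp.shape}"
        )
    if yt.size == 0:
        raise InputError("empty label sequences")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def metrics(matrix: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall, specificity and F1 from one matrix.

    accuracy = (TP+TN)/N; precision = TP/(TP+FP); recall = TP/(TP+FN);
    specificity = TN/(TN+FP); F1 = 2PR/(P+R). Ratios with a zero
    denominator are returned as None (printed '-'), as is F1 when either
    constituent is undefined or P+R = 0.
    """
    m = matrix
    if m.n < 1:
        raise InputError("confusion matrix has no observations")
    if min(m.tp, m.fp, m.fn, m.tn) < 0:
        raise InputError("confusion counts must be non-negative")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(m.tp, m.tp + m.fp)
    recall = ratio(m.tp, m.tp + m.fn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (m.tp + m.tn) / m.n,
        "precision": precision,
        "recall": recall,
        "specificity": ratio(m.tn, m.tn + m.fp),
        "f1": f1,
    }


def percent_matrix(matrix: ConfusionMatrix) -> np.ndarray:
    """Row-normalized percent matrix: each cell as % of its true class."""
    arr = matrix.as_array().astype(float)
    row_sums = arr.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise InputError("percent matrix undefined: a true class is empty")
    return 100.0 * arr / row_sums


@dataclass
class EvalReport:
    """Per-replicate confusion matrices plus their aggregate."""

    per_model: list[ConfusionMatrix]
    mean_rates: np.ndarray            # 2x2 mean percent matrix
    per_model_metrics: list[dict[str, float | None]]
    mean_metrics: dict[str, float | None]
    undefined_flags: dict[str, list[int]]

    @property
    def n_models(self) -> int:
        return len(self.per_model)

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metrics["accuracy"]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(model=i, **{k: m[k] for k in METRIC_NAMES})
                for i, m in enumerate(self.per_model_metrics)]
        rows.append(dict(model="mean", **{k: self.mean_metrics[k]
                                          for k in METRIC_NAMES}))
        return pd.DataFrame(rows)

    def format_metrics(self) -> str:
        """Table-style one-liner: 3 decimals, '-' for absent metrics."""
        vals = [f"{self.mean_metrics[k]:.3f}"
                if self.mean_metrics[k] is not None else "-"
                for k in METRIC_NAMES]
        return "\t".join(vals)


def aggregate(matrices: list[ConfusionMatrix]) -> EvalReport:
    """Average replicate confusion matrices as mean percent per cell.

    All replicates must have the same test-set size (mean-of-percent only
    commutes with pooling counts under equal sizes, which this pipeline
    enforces). Metric means are computed over the models where the metric
    is defined; a metric undefined in every model stays absent.
    """
    if not matrices:
        raise InputError("no reports to aggregate")
    sizes = {m.n for m in matrices}
    if len(sizes) != 1:
        raise InputError(f"inconsistent test sizes across replicates: {sizes}")

    mean_rates = np.mean([percent_matrix(m) for m in matrices], axis=0)
    per_model_metrics = [metrics(m) for m in matrices]

    mean_metrics: dict[str, float | None] = {}
    undefined: dict[str, list[int]] = {}
    for name in METRIC_NAMES:
        defined = [pm[name] for pm in per_model_metrics if pm[name] is not None]
        undefined[name] = [i for i, pm in enumerate(per_model_metrics)
                           if pm[name] is None]
        mean_metrics[name] = float(np.mean(defined)) if defined else None

    return EvalReport(per_model=list(matrices), mean_rates=mean_rates,
                      per_model_metrics=per_model_metrics,
                      mean_metrics=mean_metrics, undefined_flags=undefined)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(reports: dict[tuple[str, str], EvalReport],
                 out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``metrics.csv`` (condition × test type rows, five metric
    columns) and ``confusion_mean.csv`` (mean percent cells) for a bundle
    of evaluations keyed by (condition, test_type)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    met_rows, cm_rows = [], []
    for (condition, test_type), rep in reports.items():
        met_rows.append({
            "condition": condition, "test_type": test_type,
            "n_models": rep.n_models,
            **{k: rep.mean_metrics[k] for k in METRIC_NAMES},
        })
        tp, fn = rep.mean_rates[0]
        fp, tn = rep.mean_rates[1]
        cm_rows.append({"condition": condition, "test_type": test_type,
                        "tp_pct": tp, "fn_pct": fn,
                        "fp_pct": fp, "tn_pct": tn})
    metrics_path = out / "metrics.csv"
    cm_path = out / "confusion_mean.csv"
    pd.DataFrame(met_rows).to_csv(metrics_path, index=False)
    pd.DataFrame(cm_rows).to_csv(cm_path, index=False)
    return metrics_path, cm_path


def plot_mean_matrix(report: EvalReport, title: str,
                     path: str | Path) -> Path:
    """Render one mean percent confusion matrix as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    im = ax.imshow(report.mean_rates, cmap="Blues", vmin=0, vmax=100)
    for i in range(2):
        for j in range(2):
            val = report.mean_rates[i, j]
            ax.text(j, i, f"{val:.1f}%", ha="center", va="center",
                    color="black" if val < 60 else "white")
    ax.set_xticks([0, 1], ["pred +", "pred -"])
    ax.set_yticks([0, 1], ["true +", "true -"])
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
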