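"""Confusion-matrix accuracy metrics and classification-map rendering.

Convention: rows index the true class i, columns the predicted class j, so
``x[i, j]`` counts samples of true class i predicted as j (1-based labels on
the outside, 0 reserved for unlabeled background and excluded upstream).

Metrics:

* OA    = sum_i x_ii / N                         (overall accuracy)
* AA    = mean_i x_ii / row_i                    (class-averaged accuracy)
* Kappa = (N sum_i x_ii - sum_i row_i col_i) / (N^2 - sum_i row_i col_i)
* PA_i  = x_ii / row_i   (producer's accuracy, per-class recall)
* UA_j  = x_jj / col_j   (user's accuracy, per-class precision)

Undefined per-class entries (empty row/column) are reported as NaN, never 0.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ParameterError, ShapeMismatchError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "overall_accuracy",
    "average_accuracy",
    "kappa",
    "producer_user_accuracy",
    "metrics_report",
    "default_palette",
    "render_classification_map",
    "save_classification_png",
]


@dataclass
class ConfusionMatrix:
    """n x n non-negative integer counts; rows true, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ShapeMismatchError("confusion matrix must be square")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ParameterError("confusion counts must be non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true: np.ndarray, pred: np.ndarray, n: int) -> ConfusionMatrix:
    """Count table x_ij = #{true == i and pred == j} for labels in [1, n]."""
    true = np.asarray(true).ravel()
    pred = np.asarray(pred).ravel()
    if true.shape != pred.shape:
        raise ShapeMismatchError("true/pred length mismatch")
    if true.size and (true.min() < 1 or true.max() > n or pred.min() < 1 or pred.max() > n):
        raise ParameterError(f"labels must lie in [1, {n}]")
    counts = np.bincount((true - 1) * n + (pred - 1), minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def average_accuracy(cm: ConfusionMatrix, on_empty_row: str = "error") -> float:
    rows = cm.counts.sum(axis=1)
    diag = np.diag(cm.counts)
    if np.any(rows == 0):
        if on_empty_row == "error":
            raise UndefinedMetricError("a true class has no samples; AA undefined")
        if on_empty_row != "drop":
            raise ParameterError(f"unknown on_empty_row mode {on_empty_row!r}")
    ok = rows > 0
    if not np.any(ok):
        raise UndefinedMetricError("all classes empty")
    return float(np.mean(diag[ok] / rows[ok]))


def kappa(cm: ConfusionMatrix) -> float:
    n_tot = cm.total
    if n_tot == 0:
        raise UndefinedMetricError("empty confusion matrix")
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    chance = float(rows @ cols)
    denom = n_tot * n_tot - chance
    if denom == 0:
        raise UndefinedMetricError("chance agreement is 1; kappa undefined")
    return float((n_tot * np.trace(cm.counts) - chance) / denom)


def producer_user_accuracy(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(PA, UA) vectors; empty rows/columns yield NaN entries."""
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    diag = np.diag(cm.counts).astype(float)
    pa = np.where(rows > 0, diag / np.where(rows > 0, rows, 1.0), np.nan)
    ua = np.where(cols > 0, diag / np.where(cols > 0, cols, 1.0), np.nan)
    return pa, ua


@dataclass
class MetricsReport:
    """Full metric suite for one evaluation; stored at full precision."""

    oa: float
    aa: float
    kappa: float
    pa: np.ndarray
    ua: np.ndarray

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "aa": self.aa,
            "kappa": self.kappa,
            "pa": [None if np.isnan(v) else v for v in self.pa],
            "ua": [None if np.isnan(v) else v for v in self.ua],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        # percentages to 3 decimals, the field's usual reporting style
        return (
            f"OA={100 * self.oa:.3f}%  AA={100 * self.aa:.3f}%  "
            f"Kappa={self.kappa:.4f}"
        )


def metrics_report(cm: ConfusionMatrix, on_empty_row: str = "drop") -> MetricsReport:
    pa, ua = producer_user_accuracy(cm)
    return MetricsReport(
        oa=overall_accuracy(cm),
        aa=average_accuracy(cm, on_empty_row=on_empty_row),
        kappa=kappa(cm),
        pa=pa,
        ua=ua,
    )


def default_palette(n: int) -> dict[int, tuple[int, int, int]]:
    """n visually distinct colors for classes 1..n; background 0 is black."""
    palette = {0: (0, 0, 0)}
    for i in range(1, n + 1):
        h = (i - 1) / max(n, 1)
        r, g, b = colorsys.hsv_to_rgb(h, 0.85 if i % 2 else 0.55, 0.95 if i % 2 else 0.75)
        palette[i] = (int(255 * r), int(255 * g), int(255 * b))
    return palette


def render_classification_map(
    labels: np.ndarray, palette: dict[int, tuple[int, int, int]] | None = None
) -> np.ndarray:
    """Color image (M, N, 3) uint8 from a label map; background 0 -> black."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    if palette is None:
        palette = default_palette(int(present.max()) if present.size else 0)
    missing = [int(v) for v in present if int(v) not in palette]
    if missing:
        raise ParameterError(f"palette lacks entries for labels {missing}")
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab in present:
        out[labels == lab] = palette[int(lab)]
    return out


def save_classification_png(
    labels: np.ndarray, path, palette: dict[int, tuple[int, int, int]] | None = None
) -> None:
    """Write a paletted PNG whose palette index equals the class label."""
    labels = np.asarray(labels)
    top = int(labels.max()) if labels.size else 0
    if palette is None:
        palette = default_palette(top)
    if top > 255:
        raise ParameterError("paletted PNG supports at most 255 classes")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = []
    for i in range(256):
        flat.extend(palette.get(i, (0, 0, 0)))
    img.putpalette(flat)
    img.save(path)
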