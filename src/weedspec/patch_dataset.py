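"""3-D neighbourhood patches, Tr-ratio splits and stratified k-fold CV.

Each labeled pixel (label >= 1; 0 is unlabeled background) contributes one
training sample: the w x w x B window of the reduced cube centred on it, with
the centre pixel's label as the target.  Borders are handled by edge
replication so every labeled pixel stays usable.  Windows of nearby samples
overlap; train and test sets are disjoint in *centre pixels*, which is the
standard (and mildly optimistic) protocol for patch-based HSI classification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import StratifiedKFold

from .errors import EmptySelectionError, ParameterError, ShapeMismatchError, StratificationError
from .superpixel import ReducedCube

__all__ = [
    "PatchSet",
    "SplitSpec",
    "extract_patches",
    "split_train_test",
    "kfold_splits",
    "save_patchset",
    "load_patchset",
]


@dataclass
class PatchSet:
    """Windows (n, w, w, B), centre coordinates (n, 2), labels (n,) in [1, n_classes]."""

    windows: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        if self.windows.ndim != 4 or self.windows.shape[1] != self.windows.shape[2]:
            raise ShapeMismatchError("windows must be (n, w, w, B)")
        if len(self.labels) != len(self.windows) or len(self.centers) != len(self.windows):
            raise ShapeMismatchError("windows/centers/labels lengths differ")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.n_classes):
            raise ParameterError("labels must lie in [1, n_classes]")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def w(self) -> int:
        return self.windows.shape[1]

    @property
    def B(self) -> int:
        return self.windows.shape[3]

    def subset(self, idx: np.ndarray) -> "PatchSet":
        return PatchSet(
            windows=self.windows[idx],
            centers=self.centers[idx],
            labels=self.labels[idx],
            n_classes=self.n_classes,
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]


@dataclass(frozen=True)
class SplitSpec:
    """Training fraction Tr, RNG seed and stratification flag."""

    tr: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tr < 1.0:
            raise ParameterError("tr must lie strictly between 0 and 1")


def extract_patches(
    rc: ReducedCube, labels: np.ndarray, w: int, padding: str = "edge"
) -> PatchSet:
    """One w x w x B patch per labeled pixel, borders replicate-padded."""
    if w % 2 == 0 or w < 1:
        raise ParameterError("window size w must be odd and positive")
    labels = np.asarray(labels)
    m, n, b = rc.values.shape
    if labels.shape != (m, n):
        raise ShapeMismatchError("label map shape does not match cube")
    rows, cols = np.nonzero(labels)
    if rows.size == 0:
        raise EmptySelectionError("label map has no labeled pixels")
    half = w // 2
    if padding == "edge":
        padded = np.pad(rc.values, ((half, half), (half, half), (0, 0)), mode="edge")
    elif padding == "zero":
        padded = np.pad(rc.values, ((half, half), (half, half), (0, 0)))
    else:
        raise ParameterError(f"unknown padding {padding!r}")
    view = sliding_window_view(padded, (w, w), axis=(0, 1))  # (M, N, B, w, w)
    windows = view[rows, cols].transpose(0, 2, 3, 1)  # (n, w, w, B)
    lab = labels[rows, cols].astype(int)
    return PatchSet(
        windows=np.ascontiguousarray(windows),
        centers=np.stack([rows, cols], axis=1),
        labels=lab,
        n_classes=int(lab.max()),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(ps: PatchSet, spec: SplitSpec) -> tuple[PatchSet, PatchSet]:
    """Disjoint, exhaustive Tr split; per-class share round(tr*count), floor 1."""
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if spec.stratified:
        for cls in range(1, ps.n_classes + 1):
            members = np.nonzero(ps.labels == cls)[0]
            if members.size == 0:
                raise StratificationError(f"class {cls} has no samples")
            perm = rng.permutation(members)
            n_tr = max(1, _round_half_up(spec.tr * members.size))
            train_idx.append(perm[:n_tr])
            test_idx.append(perm[n_tr:])
    else:
        perm = rng.permutation(len(ps))
        n_tr = max(1, _round_half_up(spec.tr * len(ps)))
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx)) if any(a.size for a in test_idx) else np.array([], int)
    return ps.subset(tr), ps.subset(te)


def kfold_splits(
    ps: PatchSet, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions over the patch set (train, validation) indices."""
    if k < 2:
        raise ParameterError("k must be at least 2")
    counts = ps.class_counts()
    if np.any(counts > 0) and counts[counts > 0].min() < k:
        raise StratificationError(
            f"smallest class has {counts[counts > 0].min()} samples < k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, val) for train, val in skf.split(np.zeros(len(ps)), ps.labels)
    ]


def save_patchset(ps: PatchSet, path, meta: dict | None = None) -> None:
    """Persist a patch set (archive dialect) with split metadata for resumption."""
    np.savez(
        path,
        windows=ps.windows,
        centers=ps.centers,
        labels=ps.labels,
        n_classes=np.array(ps.n_classes),
        meta=np.array(json.dumps(meta or {})),
    )


def load_patchset(path) -> tuple[PatchSet, dict]:
    with np.load(path) as z:
        ps = PatchSet(
            windows=z["windows"],
            centers=z["centers"],
            labels=z["labels"],
            n_classes=int(z["n_classes"]),
        )
        meta = json.loads(str(z["meta"]))
    return ps, meta
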