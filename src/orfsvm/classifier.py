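"""Class-weighted linear SVM training, evaluation, CV screening and tuning.

The decision function is f(x) = w.x + b with x the min-max-scaled feature
vector; a sequence is predicted coding iff f(x) > 0 (plus any threshold
offset).  Misclassification costs are C for positives and C * w_ratio for
negatives, with w_ratio = w_minus / w_plus and w_plus fixed at 1, so raising
w_ratio trades sensitivity for specificity.

Performance is summarised by sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP) (both percentages) and accuracy = (Sn + Sp)/2 — the balanced
mean, not the pooled fraction correct, so class imbalance does not mask the
minority class.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from .features import (
    BLOCK_WIDTHS,
    FEATURE_ORDER_VERSION,
    FULL_SELECTION,
    ScalingModel,
    encode_matrix,
)

__all__ = [
    "TrainedModel",
    "PerformanceReport",
    "GridSearchResult",
    "Prediction",
    "train",
    "decision_scores",
    "evaluate",
    "accuracy_from_sn_sp",
    "confusion_from_scores",
    "make_folds",
    "cross_validate",
    "screen_combinations",
    "grid_search",
    "threshold_sweep",
    "predict_orfs",
    "train_on_sequences",
    "save_model",
    "load_model",
]

DEFAULT_C = 2.0 ** -3.5
DEFAULT_W_RATIO = 2.0 ** 0.6
_SOLVER_TOL = 1e-4
_MAX_ITER = 20000


@dataclass
class TrainedModel:
    """Linear decision function plus everything needed to reapply it."""

    weights: np.ndarray
    bias: float
    C: float
    w_ratio: float
    scaler: Optional[ScalingModel] = None
    selection: tuple[int, ...] = FULL_SELECTION
    step: int = 3

    @property
    def width(self) -> int:
        return self.weights.shape[0]


@dataclass
class PerformanceReport:
    """Confusion counts with Sn/Sp/accuracy; optionally per-fold CV detail."""

    tp: int
    fn: int
    tn: int
    fp: int
    sn_folds: Optional[list[float]] = None
    sp_folds: Optional[list[float]] = None
    misclassified_positives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fn == 0:
            raise ValueError("no positive samples (TP + FN = 0)")
        if self.tn + self.fp == 0:
            raise ValueError("no negative samples (TN + FP = 0)")

    @property
    def sn(self) -> float:
        """Sensitivity TP/(TP+FN), percent; or mean of per-fold values in CV."""
        if self.sn_folds is not None:
            return float(np.mean(self.sn_folds))
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        """Specificity TN/(TN+FP), percent; or mean of per-fold values in CV."""
        if self.sp_folds is not None:
            return float(np.mean(self.sp_folds))
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        """Balanced accuracy (Sn + Sp)/2, percent."""
        return (self.sn + self.sp) / 2.0

    @property
    def sn_std(self) -> Optional[float]:
        if self.sn_folds is None:
            return None
        return float(np.std(self.sn_folds, ddof=1)) if len(self.sn_folds) > 1 else 0.0

    @property
    def sp_std(self) -> Optional[float]:
        if self.sp_folds is None:
            return None
        return float(np.std(self.sp_folds, ddof=1)) if len(self.sp_folds) > 1 else 0.0


@dataclass
class GridSearchResult:
    """CV accuracy over a (log2 C, log2 w_ratio) grid, with the best cell."""

    log2C_grid: tuple[float, ...]
    log2w_grid: tuple[float, ...]
    accuracy: np.ndarray  # shape (len(log2C_grid), len(log2w_grid))
    best_log2C: float
    best_log2w: float

    @property
    def best_C(self) -> float:
        return 2.0 ** self.best_log2C

    @property
    def best_w_ratio(self) -> float:
        return 2.0 ** self.best_log2w


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    length_bp: int
    score: Optional[float]
    label: str  # coding | noncoding | unscorable


# ---------------------------------------------------------------------------
# core fit / score / evaluate


def train(
    X: np.ndarray,
    y: Sequence[int],
    C: float = DEFAULT_C,
    w_ratio: float = DEFAULT_W_RATIO,
    scaler: Optional[ScalingModel] = None,
    selection: tuple[int, ...] = FULL_SELECTION,
    step: int = 3,
    random_state: int = 0,
) -> TrainedModel:
    """Fit the class-weighted linear SVM on already-scaled vectors.

    y holds +1 (coding) / -1 (noncoding).  The effective cost is C for
    positives and C * w_ratio for negatives.  Deterministic for a fixed
    input order and random_state.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    classes = set(np.unique(y))
    if classes != {-1, 1}:
        raise ValueError(f"need both classes (+1/-1) in training data, got {sorted(classes)}")
    svc = LinearSVC(
        C=C,
        class_weight={1: 1.0, -1: w_ratio},
        loss="hinge",
        dual=True,
        tol=_SOLVER_TOL,
        max_iter=_MAX_ITER,
        random_state=random_state,
    )
    svc.fit(X, y)
    return TrainedModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        w_ratio=w_ratio,
        scaler=scaler,
        selection=tuple(selection),
        step=step,
    )


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Raw margins w.x + b for already-scaled vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.width:
        raise ValueError(f"width mismatch: model {model.width}, data {X.shape[1]}")
    return X @ model.weights + model.bias


def evaluate(tp: int, fn: int, tn: int, fp: int) -> PerformanceReport:
    """Sn/Sp/accuracy from a confusion table; errors on an empty class."""
    return PerformanceReport(tp=tp, fn=fn, tn=tn, fp=fp)


def accuracy_from_sn_sp(sn: float, sp: float) -> float:
    """Balanced accuracy from sensitivity and specificity percentages."""
    return (sn + sp) / 2.0


def confusion_from_scores(
    scores: np.ndarray, y: Sequence[int], threshold: float = 0.0
) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) predicting coding iff score > threshold."""
    y = np.asarray(y, dtype=int)
    pred = np.asarray(scores) > threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == -1)))
    fp = int(np.sum(pred & (y == -1)))
    return tp, fn, tn, fp


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(y: Sequence[int], k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partition, stratified when class sizes allow.

    Every training split must contain both classes; if a draw violates this
    the partition is re-drawn with a derived seed, at most 10 times.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    if n_min < 1:
        raise ValueError("need both classes for cross-validation")
    for attempt in range(10):
        rs = seed + 1_000_003 * attempt
        if k <= n_min:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        else:  # degenerate folds (up to leave-one-out): plain k-fold
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
        folds = [
            (tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros_like(y), y)
        ]
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not draw a partition with both classes in every training split")


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    C: float = DEFAULT_C,
    w_ratio: float = DEFAULT_W_RATIO,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
    folds: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
    refit_scaler: bool = True,
) -> PerformanceReport:
    """Seeded k-fold CV with the scaler re-fit inside every fold (no leakage).

    Returns pooled confusion counts, per-fold Sn/Sp (whose means and sample
    standard deviations summarise the run) and the identities of positives
    that were misclassified in their held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds is None:
        folds = make_folds(y, k, seed)
    global_scaler = None if refit_scaler else ScalingModel.fit(X)
    tp = fn = tn = fp = 0
    sn_folds: list[float] = []
    sp_folds: list[float] = []
    missed: list[str] = []
    for tr, te in folds:
        scaler = ScalingModel.fit(X[tr]) if refit_scaler else global_scaler
        model = train(scaler.transform(X[tr]), y[tr], C=C, w_ratio=w_ratio)
        scores = decision_scores(model, scaler.transform(X[te]))
        ftp, ffn, ftn, ffp = confusion_from_scores(scores, y[te])
        tp, fn, tn, fp = tp + ftp, fn + ffn, tn + ftn, fp + ffp
        if ftp + ffn > 0:
            sn_folds.append(100.0 * ftp / (ftp + ffn))
        if ftn + ffp > 0:
            sp_folds.append(100.0 * ftn / (ftn + ffp))
        if ids is not None:
            for i in te[(y[te] == 1) & (scores <= 0)]:
                missed.append(ids[i])
    return PerformanceReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sn_folds=sn_folds,
        sp_folds=sp_folds,
        misclassified_positives=tuple(missed),
    )


def _block_slices(selection: tuple[int, ...]) -> dict[int, slice]:
    out = {}
    off = 0
    for s in selection:
        w = BLOCK_WIDTHS[s]
        out[s] = slice(off, off + w)
        off += w
    return out


def screen_combinations(
    X_full: np.ndarray,
    y: Sequence[int],
    k: int = 10,
    C: float = DEFAULT_C,
    w_ratio: float = DEFAULT_W_RATIO,
    seed: int = 0,
) -> list[tuple[tuple[int, ...], PerformanceReport]]:
    """CV over every non-empty subset of the six measurements (63 rows).

    X_full must hold all six blocks in measurement order (width 4682).  The
    same seeded fold partition is reused for every combination so rows are
    comparable.  Rows are ordered singletons first, then pairs, ..., the
    full set last (lexicographic within a size).
    """
    X_full = np.asarray(X_full, dtype=float)
    if X_full.shape[1] != sum(BLOCK_WIDTHS.values()):
        raise ValueError("screen_combinations needs the full six-block matrix")
    slices = _block_slices(FULL_SELECTION)
    folds = make_folds(y, k, seed)
    rows: list[tuple[tuple[int, ...], PerformanceReport]] = []
    for size in range(1, 7):
        for combo in itertools.combinations(FULL_SELECTION, size):
            cols = np.concatenate([np.arange(slices[s].start, slices[s].stop) for s in combo])
            report = cross_validate(
                X_full[:, cols], y, k=k, C=C, w_ratio=w_ratio, folds=folds
            )
            rows.append((combo, report))
    return rows


DEFAULT_LOG2C_GRID = tuple(np.arange(-8.0, 4.0 + 1e-9, 0.5))
DEFAULT_LOG2W_GRID = tuple(np.round(np.arange(-2.0, 2.0 + 1e-9, 0.2), 10))


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    log2C_grid: Sequence[float] = DEFAULT_LOG2C_GRID,
    log2w_grid: Sequence[float] = DEFAULT_LOG2W_GRID,
    k: int = 10,
    seed: int = 0,
) -> GridSearchResult:
    """CV accuracy over a (log2 C, log2 w_ratio) grid with shared folds.

    Ties are broken toward the smaller C, then the smaller |log2 w_ratio|
    (the simplest, least-reweighted model).
    """
    log2C_grid = tuple(log2C_grid)
    log2w_grid = tuple(log2w_grid)
    if not log2C_grid or not log2w_grid:
        raise ValueError("grids must be non-empty")
    folds = make_folds(np.asarray(y, dtype=int), k, seed)
    acc = np.empty((len(log2C_grid), len(log2w_grid)))
    for i, lc in enumerate(log2C_grid):
        for j, lw in enumerate(log2w_grid):
            report = cross_validate(
                X, y, k=k, C=2.0 ** lc, w_ratio=2.0 ** lw, folds=folds
            )
            acc[i, j] = report.accuracy
    best_i, best_j = 0, 0
    best_key = (-acc[0, 0], log2C_grid[0], abs(log2w_grid[0]))
    for i, lc in enumerate(log2C_grid):
        for j, lw in enumerate(log2w_grid):
            key = (-acc[i, j], lc, abs(lw))
            if key < best_key:
                best_key, best_i, best_j = key, i, j
    return GridSearchResult(
        log2C_grid=log2C_grid,
        log2w_grid=log2w_grid,
        accuracy=acc,
        best_log2C=log2C_grid[best_i],
        best_log2w=log2w_grid[best_j],
    )


def threshold_sweep(
    model: TrainedModel,
    X: np.ndarray,
    y: Sequence[int],
    offsets: Sequence[float],
) -> list[tuple[float, float, float]]:
    """(offset, Sn, Sp) predicting coding iff score > offset.

    Sn is non-increasing and Sp non-decreasing in the offset, tracing the
    sensitivity/specificity trade-off around the trained hyperplane.
    """
    scores = decision_scores(model, X)
    out = []
    for t in offsets:
        if not math.isfinite(t):
            raise ValueError("offsets must be finite")
        tp, fn, tn, fp = confusion_from_scores(scores, y, threshold=t)
        sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        out.append((float(t), sn, sp))
    return out


# ---------------------------------------------------------------------------
# end-to-end sequence interfaces


def train_on_sequences(
    sequences: Sequence[str],
    labels: Sequence[int],
    selection: tuple[int, ...] = FULL_SELECTION,
    C: float = DEFAULT_C,
    w_ratio: float = DEFAULT_W_RATIO,
    step: int = 3,
    random_state: int = 0,
) -> TrainedModel:
    """Encode, fit the min-max scaler, and train in one step."""
    X = encode_matrix(sequences, selection, step)
    scaler = ScalingModel.fit(X)
    return train(
        scaler.transform(X),
        labels,
        C=C,
        w_ratio=w_ratio,
        scaler=scaler,
        selection=selection,
        step=step,
        random_state=random_state,
    )


def predict_orfs(
    model: TrainedModel, sequences: Sequence[tuple[str, str]]
) -> list[Prediction]:
    """Score (id, sequence) pairs with the model's own encoder and scaler.

    Sequences shorter than one codon are flagged unscorable, not dropped.
    """
    if model.scaler is None:
        raise ValueError("model has no attached scaler; train via train_on_sequences")
    out: list[Optional[Prediction]] = [None] * len(sequences)
    scorable: list[tuple[int, str]] = []
    for i, (seq_id, seq) in enumerate(sequences):
        if len(seq) < 3:
            out[i] = Prediction(seq_id, len(seq), None, "unscorable")
        else:
            scorable.append((i, seq))
    if scorable:
        X = encode_matrix([s for _, s in scorable], model.selection, model.step)
        scores = decision_scores(model, model.scaler.transform(X))
        for (i, _), score in zip(scorable, scores):
            seq_id, seq = sequences[i]
            label = "coding" if score > 0 else "noncoding"
            out[i] = Prediction(seq_id, len(seq), float(score), label)
    return [p for p in out if p is not None]


# ---------------------------------------------------------------------------
# model persistence (plain text; reload reproduces scores exactly)


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "format": "orfsvm-model-1",
        "feature_order": FEATURE_ORDER_VERSION,
        "selection": list(model.selection),
        "step": model.step,
        "C": model.C,
        "w_ratio": model.w_ratio,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "scaler_min": None if model.scaler is None else model.scaler.mins.tolist(),
        "scaler_max": None if model.scaler is None else model.scaler.maxs.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("feature_order") != FEATURE_ORDER_VERSION:
        raise ValueError(
            f"model was saved with feature ordering {payload.get('feature_order')!r}; "
            f"this build uses {FEATURE_ORDER_VERSION!r}"
        )
    scaler = None
    if payload["scaler_min"] is not None:
        scaler = ScalingModel(
            mins=np.array(payload["scaler_min"]), maxs=np.array(payload["scaler_max"])
        )
    return TrainedModel(
        weights=np.array(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        C=float(payload["C"]),
        w_ratio=float(payload["w_ratio"]),
        scaler=scaler,
        selection=tuple(payload["selection"]),
        step=int(payload["step"]),
    )
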