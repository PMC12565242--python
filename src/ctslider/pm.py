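"""Position-marker (PM) dataset construction, slice classifier, peak mining.

Three anatomical position markers anchor slice selection in each CT case:
the apical lung onset (upper), the tracheal bifurcation (middle) and the
upper diaphragm (lower).  Since each case contributes exactly one slice per
marker class, the slice-classification dataset is severely imbalanced; it is
rebalanced by randomly discarding 75% of non-marker slices and oversampling
each marker class up to the retained non-marker count.

At inference, peak slice mining (PSM) turns the classifier's per-slice
confidences into one selected slice per marker class: confidences are
softmax-normalised *along the slice axis* independently per class, and the
argmax slice is taken (ties to the smallest index).  Selection is invariant
to the softmax, which is kept for reporting calibrated per-slice
probabilities.

Marker extraction is scored with 1-Up-Down accuracy: a prediction within one
slice of the ground truth counts as correct, since neighbouring slices carry
nearly identical anatomy at 4 mm spacing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .preprocess import resize_image

__all__ = [
    "PM_CLASSES",
    "PMAnnotation",
    "SliceClassDataset",
    "PMSelection",
    "build_balanced_dataset",
    "PMExtractor",
    "train_pm_extractor",
    "psm_select",
    "one_up_down_accuracy",
    "deviation_profile",
]

PM_CLASSES = ("upper", "middle", "lower", "non_pm")


@dataclass(frozen=True)
class PMAnnotation:
    """The three marker slice indices of one case (0-based)."""

    case_id: str
    upper: int
    middle: int
    lower: int

    def __post_init__(self):
        if not 0 <= self.upper < self.middle < self.lower:
            raise ValueError(
                f"{self.case_id}: marker indices must satisfy "
                f"0 <= upper < middle < lower, got "
                f"({self.upper}, {self.middle}, {self.lower})")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.upper, self.middle, self.lower)


@dataclass
class SliceClassDataset:
    """Balanced slice-classification records plus per-class loss weights."""

    records: pd.DataFrame          # case_id, slice_index, pm_class, augment
    class_weights: dict[str, float]


@dataclass
class PMSelection:
    """PSM output: one peak slice per marker class with its probability."""

    case_id: str
    indices: tuple[int, int, int]
    peak_probs: tuple[float, float, float]

    @property
    def upper(self) -> int:
        return self.indices[0]

    @property
    def middle(self) -> int:
        return self.indices[1]

    @property
    def lower(self) -> int:
        return self.indices[2]


def build_balanced_dataset(annotations: list[PMAnnotation],
                           n_slices: list[int] | int,
                           seed: int = 0,
                           downsample_frac: float = 0.75) -> SliceClassDataset:
    """Rebalance marker vs non-marker slices.

    Non-marker slices are randomly downsampled by ``downsample_frac``
    (default: remove 75%, retain 25%); each marker class is then oversampled
    (replicated, replicas flagged for augmentation) until its count matches
    the retained non-marker count.
    """
    if not 0.0 <= downsample_frac < 1.0:
        raise ValueError(f"downsample_frac must be in [0, 1), got {downsample_frac}")
    if isinstance(n_slices, int):
        n_slices = [n_slices] * len(annotations)
    if len(n_slices) != len(annotations):
        raise ValueError("annotations and n_slices length mismatch")

    rng = np.random.default_rng(seed)
    non_pm: list[tuple[str, int]] = []
    per_class: dict[str, list[tuple[str, int]]] = {c: [] for c in PM_CLASSES[:3]}
    for ann, m in zip(annotations, n_slices):
        if m < 4:
            raise ValueError(f"{ann.case_id}: need at least 4 slices, got {m}")
        if ann.lower > m - 1:
            raise ValueError(f"{ann.case_id}: lower marker {ann.lower} outside volume of {m} slices")
        pm_idx = {ann.upper: "upper", ann.middle: "middle", ann.lower: "lower"}
        for idx in range(m):
            cls = pm_idx.get(idx)
            if cls is None:
                non_pm.append((ann.case_id, idx))
            else:
                per_class[cls].append((ann.case_id, idx))

    n_keep = int(round((1.0 - downsample_frac) * len(non_pm)))
    keep_idx = rng.choice(len(non_pm), size=n_keep, replace=False)
    rows = [(cid, idx, "non_pm", False) for cid, idx in
            (non_pm[i] for i in sorted(keep_idx))]
    for cls in PM_CLASSES[:3]:
        base = per_class[cls]
        reps = int(np.ceil(n_keep / len(base)))
        pool = (base * reps)[:n_keep]
        rows.extend((cid, idx, cls, i >= len(base)) for i, (cid, idx) in enumerate(pool))

    records = pd.DataFrame(rows, columns=["case_id", "slice_index", "pm_class", "augment"])
    counts = records["pm_class"].value_counts()
    total = len(records)
    weights = {c: total / (len(PM_CLASSES) * counts[c]) for c in PM_CLASSES}
    return SliceClassDataset(records=records, class_weights=weights)


class PMExtractor(BaseEstimator, ClassifierMixin):
    """Slice classifier over the four classes (upper, middle, lower, non-PM).

    A three-block strided CNN trained with weighted cross-entropy and Adam;
    inputs are single-channel images normalised to [0, 1] and resized to
    ``input_size``.  The production-scale configuration in the source study
    used a large pretrained CNN at 256 px; this compact backbone keeps the
    identical interface at a size trainable on CPU.
    """

    def __init__(self, input_size: int = 64, channels: tuple[int, ...] = (8, 16, 32),
                 epochs: int = 10, batch_size: int = 128, lr: float = 1e-3,
                 class_weight: dict[str, float] | None = None, seed: int = 0,
                 augment_shift: int = 2):
        self.input_size = input_size
        self.channels = channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.class_weight = class_weight
        self.seed = seed
        self.augment_shift = augment_shift

    # -- internal network ---------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        chans = (1,) + tuple(self.channels)
        self._convs = [
            _nn.Conv2d(chans[i], chans[i + 1], kernel=3, stride=2, rng=rng,
                       padding=1, name=f"conv{i}") for i in range(len(self.channels))
        ]
        self._acts = [_nn.ReLU() for _ in self._convs]
        # head sees mean- and max-pooled features: the mean carries area/size
        # cues, the max carries presence cues for small structures (bronchial
        # lumens, gas bubbles) that vanish under averaging
        self._head = _nn.Linear(2 * chans[-1], len(PM_CLASSES), rng, name="head")

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, None, :, :]
        for conv, act in zip(self._convs, self._acts):
            h = act.forward(conv.forward(h))
        n, c, hh, ww = h.shape
        self._gap_shape = h.shape
        flat = h.reshape(n, c, hh * ww)
        self._argmax = np.argmax(flat, axis=2)
        pooled = np.concatenate([flat.mean(axis=2),
                                 np.take_along_axis(flat, self._argmax[:, :, None],
                                                    axis=2)[:, :, 0]], axis=1)
        return self._head.forward(pooled)

    def _backward(self, glogits: np.ndarray) -> None:
        gpool = self._head.backward(glogits)
        n, c, hh, ww = self._gap_shape
        gmean, gmax = gpool[:, :c], gpool[:, c:]
        gh = np.broadcast_to(gmean[:, :, None], (n, c, hh * ww)) / (hh * ww)
        gh = gh.copy()
        np.put_along_axis(gh, self._argmax[:, :, None],
                          np.take_along_axis(gh, self._argmax[:, :, None], axis=2)
                          + gmax[:, :, None], axis=2)
        gh = gh.reshape(n, c, hh, ww)
        for conv, act in zip(reversed(self._convs), reversed(self._acts)):
            gh = conv.backward(act.backward(gh))

    def _params(self) -> list[_nn.Parameter]:
        out = []
        for m in (*self._convs, self._head):
            out.extend(m.parameters())
        return out

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"expected (n, h, w) image array, got shape {X.shape}")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            X = np.stack([resize_image(img, self.input_size) for img in X])
        return np.clip(X, 0.0, 1.0)

    # -- estimator API ------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, augment: np.ndarray | None = None):
        y = self._encode_labels(y)
        missing = set(range(len(PM_CLASSES))) - set(np.unique(y).tolist())
        if missing:
            names = [PM_CLASSES[i] for i in sorted(missing)]
            raise ValueError(f"classes absent from training data: {names}")
        X = self._prepare(X)
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        self.classes_ = np.arange(len(PM_CLASSES))
        if self.class_weight is not None:
            w = np.array([self.class_weight[c] for c in PM_CLASSES])
        else:
            w = None
        params = self._params()
        opt = _nn.Adam(params, lr=self.lr)
        n = len(X)
        aug = np.zeros(n, dtype=bool) if augment is None else np.asarray(augment, dtype=bool)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx].copy()
                flags = aug[idx]
                if flags.any() and self.augment_shift > 0:
                    for j in np.nonzero(flags)[0]:
                        dy, dx = rng.integers(-self.augment_shift, self.augment_shift + 1, 2)
                        xb[j] = np.roll(xb[j], (dy, dx), axis=(0, 1))
                    xb[flags] = np.clip(
                        xb[flags] + rng.normal(0, 0.01, xb[flags].shape), 0, 1)
                logits = self._forward(xb)
                loss, glogits = _nn.softmax_cross_entropy(logits, y[idx], w)
                for p in params:
                    p.grad[...] = 0.0
                self._backward(glogits)
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
        self.n_features_in_ = self.input_size * self.input_size
        return self

    @staticmethod
    def _encode_labels(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "OU":
            lookup = {c: i for i, c in enumerate(PM_CLASSES)}
            y = np.array([lookup[str(v)] for v in y])
        return y.astype(int)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Raw per-slice logits over the four classes, shape (n, 4)."""
        if not hasattr(self, "_head"):
            raise RuntimeError("PMExtractor is not fitted")
        return self._forward(self._prepare(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.decision_function(X), axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision_function(X), axis=-1)


def train_pm_extractor(dataset: SliceClassDataset, image_loader,
                       config: dict | None = None) -> PMExtractor:
    """Fit a :class:`PMExtractor` on a balanced dataset.

    ``image_loader(case_id, slice_index)`` must return one 2D slice image in
    [0, 1].  ``config`` keys override the estimator defaults (epochs,
    batch_size, lr, input_size, channels, seed); class weights default to
    the dataset's inverse-frequency weights.
    """
    if len(dataset.records) == 0:
        raise ValueError("empty dataset")
    cfg = dict(config or {})
    cfg.setdefault("class_weight", dataset.class_weights)
    est = PMExtractor(**cfg)
    X = np.stack([image_loader(r.case_id, r.slice_index)
                  for r in dataset.records.itertuples()])
    y = dataset.records["pm_class"].to_numpy()
    return est.fit(X, y, augment=dataset.records["augment"].to_numpy())


def psm_select(confidences: np.ndarray, case_id: str = "") -> PMSelection:
    """Peak slice mining over a per-case confidence matrix.

    ``confidences`` has shape (M, 3) of marker-class columns, or (M, 4) with
    a trailing non-marker column that is excluded before selection.  Each
    column is softmax-normalised across slices and its argmax slice selected
    (ties to the smallest index).
    """
    c = np.asarray(confidences, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] not in (3, 4):
        raise ValueError(f"expected (M, 3) or (M, 4) confidences, got shape {c.shape}")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite confidences")
    c = c[:, :3]
    probs = _nn.softmax(c, axis=0)
    indices = tuple(int(np.argmax(probs[:, k])) for k in range(3))
    peaks = tuple(float(probs[indices[k], k]) for k in range(3))
    if not indices[0] < indices[1] < indices[2]:
        warnings.warn(f"selected marker slices are not in anatomical order: {indices}",
                      stacklevel=2)
    return PMSelection(case_id=case_id, indices=indices, peak_probs=peaks)


def one_up_down_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of predictions within one slice of the ground truth."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("need equal-length non-empty paired index lists")
    return float(np.mean(np.abs(predicted - truth) <= 1))


def deviation_profile(predicted: np.ndarray, truth: np.ndarray) -> dict[int, int]:
    """Histogram of signed slice offsets (predicted - truth)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("paired lists must have equal length")
    return dict(sorted(Counter((predicted - truth).tolist()).items()))
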