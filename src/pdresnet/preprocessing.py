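"""Tabular-to-image preprocessing for the gait classifier.

The stages, in pipeline order: SMOTE minority oversampling on the raw
feature table, per-feature min-max normalization fitted on the training
partition, degree-2 polynomial elevation of the 194 features to a
117x117-shaped vector, row-major reshape to a single-channel image,
bilinear resize to 112x112, a stratified 70/30 split, random-erasing
augmentation (training batches only) and batching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler

from .cohort import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "SmoteParams",
    "ElevationSpec",
    "EraseParams",
    "SplitIndices",
    "Normalizer",
    "smote_balance",
    "polynomial_elevate",
    "elevated_term_count",
    "to_image",
    "flatten_image",
    "resize_image",
    "split_train_test",
    "random_erase",
    "make_batches",
    "infer_feature_columns",
]

NON_FEATURE_COLUMNS = ("subject_id", "diagnosis", "severity", "synthetic")


def infer_feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a cohort-style table (everything but bookkeeping)."""
    return [c for c in table.columns if c not in NON_FEATURE_COLUMNS]


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoteParams:
    """SMOTE settings: number of minority neighbours and RNG seed."""
    k_neighbors: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


def smote_balance(table: pd.DataFrame, params: SmoteParams | None = None,
                  label_col: str = "diagnosis") -> pd.DataFrame:
    """Balance a two-class table by synthetic minority oversampling.

    Each synthetic row is ``x + u * (x_nn - x)`` for a minority row ``x``,
    one of its ``k`` Euclidean nearest minority neighbours ``x_nn``, and
    ``u ~ Uniform(0, 1)``. Original rows are returned unchanged (flagged
    ``synthetic = False``); synthetic rows are appended with
    ``synthetic = True`` and inherit all non-feature columns from their
    seed row.
    """
    params = params or SmoteParams()
    params.validate()
    classes = table[label_col].value_counts()
    if len(classes) != 2:
        raise ValueError(
            f"smote_balance needs exactly two classes in {label_col!r}, "
            f"found {len(classes)}: {list(classes.index)}")
    minority_label = classes.idxmin()
    n_min, n_maj = int(classes.min()), int(classes.max())
    out = table.copy()
    out["synthetic"] = False
    if n_min == n_maj:
        return out
    if n_min <= params.k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples but k_neighbors="
            f"{params.k_neighbors}; choose k < {n_min}")

    feats = infer_feature_columns(table)
    minority = table[table[label_col] == minority_label]
    X = minority[feats].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(params.seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, params.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = X[base]
    x_nn = X[neigh[base, pick]]
    synth_feats = x + u[:, None] * (x_nn - x)

    parents = minority.iloc[base].reset_index(drop=True)
    other_cols = [c for c in table.columns if c not in feats]
    synth = pd.concat([pd.DataFrame(synth_feats, columns=feats),
                       parents[other_cols]], axis=1)[list(table.columns)].copy()
    synth["subject_id"] = [f"syn_{i + 1:04d}" for i in range(n_new)]
    synth["synthetic"] = True
    return pd.concat([out, synth], ignore_index=True)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class Normalizer:
    """Per-feature min-max scaler to [0, 1], fitted on training rows only.

    Constant features map to 0; values outside the fitted range (e.g. on
    test rows) are clipped into [0, 1].
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=True)
        self._fitted = False

    def fit(self, features: np.ndarray | pd.DataFrame) -> "Normalizer":
        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError("fit expects a 2-D (rows x features) array")
        self._scaler.fit(X)
        self._fitted = True
        return self

    def transform(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("Normalizer.transform called before fit")
        X = np.asarray(features, dtype=float)
        squeeze = X.ndim == 1
        out = self._scaler.transform(np.atleast_2d(X))
        return out[0] if squeeze else out


def fit_normalizer(train_features) -> Normalizer:
    return Normalizer().fit(train_features)


def apply_normalizer(normalizer: Normalizer, features) -> np.ndarray:
    return normalizer.transform(features)


# ---------------------------------------------------------------------------
# Polynomial elevation and image conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElevationSpec:
    """Degree-2 polynomial elevation with a fixed, reproducible term order.

    Terms are emitted as: original features, (optionally) their squares,
    then pairwise products x_i * x_j with (i, j) lexicographic for i < j.
    The output is truncated to the first ``target_side ** 2`` terms or
    zero-padded up to that length.
    """
    degree: int = 2
    include_squares: bool = True
    include_bias: bool = False
    target_side: int = 117

    def validate(self) -> None:
        if self.degree != 2:
            raise ValueError("only degree-2 elevation is supported")
        if self.target_side < 1:
            raise ValueError(f"target_side must be >= 1, got {self.target_side}")


def elevated_term_count(n_features: int, spec: ElevationSpec) -> int:
    """Number of generated terms before truncation/padding."""
    n = n_features
    count = n + n * (n - 1) // 2
    if spec.include_squares:
        count += n
    if spec.include_bias:
        count += 1
    return count


def polynomial_elevate(features: np.ndarray, spec: ElevationSpec | None = None
                       ) -> np.ndarray:
    """Elevate feature vectors to length ``target_side ** 2``.

    Accepts a single vector or a (rows x features) matrix; returns the
    elevated vector(s) with matching leading shape.
    """
    spec = spec or ElevationSpec()
    spec.validate()
    X = np.asarray(features, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("polynomial_elevate requires finite inputs")
    n_rows, n_feat = X.shape
    parts = []
    if spec.include_bias:
        parts.append(np.ones((n_rows, 1)))
    parts.append(X)
    if spec.include_squares:
        parts.append(X ** 2)
    i, j = np.triu_indices(n_feat, k=1)
    parts.append(X[:, i] * X[:, j])
    full = np.concatenate(parts, axis=1)

    length = spec.target_side ** 2
    if full.shape[1] >= length:
        out = full[:, :length]
    else:
        out = np.zeros((n_rows, length))
        out[:, :full.shape[1]] = full
    return out[0] if squeeze else out


def to_image(vector: np.ndarray, side: int) -> np.ndarray:
    """Row-major reshape of a length ``side**2`` vector to a square image."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size != side * side:
        raise ValueError(
            f"to_image expects a flat vector of length {side * side}, "
            f"got shape {v.shape}")
    return v.reshape(side, side)


def flatten_image(image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_image` (row-major)."""
    return np.asarray(image, dtype=float).reshape(-1)


def resize_image(image: np.ndarray, new_side: int = 112) -> np.ndarray:
    """Bilinear, corner-aligned resize of square image(s).

    Sampling positions are ``i * (side - 1) / (new_side - 1)`` so the four
    corners are preserved; constant images stay constant. Leading batch
    dimensions are broadcast (shape ``(..., side, side)``).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim < 2 or img.shape[-1] != img.shape[-2]:
        raise ValueError("resize_image expects square image(s)")
    side = img.shape[-1]
    if side < 2:
        raise ValueError("resize_image requires image side >= 2")
    if new_side < 1:
        raise ValueError(f"new_side must be >= 1, got {new_side}")
    if new_side == 1:
        src = np.array([0.0])
    else:
        src = np.arange(new_side) * (side - 1) / (new_side - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, side - 1)
    f = src - i0

    # Separate gather along rows then columns (direct 2-D bilinear weights).
    ry0, ry1, fy = i0[:, None], i1[:, None], f[:, None]
    cx0, cx1, fx = i0[None, :], i1[None, :], f[None, :]
    a = img[..., ry0, cx0]
    b = img[..., ry0, cx1]
    c = img[..., ry1, cx0]
    d = img[..., ry1, cx1]
    return ((1 - fy) * (1 - fx) * a + (1 - fy) * fx * b
            + fy * (1 - fx) * c + fy * fx * d)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices covering the whole table."""
    train_ids: np.ndarray
    test_ids: np.ndarray
    test_fraction: float
    stratified: bool
    seed: int


def split_train_test(n: int, test_fraction: float = 0.3, stratified: bool = True,
                     seed: int = 0, labels: np.ndarray | None = None
                     ) -> SplitIndices:
    """Stratified random split; test size is the nearest-integer round of
    ``n * test_fraction`` (so 592 rows at 0.3 give a 178-sample test set).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if stratified and labels is None:
        raise ValueError("stratified split requires labels")
    n_test = int(np.floor(n * test_fraction + 0.5))
    strat = np.asarray(labels) if stratified else None
    if strat is not None and len(np.unique(strat)) < 2:
        raise ValueError("stratified split requires both classes present")
    train_ids, test_ids = train_test_split(
        np.arange(n), test_size=n_test, stratify=strat, random_state=seed)
    return SplitIndices(np.sort(train_ids), np.sort(test_ids),
                        test_fraction, stratified, seed)


# ---------------------------------------------------------------------------
# Random erasing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EraseParams:
    """Random-erasing augmentation settings.

    Defaults follow the original random-erasing recipe: apply with
    probability 0.5, rectangle area 2-33% of the image, aspect ratio in
    (0.3, 3.3), uniform-random fill on the normalized [0, 1] scale.
    """
    probability: float = 0.5
    area_ratio_range: tuple[float, float] = (0.02, 0.33)
    aspect_ratio_range: tuple[float, float] = (0.3, 3.3)
    fill_rule: str = "uniform-random"

    def validate(self) -> None:
        lo, hi = self.area_ratio_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"area_ratio_range must satisfy 0 <= lo <= hi <= 1, "
                             f"got {self.area_ratio_range}")
        alo, ahi = self.aspect_ratio_range
        if not (alo > 0 and ahi >= alo):
            raise ValueError(f"aspect_ratio_range bounds must be positive, "
                             f"got {self.aspect_ratio_range}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0, 1], got {self.probability}")
        if self.fill_rule not in ("uniform-random", "mean", "zero"):
            raise ValueError(f"unknown fill_rule {self.fill_rule!r}")


def random_erase(image: np.ndarray, params: EraseParams | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Overwrite one random rectangle of the image (training-time only).

    With probability ``params.probability`` a rectangle whose area and
    aspect ratio are drawn from the configured ranges (rejection-sampled
    to fit, 100 attempts) is filled per ``fill_rule``; pixels outside it
    are untouched. Returns a new array.
    """
    params = params or EraseParams()
    params.validate()
    rng = rng if rng is not None else np.random.default_rng()
    img = np.array(image, dtype=float, copy=True)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("random_erase expects a 2-D image with side >= 2")
    if rng.uniform() >= params.probability:
        return img
    H, W = img.shape
    area = H * W
    for _ in range(100):
        target = rng.uniform(*params.area_ratio_range) * area
        aspect = rng.uniform(*params.aspect_ratio_range)
        h = int(round(np.sqrt(target * aspect)))
        w = int(round(np.sqrt(target / aspect)))
        if 1 <= h <= H and 1 <= w <= W:
            top = int(rng.integers(0, H - h + 1))
            left = int(rng.integers(0, W - w + 1))
            if params.fill_rule == "uniform-random":
                fill = rng.uniform(0.0, 1.0, size=(h, w))
            elif params.fill_rule == "mean":
                fill = img.mean()
            else:
                fill = 0.0
            img[top:top + h, left:left + w] = fill
            return img
    logger.warning("random_erase: no feasible rectangle after 100 attempts; "
                   "image returned unchanged")
    return img


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def make_batches(indices: np.ndarray, batch_size: int = 23, shuffle: bool = True,
                 rng: np.random.Generator | int | None = None) -> list[np.ndarray]:
    """Partition indices into consecutive batches (last one may be short)."""
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    idx = np.asarray(indices).copy()
    if idx.size == 0:
        raise ValueError("make_batches received an empty index set")
    if shuffle:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        rng.shuffle(idx)
    return [idx[i:i + batch_size] for i in range(0, idx.size, batch_size)]


# Convenience re-export so callers can reason about the default schema size.
def default_feature_count() -> int:
    return len(feature_columns())
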