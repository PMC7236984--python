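"""Epsilon-SVR quality regression and the split/iterate training protocol.

The 36 NSS features of each image are mapped to its mean opinion score
with an epsilon-SVR (radial-basis kernel, cost C = 512, kernel width
g = 0.25, ε = 0.1 by default). Training follows the randomized-split
protocol: the feature/MOS rows are permuted, 80% train the model and the
held-out 20% are scored with PLCC and RMSE; the procedure is iterated
(100 times by default) and the medians of the per-iteration PLCC and
RMSE summarize performance. The retained model is the iteration whose
PLCC sits at the lower median rank.

Features are min–max scaled to [−1, 1] with parameters computed on the
training split only, so no information leaks from the held-out rows.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .errors import JoinError
from .evaluation import plcc as _plcc
from .evaluation import rmse as _rmse

__all__ = ["ProtocolResult", "TrainedModel", "predict", "run_protocol", "train_svr"]

DEFAULT_C = 512.0
DEFAULT_G = 0.25
DEFAULT_EPSILON = 0.1

_FEATURE_COLS = [f"f{i}" for i in range(1, 37)]


def _fingerprint(columns: Sequence[str]) -> str:
    return hashlib.sha256(",".join(columns).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted epsilon-SVR with its feature scaling and provenance.

    ``feature_min``/``feature_max`` are the per-feature training-split
    extrema of the min–max map to [−1, 1]; ``fingerprint`` hashes the
    feature-column order so a model can refuse mismatched tables.
    """

    svr: SVR
    feature_min: np.ndarray
    feature_max: np.ndarray
    feature_columns: List[str]
    fingerprint: str
    C: float = DEFAULT_C
    g: float = DEFAULT_G
    epsilon: float = DEFAULT_EPSILON

    @property
    def hyperparameters(self) -> dict:
        return {"C": self.C, "g": self.g, "epsilon": self.epsilon, "kernel": "rbf"}

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        span = np.where(span > 0, span, 1.0)  # constant feature -> midpoint
        return 2.0 * (X - self.feature_min) / span - 1.0

    def save(self, path) -> None:
        state = {
            "format": "woodiqa-svr-v1",
            "svr": self.svr,
            "feature_min": self.feature_min,
            "feature_max": self.feature_max,
            "feature_columns": self.feature_columns,
            "fingerprint": self.fingerprint,
            "C": self.C,
            "g": self.g,
            "epsilon": self.epsilon,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        if state.get("format") != "woodiqa-svr-v1":
            raise ValueError(f"{path}: not a woodiqa model file")
        state.pop("format")
        return cls(**state)


def _join_features_targets(features: pd.DataFrame, targets: pd.DataFrame):
    if "image_id" not in features.columns or "image_id" not in targets.columns:
        raise JoinError("both tables need an image_id column")
    feat_cols = [c for c in features.columns if c != "image_id"]
    f_ids = set(features["image_id"].astype(str))
    t_ids = set(targets["image_id"].astype(str))
    unmatched = sorted(f_ids ^ t_ids)
    if unmatched:
        raise JoinError(f"unmatched image ids between features and targets: {unmatched}", unmatched)
    target_col = "mos" if "mos" in targets.columns else targets.columns[1]
    merged = features.merge(targets[["image_id", target_col]], on="image_id")
    merged = merged.sort_values("image_id", kind="stable").reset_index(drop=True)
    X = merged[feat_cols].to_numpy(dtype=float)
    y = merged[target_col].to_numpy(dtype=float)
    ids = merged["image_id"].astype(str).tolist()
    return X, y, ids, feat_cols


def _fit(X: np.ndarray, y: np.ndarray, feat_cols, C, g, epsilon) -> TrainedModel:
    fmin = X.min(axis=0)
    fmax = X.max(axis=0)
    model = TrainedModel(
        svr=SVR(kernel="rbf", C=C, gamma=g, epsilon=epsilon),
        feature_min=fmin,
        feature_max=fmax,
        feature_columns=list(feat_cols),
        fingerprint=_fingerprint(feat_cols),
        C=C,
        g=g,
        epsilon=epsilon,
    )
    model.svr.fit(model.scale(X), y)
    return model


def train_svr(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    C: float = DEFAULT_C,
    g: float = DEFAULT_G,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
) -> TrainedModel:
    """Fit an epsilon-SVR on all paired rows of a feature and target table.

    Rows are joined on ``image_id`` (an error lists any unmatched ids)
    and sorted canonically by id, so permuting the input row order does
    not change the fit. ``seed`` is accepted for interface symmetry; the
    deterministic libsvm fit does not consume randomness.
    """
    X, y, _, feat_cols = _join_features_targets(features, targets)
    if len(y) < 10:
        raise ValueError(f"need at least 10 paired rows to train, got {len(y)}")
    if np.any(y < 1.0) or np.any(y > 5.0):
        raise ValueError("targets must lie within the 1..5 opinion scale")
    return _fit(X, y, feat_cols, C, g, epsilon)


def predict(model: TrainedModel, features: pd.DataFrame, clamp: bool = False) -> pd.DataFrame:
    """Score feature rows with a trained model.

    Returns a DataFrame ``image_id, score`` with raw SVR outputs (no
    clamping unless ``clamp=True``, which also adds a ``score_clamped``
    column restricted to [1, 5]).
    """
    feat_cols = [c for c in features.columns if c != "image_id"]
    if feat_cols != model.feature_columns or _fingerprint(feat_cols) != model.fingerprint:
        raise ValueError(
            f"feature columns {feat_cols[:3]}...({len(feat_cols)}) do not match the "
            f"model's fingerprint over {len(model.feature_columns)} columns"
        )
    out = pd.DataFrame({"image_id": features["image_id"].astype(str)})
    if len(features) == 0:
        out["score"] = pd.Series(dtype=float)
        return out
    X = features[feat_cols].to_numpy(dtype=float)
    out["score"] = model.svr.predict(model.scale(X))
    if clamp:
        out["score_clamped"] = out["score"].clip(1.0, 5.0)
    return out


@dataclass
class ProtocolResult:
    """Outcome of the iterated random-split protocol."""

    plcc: List[float]
    rmse: List[float]
    median_plcc: float
    median_rmse: float
    selected_model: TrainedModel
    selected_iteration: int

    def __post_init__(self):
        assert np.isclose(self.median_plcc, float(np.median(self.plcc)))
        assert np.isclose(self.median_rmse, float(np.median(self.rmse)))


def _median_rank_index(values: List[float]) -> int:
    """Index of the iteration holding the (lower) median order statistic."""
    order = np.argsort(values, kind="stable")
    n = len(values)
    rank = (n - 1) // 2  # lower median for even n, middle for odd
    return int(order[rank])


def run_protocol(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    C: float = DEFAULT_C,
    g: float = DEFAULT_G,
    epsilon: float = DEFAULT_EPSILON,
    n_iter: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    group_by: Optional[pd.DataFrame] = None,
) -> ProtocolResult:
    """Run the iterated 80/20 random-split training protocol.

    Each iteration draws an independent random permutation of the rows,
    trains on the first ``train_frac`` share and evaluates PLCC and RMSE
    on the held-out remainder. The medians over ``n_iter`` iterations
    summarize performance, and the model refitted on the split whose
    PLCC attains the lower-median rank is retained.

    ``group_by`` (optional, columns ``image_id, reference_id``) switches
    to a leakage-safe split: whole reference groups are assigned to one
    side, so distorted versions of a reference never straddle the split.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie strictly between 0 and 1")
    X, y, ids, feat_cols = _join_features_targets(features, targets)
    n = len(y)

    groups = None
    if group_by is not None:
        mapping = dict(
            zip(group_by["image_id"].astype(str), group_by["reference_id"].astype(str))
        )
        groups = np.asarray([mapping[i] for i in ids])

    rng = np.random.default_rng(seed)
    plcc_list: List[float] = []
    rmse_list: List[float] = []
    splits: List[np.ndarray] = []
    for _ in range(n_iter):
        if groups is None:
            perm = rng.permutation(n)
            n_train = int(round(train_frac * n))
            if n_train == 0 or n_train == n:
                raise ValueError("split leaves one side empty; add rows or adjust train_frac")
            train_idx = perm[:n_train]
            test_idx = perm[n_train:]
        else:
            uniq = np.unique(groups)
            gperm = rng.permutation(len(uniq))
            n_train_g = int(round(train_frac * len(uniq)))
            if n_train_g == 0 or n_train_g == len(uniq):
                raise ValueError("group split leaves one side empty")
            train_groups = set(uniq[gperm[:n_train_g]])
            mask = np.array([g_ in train_groups for g_ in groups])
            train_idx = np.flatnonzero(mask)
            test_idx = np.flatnonzero(~mask)
        model = _fit(X[train_idx], y[train_idx], feat_cols, C, g, epsilon)
        pred = model.svr.predict(model.scale(X[test_idx]))
        plcc_list.append(_plcc(y[test_idx], pred))
        rmse_list.append(_rmse(y[test_idx], pred))
        splits.append(train_idx)

    sel = _median_rank_index(plcc_list)
    selected = _fit(X[splits[sel]], y[splits[sel]], feat_cols, C, g, epsilon)
    return ProtocolResult(
        plcc=plcc_list,
        rmse=rmse_list,
        median_plcc=float(np.median(plcc_list)),
        median_rmse=float(np.median(rmse_list)),
        selected_model=selected,
        selected_iteration=sel,
    )
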