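"""Comparison one-class classifiers: Parzen window, k-means variants, ocSVM.

All distance-based baselines share OCKRA's Gaussian kernel
exp(−½ (d/h)²) and the same 60-second-subsample width rule, so the methods
differ only in their reference-point sets: every training point (Parzen),
the nearest of k cluster centres (k-means1), or all k centres averaged
(k-means2).  The one-class SVM is an adapter over an established
implementation, as in the original comparison, with RBF kernel and the
LibSVM-style defaults γ=0.038, ν=0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ockra.core import compute_threshold, kmeanspp_fit, member_similarity
from ockra.preprocess import LabeledDataset


@dataclass
class ParzenModel:
    """Kernel scorer with one window of width ``width`` per training point."""

    training_points: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.training_points = np.atleast_2d(np.asarray(self.training_points, dtype=float))
        if not self.width > 0:
            raise ValueError("width must be positive")


@dataclass
class CentroidModel:
    """Kernel scorer over k-means++ centres; ``mode`` picks nearest vs. all."""

    centroids: np.ndarray
    width: float
    mode: str = "closest_center"

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.mode not in ("closest_center", "all_centers"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _as_matrix(T):
    if isinstance(T, LabeledDataset):
        return T.X, T.timestamps
    return np.atleast_2d(np.asarray(T, dtype=float)), None


def parzen_train(T, timestamps: np.ndarray | None = None) -> ParzenModel:
    """Window width = mean pairwise distance of the 60-s subsample (OCKRA's δ rule)."""
    X, ts = _as_matrix(T)
    if timestamps is not None:
        ts = timestamps
    return ParzenModel(training_points=X, width=compute_threshold(X, ts))


def parzen_score(O, model: ParzenModel) -> np.ndarray | float:
    """Mean Gaussian kernel over all training points; in (0, 1]."""
    O = np.atleast_2d(np.asarray(O, dtype=float))
    if O.shape[1] != model.training_points.shape[1]:
        raise ValueError("query dimensionality does not match training data")
    d = cdist(O, model.training_points)
    scores = member_similarity(d, model.width).mean(axis=1)
    return float(scores[0]) if len(scores) == 1 else scores


def kmeans_baseline_train(
    T,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
    mode: str = "closest_center",
    timestamps: np.ndarray | None = None,
) -> CentroidModel:
    """Fit k-means++ centres on the training data, width per the 60-s rule."""
    X, ts = _as_matrix(T)
    if timestamps is not None:
        ts = timestamps
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    centroids = kmeanspp_fit(X, k, rng)
    return CentroidModel(centroids=centroids, width=compute_threshold(X, ts), mode=mode)


def kmeans1_score(O, model: CentroidModel) -> np.ndarray | float:
    """Kernel of the distance to the closest centre only."""
    O = np.atleast_2d(np.asarray(O, dtype=float))
    if O.shape[1] != model.centroids.shape[1]:
        raise ValueError("query dimensionality does not match centroids")
    dmin = cdist(O, model.centroids).min(axis=1)
    scores = member_similarity(dmin, model.width)
    scores = np.atleast_1d(scores)
    return float(scores[0]) if len(scores) == 1 else scores


def kmeans2_score(O, model: CentroidModel) -> np.ndarray | float:
    """Mean kernel over all centres; never exceeds the closest-centre score."""
    O = np.atleast_2d(np.asarray(O, dtype=float))
    if O.shape[1] != model.centroids.shape[1]:
        raise ValueError("query dimensionality does not match centroids")
    d = cdist(O, model.centroids)
    scores = member_similarity(d, model.width).mean(axis=1)
    return float(scores[0]) if len(scores) == 1 else scores


def ocsvm_adapter(T, gamma: float = 0.038, nu: float = 0.5):
    """One-class SVM baseline delegating to scikit-learn's OneClassSVM.

    Returns a callable mapping a query matrix to decision scores (higher =
    more normal), matching the orientation of the similarity-based methods.
    The parameters mirror the classic LibSVM defaults used in the original
    comparison.
    """
    try:
        from sklearn.svm import OneClassSVM
    except ImportError as exc:  # pragma: no cover - environment guard
        raise RuntimeError(
            "the ocSVM baseline requires scikit-learn; install it or drop "
            "'ocsvm' from the method list"
        ) from exc
    X, _ = _as_matrix(T)
    svm = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu).fit(X)

    def score(O):
        O = np.atleast_2d(np.asarray(O, dtype=float))
        return svm.decision_function(O)

    score.params = {"gamma": gamma, "nu": nu, "kernel": "rbf"}
    return score


def baseline_to_dict(model) -> dict:
    """JSON-serializable form with a ``type`` discriminator."""
    if isinstance(model, ParzenModel):
        return {
            "version": 1,
            "type": "parzen",
            "width": model.width,
            "training_points": model.training_points.tolist(),
        }
    if isinstance(model, CentroidModel):
        return {
            "version": 1,
            "type": "kmeans1" if model.mode == "closest_center" else "kmeans2",
            "width": model.width,
            "centroids": model.centroids.tolist(),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def baseline_from_dict(doc: dict):
    kind = doc.get("type")
    if kind == "parzen":
        return ParzenModel(
            training_points=np.asarray(doc["training_points"], dtype=float),
            width=float(doc["width"]),
        )
    if kind in ("kmeans1", "kmeans2"):
        return CentroidModel(
            centroids=np.asarray(doc["centroids"], dtype=float),
            width=float(doc["width"]),
            mode="closest_center" if kind == "kmeans1" else "all_centers",
        )
    raise ValueError(f"unknown model type {kind!r}")


METHODS = ("ockra", "parzen", "kmeans1", "kmeans2", "ocsvm")


def train_scorer(
    method: str,
    T,
    n_members: int = 100,
    k: int = 10,
    seed: int = 0,
    timestamps: np.ndarray | None = None,
):
    """Uniform train-then-score entry point used by the evaluation harness.

    Returns a callable ``scores = f(X)``; for every method higher means more
    normal, so evaluation can treat all scorers identically.
    """
    from ockra import core

    if method == "ockra":
        model = core.train(T, n_members=n_members, k=k, master_seed=seed, timestamps=timestamps)
        return lambda X: core.classify_batch(X, model)
    if method == "parzen":
        model = parzen_train(T, timestamps=timestamps)
        return lambda X: np.atleast_1d(parzen_score(X, model))
    if method in ("kmeans1", "kmeans2"):
        mode = "closest_center" if method == "kmeans1" else "all_centers"
        model = kmeans_baseline_train(T, k=k, rng=seed, mode=mode, timestamps=timestamps)
        scorer = kmeans1_score if method == "kmeans1" else kmeans2_score
        return lambda X: np.atleast_1d(scorer(X, model))
    if method == "ocsvm":
        return ocsvm_adapter(T)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
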