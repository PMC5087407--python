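"""The OCKRA ensemble: one-class k-means++ over random feature projections.

Training draws, for each of the ensemble members (100 by default), ``n``
feature indices uniformly *with replacement* from the ``n`` available
features and deduplicates them — retaining about 63% of the features per
member and giving the ensemble its diversity.  The training matrix is
projected onto the selected features, a per-member distance threshold δ is
computed as the mean pairwise Euclidean distance among rows subsampled at
60-second spacing, and k-means++ (k = 10 by default) clusters the projection;
the member keeps only its feature set, the k centroids and δ.

Classification projects a query onto each member's feature set, finds the
Euclidean distance d_min to the nearest centroid, converts it to a similarity
exp(−½ (d_min/δ)²) and averages over members.  A similarity near 1 means the
query resembles trained normal behavior; near 0 flags a risk-prone deviation.
The kernel gives > 0.6 for distances below δ and < 0.02 beyond 3δ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from ockra.preprocess import LabeledDataset

#: Threshold floor for degenerate (constant) training data, so identical
#: queries still score 1 and anything else scores ~0.
DELTA_FLOOR = 1e-12

_LLOYD_MAX_ITER = 100
_LLOYD_TOL = 1e-6


@dataclass
class MemberModel:
    """One ensemble member: feature subset, k-means++ centroids, threshold δ."""

    features: np.ndarray  # sorted unique 0-based feature indices
    centroids: np.ndarray  # (k', n') with n' = len(features)
    delta: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=int)
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.centroids.shape[1] != len(self.features):
            raise ValueError("centroid dimensionality must match feature count")
        if not self.delta > 0:
            raise ValueError("delta must be positive")


@dataclass
class EnsembleModel:
    members: list[MemberModel]
    k: int
    master_seed: int
    n_features: int

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_centroids(self) -> int:
        return sum(m.centroids.shape[0] for m in self.members)


def select_random_features(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` feature indices uniformly with replacement and deduplicate.

    Returns the sorted unique 0-based indices; on average about 63% of the
    features survive deduplication (exactly ``n(1 - (1 - 1/n)^n)`` in
    expectation).  Always non-empty.
    """
    if n < 1:
        raise ValueError("need at least one feature")
    return np.unique(rng.integers(0, n, size=n))


def project(X: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Column subset of ``X`` in ascending feature-index order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    features = np.asarray(features, dtype=int)
    if len(features) and (features.min() < 0 or features.max() >= X.shape[1]):
        raise IndexError(
            f"feature index out of range for {X.shape[1]}-column matrix"
        )
    return X[:, np.sort(features)]


def subsample_60s(X: np.ndarray, timestamps: np.ndarray | None = None) -> np.ndarray:
    """Keep the first row, then greedily every row ≥ 60 s after the last kept.

    Without timestamps, every 60th row is kept (the per-second feature vectors
    make the two equivalent).  Reduces m rows to roughly m/60.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if timestamps is None:
        return X[::60]
    timestamps = np.asarray(timestamps, dtype=float)
    keep = [0]
    last = timestamps[0]
    for i in range(1, len(timestamps)):
        if timestamps[i] - last >= 60.0:
            keep.append(i)
            last = timestamps[i]
    return X[np.asarray(keep)]


def compute_threshold(Xp: np.ndarray, timestamps: np.ndarray | None = None) -> float:
    """Distance threshold δ: mean pairwise Euclidean distance of the 60-s subsample.

    Falls back to the full matrix when subsampling leaves fewer than two rows;
    degenerate constant data gets a tiny positive floor instead of 0.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    if Xp.shape[0] < 2:
        raise ValueError("need at least two rows to compute a distance threshold")
    sub = subsample_60s(Xp, timestamps)
    if sub.shape[0] < 2:
        sub = Xp
    delta = float(pdist(sub).mean())
    return max(delta, DELTA_FLOOR)


def kmeanspp_fit(Xp: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding followed by Lloyd iterations, Euclidean distance.

    The first centre is drawn uniformly from the rows; each subsequent centre
    with probability proportional to the squared distance to the nearest
    chosen centre.  Lloyd runs to convergence (centroid shift < 1e-6) or 100
    iterations; an emptied cluster is re-seeded with the point farthest from
    its current centroid.  Returns ``min(k, #distinct rows)`` centroids.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    if Xp.shape[0] == 0:
        raise ValueError("cannot cluster an empty matrix")
    if k < 1:
        raise ValueError("k must be at least 1")
    n_distinct = len(np.unique(Xp, axis=0))
    k_eff = min(k, n_distinct)

    # seeding
    centers = np.empty((k_eff, Xp.shape[1]))
    centers[0] = Xp[rng.integers(0, Xp.shape[0])]
    d2 = np.sum((Xp - centers[0]) ** 2, axis=1)
    for j in range(1, k_eff):
        total = d2.sum()
        if total <= 0:  # only duplicates of chosen centers remain
            centers = centers[:j]
            break
        centers[j] = Xp[rng.choice(Xp.shape[0], p=d2 / total)]
        d2 = np.minimum(d2, np.sum((Xp - centers[j]) ** 2, axis=1))
    k_eff = centers.shape[0]

    # Lloyd
    for _ in range(_LLOYD_MAX_ITER):
        dist = cdist(Xp, centers)
        assign = dist.argmin(axis=1)  # argmin -> lowest index on ties
        new_centers = centers.copy()
        for j in range(k_eff):
            mask = assign == j
            if mask.any():
                new_centers[j] = Xp[mask].mean(axis=0)
            else:  # empty cluster: move to the worst-fit point
                farthest = dist[np.arange(len(Xp)), assign].argmax()
                new_centers[j] = Xp[farthest]
                assign[farthest] = j
        shift = np.max(np.linalg.norm(new_centers - centers, axis=1))
        centers = new_centers
        if shift < _LLOYD_TOL:
            break
    return centers


def _as_matrix(T) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(T, LabeledDataset):
        return T.X, T.timestamps  # labels never consulted
    return np.atleast_2d(np.asarray(T, dtype=float)), None


def train(
    T,
    n_members: int = 100,
    k: int = 10,
    master_seed: int = 0,
    timestamps: np.ndarray | None = None,
) -> EnsembleModel:
    """Train the ensemble on normal-behavior data ``T`` (matrix or LabeledDataset).

    Each member gets an independent child RNG spawned deterministically from
    ``master_seed``, so retraining with the same seed and data reproduces the
    model exactly, member by member.
    """
    X, ts = _as_matrix(T)
    if timestamps is not None:
        ts = np.asarray(timestamps, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("training requires at least two samples")
    if n_members < 1:
        raise ValueError("n_members must be at least 1")
    children = np.random.SeedSequence(master_seed).spawn(n_members)
    members = []
    for child in children:
        rng = np.random.default_rng(child)
        feats = select_random_features(X.shape[1], rng)
        Xp = project(X, feats)
        delta = compute_threshold(Xp, ts)
        centroids = kmeanspp_fit(Xp, k, rng)
        members.append(MemberModel(features=feats, centroids=centroids, delta=delta))
    return EnsembleModel(members=members, k=k, master_seed=master_seed, n_features=X.shape[1])


def member_similarity(dmin, delta: float):
    """Gaussian kernel of nearest-centroid distance: exp(−½ (d_min/δ)²).

    Strictly decreasing in ``dmin``; 1 at zero distance, ≈0.6065 at δ and
    ≈0.0111 at 3δ.  Accepts scalars or arrays of distances.
    """
    if not delta > 0:
        raise ValueError("delta must be positive")
    dmin = np.asarray(dmin, dtype=float)
    if np.any(dmin < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-0.5 * (dmin / delta) ** 2)
    return float(out) if out.ndim == 0 else out


def classify_batch(X, model: EnsembleModel) -> np.ndarray:
    """Ensemble similarity score in [0, 1] for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"query has {X.shape[1]} features, model was trained on {model.n_features}"
        )
    s = np.zeros(X.shape[0])
    for member in model.members:
        dmin = cdist(X[:, member.features], member.centroids).min(axis=1)
        s += member_similarity(dmin, member.delta)
    return s / model.n_members


def classify(o, model: EnsembleModel) -> float:
    """Similarity of a single query: 1 ⇒ normal behavior, 0 ⇒ risk-prone."""
    return float(classify_batch(np.atleast_2d(o), model)[0])


# --- serialization ---------------------------------------------------------

_FORMAT_VERSION = 1


def model_to_dict(model: EnsembleModel) -> dict:
    return {
        "version": _FORMAT_VERSION,
        "type": "ockra",
        "n": model.n_features,
        "k": model.k,
        "master_seed": model.master_seed,
        "members": [
            {
                "features": m.features.tolist(),
                "delta": m.delta,
                "centroids": m.centroids.tolist(),
            }
            for m in model.members
        ],
    }


def model_from_dict(doc: dict) -> EnsembleModel:
    members = [
        MemberModel(
            features=np.asarray(m["features"], dtype=int),
            centroids=np.asarray(m["centroids"], dtype=float),
            delta=float(m["delta"]),
        )
        for m in doc["members"]
    ]
    return EnsembleModel(
        members=members,
        k=int(doc["k"]),
        master_seed=int(doc["master_seed"]),
        n_features=int(doc["n"]),
    )


def save_model(model: EnsembleModel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path) -> EnsembleModel:
    return model_from_dict(json.loads(Path(path).read_text()))
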