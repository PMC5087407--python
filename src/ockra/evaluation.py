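"""Per-subject cross-validated ROC / precision-recall evaluation.

The anomaly ("atypical") class is the positive class throughout.  Classifier
outputs are similarities — near 1 for normal behavior, near 0 for risk — so a
query is called positive when its score falls at or below the sweep
threshold.  Curves are built with a single sorted pass over the scores in the
style of Fawcett's ROC construction (one operating point per distinct score,
which handles ties correctly under the trapezoidal rule), AUC is the
trapezoidal area under TPR vs. FPR, and population curves are produced by
vertical averaging on a fixed 101-point grid.

The published per-subject AUC benchmark for the PRIDE personal-risk study
(23 subjects × 5 methods, in percent) ships with the package for comparison
arithmetic and the paired statistical tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ockra import baselines, core
from ockra.preprocess import (
    LABEL_ATYPICAL,
    LABEL_TYPICAL,
    LabeledDataset,
    split_folds,
)


@dataclass
class ScoredTestSet:
    """Similarity scores with ground-truth labels for one evaluation unit."""

    scores: np.ndarray
    labels: np.ndarray
    subject_id: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")

    @property
    def is_anomaly(self) -> np.ndarray:
        return self.labels == LABEL_ATYPICAL


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class PrCurve:
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray


def _sweep(scored: ScoredTestSet):
    """Single ascending pass over scores; cumulative TP/FP at distinct-score cuts.

    Calling "positive" (anomalous) at threshold θ means score ≤ θ, so sweeping
    ascending visits queries from most to least anomalous.
    """
    y = scored.is_anomaly
    P = int(y.sum())
    N = int(len(y) - P)
    if P == 0 or N == 0:
        raise ValueError("curve construction needs both typical and atypical rows")
    order = np.argsort(scored.scores, kind="stable")
    s = scored.scores[order]
    tp = np.cumsum(y[order])
    fp = np.arange(1, len(s) + 1) - tp
    # keep one point per distinct score: the last index of each tied group
    last = np.r_[s[1:] != s[:-1], True]
    return s[last], tp[last], fp[last], P, N


def roc_points(scored: ScoredTestSet) -> RocCurve:
    """ROC curve (FPR, TPR) from (0,0) to (1,1), anomalies positive."""
    thr, tp, fp, P, N = _sweep(scored)
    fpr = np.r_[0.0, fp / N]
    tpr = np.r_[0.0, tp / P]
    thresholds = np.r_[-np.inf, thr]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve, in [0, 1]."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def pr_points(scored: ScoredTestSet) -> PrCurve:
    """Precision-recall curve over the same ascending threshold sweep.

    The sweep stops once full recall is first reached; beyond that point
    recall is constant and precision only decays, adding no information.
    """
    thr, tp, fp, P, _ = _sweep(scored)
    recall = tp / P
    precision = tp / (tp + fp)
    stop = int(np.argmax(recall >= 1.0)) + 1
    return PrCurve(recall=recall[:stop], precision=precision[:stop], thresholds=thr[:stop])


def average_curves(
    curves, kind: str = "roc", n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical averaging: mean and sample-std of y at fixed x grid points.

    For ROC curves TPR is interpolated on an FPR grid, for PR curves
    precision on a recall grid; returns ``(grid, mean, std)``.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    ys = []
    for c in curves:
        if kind == "roc":
            x, y = c.fpr, c.tpr
        elif kind == "pr":
            x, y = c.recall, c.precision
        else:
            raise ValueError(f"unknown curve kind {kind!r}")
        ys.append(np.interp(grid, x, y))
    ys = np.vstack(ys)
    mean = ys.mean(axis=0)
    std = ys.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_grid)
    return grid, mean, std


@dataclass
class ExperimentResult:
    auc_table: pd.DataFrame  # subjects × methods, AUC in percent
    roc_curves: dict  # (subject, method) -> RocCurve
    pr_curves: dict  # (subject, method) -> PrCurve
    scored: dict  # (subject, method) -> ScoredTestSet


def run_experiment(
    subjects: dict,
    methods=("ockra",),
    n_members: int = 100,
    k: int = 10,
    seed: int = 0,
    n_folds: int = 5,
) -> ExperimentResult:
    """Five-fold per-subject evaluation of one or more one-class methods.

    ``subjects`` maps subject id to a ``(normal, anomalous)`` pair of
    LabeledDatasets.  For every repetition, four contiguous folds of the
    normal log train the method; the held-out fold joined with the full
    anomaly log is scored.  Scores are pooled across the five folds before
    one curve per subject and method is built, and AUC is reported in
    percent.  Anomaly labels never reach any training path.
    """
    auc_rows = {}
    roc_curves, pr_curves, scored_sets = {}, {}, {}
    for si, (subject, (normal, anomalous)) in enumerate(sorted(subjects.items())):
        subject_seed = (seed * 100003 + si) % (2**31)
        row = {}
        for method in methods:
            scores, labels = [], []
            for fold in split_folds(normal, anomalous, n_folds=n_folds):
                train_X = normal.X[fold.train_rows]
                train_ts = (
                    normal.timestamps[fold.train_rows]
                    if normal.timestamps is not None
                    else None
                )
                scorer = baselines.train_scorer(
                    method,
                    train_X,
                    n_members=n_members,
                    k=k,
                    seed=subject_seed,
                    timestamps=train_ts,
                )
                test_X = np.vstack(
                    [normal.X[fold.test_rows], anomalous.X[fold.anomaly_rows]]
                )
                scores.append(np.asarray(scorer(test_X), dtype=float))
                labels.append(
                    np.r_[
                        np.full(len(fold.test_rows), LABEL_TYPICAL, dtype=object),
                        np.full(len(fold.anomaly_rows), LABEL_ATYPICAL, dtype=object),
                    ]
                )
            scored = ScoredTestSet(
                scores=np.concatenate(scores),
                labels=np.concatenate(labels),
                subject_id=str(subject),
                method=method,
            )
            roc = roc_points(scored)
            roc_curves[(subject, method)] = roc
            pr_curves[(subject, method)] = pr_points(scored)
            scored_sets[(subject, method)] = scored
            row[method] = 100.0 * roc.auc
        auc_rows[subject] = row
    table = pd.DataFrame.from_dict(auc_rows, orient="index")[list(methods)]
    table.index.name = "subject"
    return ExperimentResult(
        auc_table=table, roc_curves=roc_curves, pr_curves=pr_curves, scored=scored_sets
    )


def wilcoxon_signed_rank(auc_a, auc_b) -> tuple[float, int, int]:
    """Two-sided paired Wilcoxon signed-rank test on per-subject AUCs.

    Zero differences are dropped; identical vectors give p = 1 by convention.
    Returns ``(p_value, wins_a, wins_b)`` where wins count subjects on which
    each method scored strictly higher.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    wins_a = int(np.sum(a > b))
    wins_b = int(np.sum(b > a))
    if np.all(a == b):
        return 1.0, wins_a, wins_b
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue), wins_a, wins_b


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H test across per-subject datasets (any 1-D samples)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    try:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H, p = stats.kruskal(*groups)
    except ValueError:  # all observations identical
        return 0.0, 1.0
    if not (np.isfinite(H) and np.isfinite(p)):  # constant data, tie correction 0/0
        return 0.0, 1.0
    return float(H), float(p)


REFERENCE_METHODS = ("ocsvm", "parzen", "kmeans1", "kmeans2", "ockra")


def load_reference_auc() -> pd.DataFrame:
    """Published per-subject AUC benchmark (percent) for the PRIDE study.

    23 subjects × 5 methods; the stated column means are 86.44 (ocSVM),
    88.56 (Parzen), 88.52 (k-means1), 86.81 (k-means2), 89.09 (OCKRA).
    """
    with resources.files("ockra.data").joinpath("pride_auc_benchmark.csv").open() as fh:
        df = pd.read_csv(fh, index_col="subject")
    return df
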