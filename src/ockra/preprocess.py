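"""Raw sensor-log preprocessing into per-second 26-dimensional feature vectors.

A wearable-band log mixes channels sampled at very different rates: tri-axial
motion channels at 8 Hz, heart rate / pace / speed and the cumulative counters
(steps, distance, calories) at 1 Hz, skin temperature roughly every 30 s and
UV exposure roughly every 60 s.  Feature extraction uses a one-second window
and three rules:

1. channels faster than 1 s contribute the window mean and sample standard
   deviation (``ddof=1``; a single sample gives std 0);
2. channels at exactly 1 s contribute the raw value;
3. channels slower than 1 s contribute the last observed value, carried
   forward.

Cumulative counters contribute the increment (delta) with respect to the
previous emitted window; the delta resets to 0 at the start of a contiguous
segment and after a gap longer than 120 s (battery-recharge gaps are real
absences in the log, so no vectors are emitted for them).

The resulting vector has exactly 26 fields: three tri-axial high-rate blocks
summarized by mean and std (18 fields), four instantaneous values plus the
ordinal UV level (5 fields) and three deltas (3 fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# High-rate (8 Hz) tri-axial blocks, in feature-vector order: the gyroscope
# event's acceleration stream, gyroscope angular velocity [deg/s], and the
# accelerometer [g].  Each contributes mean and sample std per axis.
HIGH_RATE_CHANNELS = (
    "gyro_accel_x", "gyro_accel_y", "gyro_accel_z",
    "gyro_x", "gyro_y", "gyro_z",
    "accel_x", "accel_y", "accel_z",
)
# 1 Hz instantaneous channels (rule 2) and slower carried-forward channels
# (rule 3), in feature-vector order.
VALUE_CHANNELS = ("heart_rate", "skin_temp", "pace", "speed", "uv")
# Cumulative 1 Hz counters contributing per-second increments.
CUMULATIVE_CHANNELS = ("steps_total", "distance_total", "calories_total")

ALL_CHANNELS = HIGH_RATE_CHANNELS + VALUE_CHANNELS + CUMULATIVE_CHANNELS

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in HIGH_RATE_CHANNELS for stat in ("mean", "std")
) + VALUE_CHANNELS + tuple(
    f"delta_{ch.removesuffix('_total')}" for ch in CUMULATIVE_CHANNELS
)

N_FEATURES = len(FEATURE_NAMES)  # 26

LABEL_TYPICAL = "typical"
LABEL_ATYPICAL = "atypical"

_UV_LEVELS = {"none": 0.0, "low": 1.0, "medium": 2.0, "high": 3.0, "very_high": 4.0}

#: Gap length (seconds) beyond which the delta reference for cumulative
#: counters is reset, so a recharge gap does not produce one huge spurious
#: increment.
GAP_RESET_SECONDS = 120.0


def encode_uv(category: str) -> float:
    """Map the band's ordinal UV exposure level to a number in 0..4."""
    key = str(category).strip().lower().replace(" ", "_")
    try:
        return _UV_LEVELS[key]
    except KeyError:
        raise ValueError(
            f"unknown UV category {category!r}; expected one of {sorted(_UV_LEVELS)}"
        ) from None


@dataclass
class LabeledDataset:
    """A feature matrix with optional per-row timestamps and labels.

    Labels, when present, are ground truth for evaluation only -- no training
    operation in this package ever reads them.
    """

    X: np.ndarray
    timestamps: np.ndarray | None = None
    labels: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        m = self.X.shape[0]
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != m:
                raise ValueError("timestamps length does not match row count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != m:
                raise ValueError("labels length does not match row count")
            bad = set(self.labels) - {LABEL_TYPICAL, LABEL_ATYPICAL}
            if bad:
                raise ValueError(f"unknown labels: {sorted(map(str, bad))}")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FoldSplit:
    """One cross-validation repetition over per-subject data.

    ``train_rows``/``test_rows`` index the normal-behavior table;
    ``anomaly_rows`` index the anomaly table and are joined with the held-out
    normal fold at test time, never used for training.
    """

    train_rows: np.ndarray
    test_rows: np.ndarray
    anomaly_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _log_to_frame(log) -> pd.DataFrame:
    if isinstance(log, pd.DataFrame):
        df = log
    else:
        df = pd.DataFrame(list(log), columns=["timestamp", "channel", "value"])
    missing = {"timestamp", "channel", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"sensor log missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("empty sensor log")
    ts = df["timestamp"].to_numpy(dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("sensor log must be sorted by timestamp")
    unknown = set(df["channel"].unique()) - set(ALL_CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(map(str, unknown))}")
    return df


def build_feature_vectors(log) -> pd.DataFrame:
    """Convert a raw multi-rate sensor log into per-second feature vectors.

    Parameters
    ----------
    log
        A DataFrame with columns ``timestamp, channel, value`` or an iterable
        of ``(timestamp, channel, value)`` records, sorted by timestamp.

    Returns
    -------
    DataFrame with a ``t`` column (integer window-start second) followed by
    the 26 feature columns of :data:`FEATURE_NAMES`.  A window is emitted only
    when it contains at least one high-rate motion sample; recharge gaps
    therefore produce no rows.
    """
    df = _log_to_frame(log)
    df = df.assign(second=np.floor(df["timestamp"].to_numpy(dtype=float)).astype(np.int64))

    hi = df[df["channel"].isin(HIGH_RATE_CHANNELS)]
    if len(hi) == 0:
        raise ValueError("log contains no high-rate motion samples; nothing to emit")
    stats = (
        hi.groupby(["second", "channel"], sort=True)["value"]
        .agg(["mean", "std"])
        .unstack("channel")
    )
    seconds = stats.index.to_numpy()

    out = pd.DataFrame({"t": seconds})
    for ch in HIGH_RATE_CHANNELS:
        if ("mean", ch) in stats.columns:
            mean = stats[("mean", ch)].to_numpy()
            std = stats[("std", ch)].to_numpy()
        else:  # channel absent from the whole log
            mean = np.zeros(len(seconds))
            std = np.full(len(seconds), np.nan)
        out[f"{ch}_mean"] = np.nan_to_num(mean, nan=0.0)
        out[f"{ch}_std"] = np.nan_to_num(std, nan=0.0)  # single sample -> 0

    def _last_per_second(channel: str) -> pd.Series:
        sub = df[df["channel"] == channel]
        return sub.groupby("second", sort=True)["value"].last()

    for ch in VALUE_CHANNELS:
        series = _last_per_second(ch)
        if len(series) == 0:
            out[ch] = 0.0
            continue
        aligned = series.reindex(
            series.index.union(pd.Index(seconds))
        ).ffill().bfill()
        out[ch] = aligned.loc[seconds].to_numpy(dtype=float)

    # Delta of cumulative counters vs. the previous emitted window, with the
    # reference reset at segment starts (first window, or gap > 120 s).
    gap = np.diff(seconds, prepend=seconds[0])
    reset = np.ones(len(seconds), dtype=bool)
    reset[1:] = gap[1:] > GAP_RESET_SECONDS
    reset[0] = True
    for ch in CUMULATIVE_CHANNELS:
        name = f"delta_{ch.removesuffix('_total')}"
        series = _last_per_second(ch)
        if len(series) == 0:
            out[name] = 0.0
            continue
        aligned = series.reindex(series.index.union(pd.Index(seconds))).ffill().bfill()
        cum = aligned.loc[seconds].to_numpy(dtype=float)
        delta = np.diff(cum, prepend=cum[0])
        delta[reset] = 0.0
        out[name] = delta

    return out[["t", *FEATURE_NAMES]]


def features_to_dataset(features: pd.DataFrame, label: str | None = None) -> LabeledDataset:
    """Wrap the output of :func:`build_feature_vectors` as a LabeledDataset."""
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = None if label is None else np.full(len(X), label, dtype=object)
    return LabeledDataset(
        X=X,
        timestamps=features["t"].to_numpy(dtype=float),
        labels=labels,
        feature_names=FEATURE_NAMES,
    )


def split_folds(
    normal: LabeledDataset, anomalous: LabeledDataset | None, n_folds: int = 5
) -> list[FoldSplit]:
    """Partition the normal rows into contiguous temporal folds.

    Each repetition trains on ``n_folds - 1`` folds of normal behavior and
    tests on the held-out fold joined with every anomaly row.  Contiguous
    blocks (rather than a random shuffle) respect the time-series structure
    of the log.
    """
    m = normal.n_rows
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if m < n_folds:
        raise ValueError(f"cannot split {m} rows into {n_folds} folds")
    anomaly_rows = (
        np.arange(anomalous.n_rows) if anomalous is not None else np.empty(0, dtype=int)
    )
    blocks = np.array_split(np.arange(m), n_folds)
    splits = []
    for i in range(n_folds):
        test = blocks[i]
        train = np.concatenate([blocks[j] for j in range(n_folds) if j != i])
        splits.append(FoldSplit(train_rows=train, test_rows=test, anomaly_rows=anomaly_rows))
    return splits


def read_labeled_csv(path) -> LabeledDataset:
    """Read a labeled feature table: feature columns plus a final ``label``.

    The last column holds ``typical``/``atypical`` when it is named ``label``;
    otherwise the file is treated as unlabeled features.  A ``t`` first column
    of timestamps is recognized and kept out of the feature matrix.
    """
    df = pd.read_csv(path)
    if df.shape[1] == 0 or len(df) == 0:
        raise ValueError(f"{path}: empty feature table")
    timestamps = None
    if df.columns[0] == "t":
        timestamps = df.pop("t").to_numpy(dtype=float)
    labels = None
    if df.columns[-1] == "label":
        raw = df.pop("label")
        for i, lab in enumerate(raw):
            if lab not in (LABEL_TYPICAL, LABEL_ATYPICAL):
                raise ValueError(f"{path}: unknown label {lab!r} at data row {i + 1}")
        labels = raw.to_numpy(dtype=object)
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, row in enumerate(df.itertuples(index=False)):
            if any(not _is_number(v) for v in row):
                raise ValueError(f"{path}: malformed numeric row at data row {i + 1}") from None
        raise
    return LabeledDataset(
        X=X, timestamps=timestamps, labels=labels, feature_names=tuple(df.columns)
    )


def _is_number(v) -> bool:
    try:
        float(v)
    except (TypeError, ValueError):
        return False
    return True


def write_labeled_csv(ds: LabeledDataset, path) -> None:
    """Write a LabeledDataset as CSV; inverse of :func:`read_labeled_csv`."""
    names = ds.feature_names or tuple(f"f{i + 1}" for i in range(ds.n_features))
    df = pd.DataFrame(ds.X, columns=list(names))
    if ds.timestamps is not None:
        df.insert(0, "t", ds.timestamps)
    if ds.labels is not None:
        df["label"] = ds.labels
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw sensor log CSV (``timestamp,channel,value``).

    UV rows may carry the ordinal category name instead of a number; they are
    converted with :func:`encode_uv`.
    """
    df = pd.read_csv(path, dtype={"timestamp": float, "channel": str})
    missing = {"timestamp", "channel", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: raw log missing columns {sorted(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        fixed = df.loc[bad, ["channel", "value"]]
        non_uv = fixed[fixed["channel"] != "uv"]
        if len(non_uv) > 0:
            row = non_uv.index[0]
            raise ValueError(f"{path}: malformed value at data row {row + 1}")
        values[bad] = [encode_uv(v) for v in fixed["value"]]
    return df.assign(value=values.astype(float))


def write_raw_csv(log: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    log.to_csv(path, index=False, columns=["timestamp", "channel", "value"])
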