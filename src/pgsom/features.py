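"""Feature pipeline: raw 7-channel sensor logs -> 101-D feature vectors.

The raw record is a numeric table of 7 channels sampled at a nominal
30 Hz: tri-axial wrist acceleration, tri-axial hip acceleration, and one
piezo ventilation channel.  Two synthetic acceleration channels (the
per-sample Euclidean norm of each tri-axial triple) are derived, giving 9
signals per window.  Each window of 500 samples yields 11 time-domain
statistics per signal plus the two Pearson correlations between each
synthetic acceleration and the piezo channel: 11 * 9 + 2 = 101 features.

Statistic conventions (pinned because dialects differ):
variance is the population variance (divide by n); RMS is
sqrt(mean-of-squares); kurtosis is Fisher excess (normal -> 0); skewness
is the Fisher-Pearson g1; energy is mean-of-squares (scale-free in window
length; plain sum-of-squares is selectable); percentiles use linear
interpolation between order statistics; a correlation with a constant
series is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

RAW_COLUMNS = ["wrist_x", "wrist_y", "wrist_z",
               "hip_x", "hip_y", "hip_z", "piezo"]
SIGNAL_NAMES = RAW_COLUMNS + ["wrist_syn", "hip_syn"]
STAT_NAMES = ["mean", "var", "rms", "kurtosis", "skewness", "energy",
              "p10", "p25", "p50", "p75", "p90"]
WINDOW_LENGTH = 500
SAMPLING_RATE = 30.0

FEATURE_NAMES: List[str] = (
    [f"{sig}_{st}" for sig in SIGNAL_NAMES for st in STAT_NAMES]
    + ["corr_hip_syn_piezo", "corr_wrist_syn_piezo"]
)
N_FEATURES = len(FEATURE_NAMES)  # 101


@dataclass
class SignalWindow:
    """One analysis window: 500 rows x 7 raw channels, optional label."""

    samples: np.ndarray
    label: Optional[int] = None
    fs: float = SAMPLING_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(RAW_COLUMNS):
            raise ValueError(
                f"window must have {len(RAW_COLUMNS)} channels, "
                f"got shape {self.samples.shape}")


def synthetic_acceleration(x: np.ndarray, y: np.ndarray,
                           z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm sqrt(x^2 + y^2 + z^2) of a tri-axial triple."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def slide_windows(raw: np.ndarray, labels: Optional[np.ndarray] = None,
                  length: int = WINDOW_LENGTH,
                  step: Optional[int] = None) -> List[SignalWindow]:
    """Cut a raw N x 7 table into consecutive windows.

    ``step`` defaults to ``length`` (non-overlapping).  A trailing
    remainder shorter than ``length`` is dropped.  The window label is the
    majority of its row labels (ties toward the smallest label).
    """
    raw = np.asarray(raw, dtype=float)
    step = length if step is None else step
    n = raw.shape[0]
    if n < length:
        warnings.warn(f"only {n} rows < window length {length}; no windows",
                      RuntimeWarning)
        return []
    windows = []
    for start in range(0, n - length + 1, step):
        block = raw[start:start + length]
        lab = None
        if labels is not None:
            vals, counts = np.unique(labels[start:start + length],
                                     return_counts=True)
            lab = int(vals[np.flatnonzero(counts == counts.max()).min()])
        windows.append(SignalWindow(samples=block, label=lab))
    return windows


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _signal_stats(s: np.ndarray, energy_mode: str) -> List[float]:
    n = s.size
    mean = float(np.mean(s))
    var = float(np.var(s))                       # population variance
    rms = float(np.sqrt(np.mean(s * s)))
    if var > 0:
        kurt = float(stats.kurtosis(s, fisher=True, bias=True))
        skew = float(stats.skew(s, bias=True))
    else:
        kurt = skew = 0.0                        # shape moments of a flat signal
    ss = float(np.sum(s * s))
    energy = ss / n if energy_mode == "mean" else ss
    pct = np.percentile(s, [10, 25, 50, 75, 90], method="linear")
    return [mean, var, rms, kurt, skew, energy, *map(float, pct)]


def extract_features(win: SignalWindow, energy_mode: str = "mean") -> np.ndarray:
    """Compute the 101-D feature vector of one window.

    Signal order: wrist x/y/z, hip x/y/z, piezo, wrist-synthetic,
    hip-synthetic; 11 statistics each (see ``STAT_NAMES``), then the
    Pearson correlations corr(hip_syn, piezo) and corr(wrist_syn, piezo).
    """
    S = win.samples
    if not np.isfinite(S).all():
        bad = [RAW_COLUMNS[j] for j in range(S.shape[1])
               if not np.isfinite(S[:, j]).all()]
        raise ValueError(f"non-finite values in channel(s): {', '.join(bad)}")
    wrist_syn = synthetic_acceleration(S[:, 0], S[:, 1], S[:, 2])
    hip_syn = synthetic_acceleration(S[:, 3], S[:, 4], S[:, 5])
    piezo = S[:, 6]
    signals = [S[:, j] for j in range(7)] + [wrist_syn, hip_syn]
    feats: List[float] = []
    for s in signals:
        feats.extend(_signal_stats(s, energy_mode))
    feats.append(_pearson(hip_syn, piezo))
    feats.append(_pearson(wrist_syn, piezo))
    return np.asarray(feats)


def featurize(raw: np.ndarray, labels: Optional[np.ndarray] = None,
              length: int = WINDOW_LENGTH, step: Optional[int] = None,
              energy_mode: str = "mean") -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Window a raw table and extract features from every window.

    Returns ``(X, y)`` where X is n_windows x 101 and y is the per-window
    majority label (None when no labels were given).
    """
    wins = slide_windows(raw, labels, length=length, step=step)
    if not wins:
        return np.empty((0, N_FEATURES)), None if labels is None else np.empty(0, int)
    X = np.stack([extract_features(w, energy_mode) for w in wins])
    y = None
    if labels is not None:
        y = np.asarray([w.label for w in wins], dtype=np.int64)
    return X, y


# ---------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------

@dataclass
class Scaler:
    """Per-column z-score parameters fitted on training features."""

    mean: np.ndarray
    std: np.ndarray          # columns with zero spread keep std = 1 (pass-through)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.std + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, doc: dict) -> "Scaler":
        return cls(mean=np.asarray(doc["mean"]), std=np.asarray(doc["std"]))


def standardize(train: np.ndarray,
                *others: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Z-score ``train`` and any further matrices using train statistics.

    Returns the scaled matrices followed by the fitted :class:`Scaler`.
    Constant columns pass through unchanged.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("training features are empty")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    # constant columns: leave values untouched rather than centering them
    mean = np.where(train.std(axis=0) > 0, mean, 0.0)
    scaler = Scaler(mean=mean, std=std)
    scaled = [scaler.transform(m) for m in (train, *others)]
    return (*scaled, scaler)


# ---------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------

def read_raw_csv(path) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Read a raw sensor CSV (wrist/hip/piezo columns, optional label)."""
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw CSV missing columns: {', '.join(missing)}")
    raw = df[RAW_COLUMNS].to_numpy(dtype=float)
    labels = df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None
    return raw, labels


def write_raw_csv(path, raw: np.ndarray,
                  labels: Optional[np.ndarray] = None) -> None:
    df = pd.DataFrame(np.asarray(raw), columns=RAW_COLUMNS)
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=np.int64)
    df.to_csv(path, index=False)


def read_feature_csv(path) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Read a feature CSV with the 101 named columns and optional label."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing[:3]}...")
    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None
    return X, y


def write_feature_csv(path, X: np.ndarray,
                      y: Optional[np.ndarray] = None) -> None:
    X = np.asarray(X)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} feature columns, got {X.shape[1]}")
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    if y is not None:
        df["label"] = np.asarray(y, dtype=np.int64)
    df.to_csv(path, index=False)
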