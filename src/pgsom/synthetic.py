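"""Synthetic activity datasets with the structure the method assumes.

The study's wearable-sensor dataset is not public, so this module supplies
two generators that reproduce its statistical shape at desk scale:

* :func:`make_feature_dataset` — class-conditional isotropic Gaussian
  clusters directly in 101-D feature space, with the 9-class imbalance of
  the original activity inventory and one deliberately overlapping class
  pair (activities 4 and 6, emulating the walking vs low-speed-running
  confusion every clusterer exhibits on the real data).
* :func:`make_raw_dataset` — per-class sinusoidal 7-channel signals at
  30 Hz with seeded noise, for end-to-end exercise of the feature
  pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .features import RAW_COLUMNS, SAMPLING_RATE

# per-class sample counts of the original 9-activity inventory
# (table working, housekeeping, moving objects, walking, cycling,
#  running low, running fast, tennis, basketball)
CLASS_COUNTS = (1635, 807, 794, 840, 1549, 1646, 494, 359, 462)
N_TOTAL = sum(CLASS_COUNTS)  # 8586


@dataclass
class SynthConfig:
    """Knobs of the synthetic generators.

    ``separation`` is the inter-centroid distance in units of the
    within-class standard deviation; ``overlap_pairs`` lists 1-based class
    pairs whose centroids are pulled to ``separation / 4`` apart to mimic
    genuinely confusable activities.
    """

    n_classes: int = 9
    class_proportions: Tuple[float, ...] = tuple(c / N_TOTAL for c in CLASS_COUNTS)
    dim: int = 101
    separation: float = 8.0
    overlap_pairs: Tuple[Tuple[int, int], ...] = ((4, 6),)
    n_samples: int = N_TOTAL
    seed: int = 0

    def __post_init__(self):
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length != n_classes")
        s = float(sum(self.class_proportions))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {s}, expected 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def class_sizes(proportions: Sequence[float], n: int) -> np.ndarray:
    """Deterministic largest-remainder rounding of proportions to counts."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(np.int64)
    rem = n - int(base.sum())
    if rem:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _centroids(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded class centroids on a sphere of radius ``separation``."""
    dirs = rng.normal(size=(cfg.n_classes, cfg.dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    C = dirs * cfg.separation
    for a, b in cfg.overlap_pairs:
        i, j = a - 1, b - 1
        mid = 0.5 * (C[i] + C[j])
        u = C[j] - C[i]
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else np.eye(cfg.dim)[0]
        half = cfg.separation / 8.0        # final distance = separation / 4
        C[i] = mid - half * u
        C[j] = mid + half * u
    return C


def make_feature_dataset(cfg: Optional[SynthConfig] = None,
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Generate (X, y): isotropic unit-variance Gaussian clusters.

    Labels are 1-based class ids.  Fully deterministic under ``cfg.seed``.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    C = _centroids(cfg, rng)
    sizes = class_sizes(cfg.class_proportions, cfg.n_samples)
    X = np.empty((cfg.n_samples, cfg.dim))
    y = np.empty(cfg.n_samples, dtype=np.int64)
    row = 0
    for k in range(cfg.n_classes):
        nk = int(sizes[k])
        X[row:row + nk] = C[k] + rng.normal(size=(nk, cfg.dim))
        y[row:row + nk] = k + 1
        row += nk
    perm = rng.permutation(cfg.n_samples)
    return X[perm], y[perm]


# class-specific fundamentals (Hz) spanning slow to vigorous activities
_CLASS_FREQS = np.linspace(0.5, 4.0, 9)


def make_raw_dataset(cfg: Optional[SynthConfig] = None,
                     rows_per_class: int = 1500,
                     noise: float = 0.2,
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Generate a raw 7-channel table with per-row labels.

    Each class contributes one bout of ``rows_per_class`` rows (>= 500 so
    windows exist) of sinusoids at a class-specific fundamental frequency
    with per-channel amplitude and phase, plus seeded Gaussian noise,
    sampled at 30 Hz.
    """
    cfg = cfg or SynthConfig()
    if rows_per_class < 1:
        raise ValueError("rows_per_class must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n_ch = len(RAW_COLUMNS)
    blocks, labels = [], []
    t = np.arange(rows_per_class) / SAMPLING_RATE
    for k in range(cfg.n_classes):
        f = _CLASS_FREQS[k % len(_CLASS_FREQS)]
        amps = 0.5 + rng.uniform(0.0, 1.5, size=n_ch)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
        sig = amps * np.sin(2.0 * np.pi * f * t[:, None] + phases)
        if noise > 0:
            sig = sig + rng.normal(scale=noise, size=sig.shape)
        blocks.append(sig)
        labels.append(np.full(rows_per_class, k + 1, dtype=np.int64))
    return np.vstack(blocks), np.concatenate(labels)
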