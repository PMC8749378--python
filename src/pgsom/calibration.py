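"""Neuron calibration: label a trained map from a small labeled subset.

Training is unsupervised; classification only becomes possible after a
calibration pass in which each labeled sample activates its best-matching
neuron and every activated neuron takes the majority class among the
samples that hit it (ties break toward the smallest class label).  Neurons
never activated during calibration inherit the label of the nearest
directly-labeled neuron in weight space, so every live neuron ends up
labeled and prediction can never encounter an unlabeled winner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .core import NetworkState, find_winner


@dataclass
class LabelMap:
    """Neuron-id -> class-label assignment with provenance bookkeeping.

    ``coverage`` is the fraction of live neurons labeled directly by
    calibration samples (the rest were filled in by nearest-neighbor
    propagation).
    """

    entries: Dict[int, int] = field(default_factory=dict)
    coverage: float = 0.0

    def __getitem__(self, nid: int) -> int:
        return self.entries[nid]

    def __len__(self) -> int:
        return len(self.entries)


def calibrate(state: NetworkState, X_lab: np.ndarray,
              y_lab: np.ndarray) -> LabelMap:
    """Label every neuron of ``state`` from labeled samples.

    Raises on an empty calibration set or mismatched lengths.
    """
    X_lab = np.asarray(X_lab, dtype=float)
    y_lab = np.asarray(y_lab)
    if X_lab.ndim != 2 or X_lab.shape[0] == 0:
        raise ValueError("calibration set is empty")
    if X_lab.shape[0] != y_lab.shape[0]:
        raise ValueError("X_lab and y_lab lengths differ")

    hits: Dict[int, Counter] = {}
    for x, y in zip(X_lab, y_lab):
        winner, _ = find_winner(state, x)
        hits.setdefault(winner, Counter())[int(y)] += 1

    entries: Dict[int, int] = {}
    for nid, counts in hits.items():
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        entries[nid] = best[0]

    all_ids = state.ids()
    labeled_ids = sorted(entries)
    n_direct = len(labeled_ids)
    dead = [nid for nid in all_ids if nid not in entries]
    if dead:
        Wl = np.stack([state.weight(nid) for nid in labeled_ids])
        for nid in dead:
            d = np.sum((Wl - state.weight(nid)) ** 2, axis=1)
            # ties toward the smallest labeled neuron id, which is the
            # first index because labeled_ids is sorted
            entries[nid] = entries[labeled_ids[int(np.argmin(d))]]
    return LabelMap(entries=entries,
                    coverage=n_direct / len(all_ids) if all_ids else 0.0)


def predict(state: NetworkState, label_map: LabelMap,
            X: np.ndarray) -> np.ndarray:
    """Classify each row of ``X`` by its winning neuron's label."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    missing = set(state.ids()) - set(label_map.entries)
    if missing:
        raise ValueError(f"label map does not cover neurons {sorted(missing)}")
    out = np.empty(X.shape[0], dtype=np.int64)
    for i, x in enumerate(X):
        winner, _ = find_winner(state, x)
        out[i] = label_map[winner]
    return out
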