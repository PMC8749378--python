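"""SOM / GSOM / PGSOM training engine.

The model is a competitive-learning network whose output layer is a set of
neurons on a 2-D integer lattice.  Three modes share one presentation
pipeline:

* ``som``   — fixed rectangular grid, weights adapt, topology frozen.
* ``gsom``  — starts from a 2x2 seed and grows at the lattice boundary when
  a winner's cumulative quantization error (CEQ) exceeds the growth
  threshold ``GT = -D * ln(SF)``; interior winners instead shed half their
  CEQ onto their lattice neighbors.
* ``pgsom`` — GSOM plus age-based pruning: every neuron carries an age
  (presentations since it last won or was born) and any neuron whose age
  exceeds the threshold ``M`` is deleted after each presentation.

One presentation of a sample x runs, in order: winner search (squared
Euclidean distance), CEQ accumulation ``ceq += eta * d``, learning-rate
decay ``eta <- (1 - R/|net|) * eta`` floored at ``eta_min``, weight update
(winner moves toward x at rate eta; its occupied lattice neighbors move
toward the winner's pre-update weight, damped by ``exp(-d_i / tau)``),
growth or error redistribution, age update, and — in pgsom mode — pruning.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .lattice import (
    GridPos,
    free_neighbor_positions,
    is_boundary,
    neighbor_positions,
    occupied_neighbor_positions,
    opposite_position,
)

MODES = ("som", "gsom", "pgsom")


@dataclass
class Neuron:
    """Snapshot of one lattice unit."""

    id: int
    pos: GridPos
    w: np.ndarray          # weight vector, feature units
    ceq: float             # cumulative quantization error, squared-distance units
    age: int               # presentations since last activation


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    ``sf`` is the spread factor in (0, 1): larger sf lowers the growth
    threshold and eases growth.  ``rf`` is the ratio factor tying the age
    threshold to the batch size (``M = round(rf * batch_size)``); an
    explicit ``m`` overrides it, and ``m = inf`` disables pruning.  ``r``
    is the learning-rate decay constant; decay contracts only while
    ``r < |network|``.  ``tau`` scales the neighbor damping
    ``exp(-d_i / tau)``; the raw form (tau = 1) underflows for large
    squared distances, so tau is exposed for high-dimensional data.
    """

    mode: str = "pgsom"
    sf: float = 0.8
    rf: Optional[float] = 1.5
    m: Optional[float] = None          # explicit age threshold; overrides rf
    eta0: float = 0.3
    r: float = 1.0
    eta_min: float = 1e-4
    eta_decay: str = "iteration"       # "iteration" or "presentation"
    tau: Optional[float] = None        # None: auto-scale to the input dimension
    batch_size: int = 4000
    calib_size: int = 2000
    max_iter: int = 50
    seed: int = 0
    som_rows: int = 10
    som_cols: int = 10

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode != "som" and not (0.0 < self.sf < 1.0):
            raise ValueError(f"sf must lie in (0, 1), got {self.sf}")
        if self.eta0 <= 0:
            raise ValueError("eta0 must be positive")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.eta_decay not in ("iteration", "presentation"):
            raise ValueError("eta_decay must be 'iteration' or 'presentation'")

    def tau_for(self, dim: int) -> float:
        """Effective neighbor-damping scale: explicit tau, or the dimension.

        The damping ``exp(-d_i / tau)`` acts on squared distances whose
        typical magnitude is the input dimension (for standardized data),
        so the automatic bandwidth is ``tau = D``; ``tau = 1`` reproduces
        the undamped-by-dimension form, which underflows to zero for
        high-dimensional inputs.
        """
        return self.tau if self.tau is not None else float(dim)

    def age_limit(self) -> float:
        """Resolved age threshold M (may be inf)."""
        if self.m is not None:
            return self.m
        if self.rf is None:
            return math.inf
        return age_threshold(self.rf, self.batch_size)


class NetworkState:
    """The living map: neurons, their lattice index, and learning-rate state.

    Internally array-backed (weight matrix + per-slot scalars with a free
    list) so winner search is a single vectorized scan; the public surface
    speaks in neuron ids and grid positions.
    """

    def __init__(self, dim: int, mode: str = "pgsom", eta: float = 0.3,
                 capacity: int = 64):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.dim = int(dim)
        self.mode = mode
        self.eta = float(eta)
        self.presentations = 0
        # per-dimension data scale for seeded weight perturbations; set by
        # train() from the data range, defaults to 1.
        self.data_scale = np.ones(self.dim)

        cap = max(4, capacity)
        self._W = np.zeros((cap, self.dim))
        self._ceq = np.zeros(cap)
        self._age = np.zeros(cap, dtype=np.int64)
        self._ids = np.full(cap, -1, dtype=np.int64)   # -1 marks a free slot
        self._rows = np.zeros(cap, dtype=np.int64)
        self._cols = np.zeros(cap, dtype=np.int64)
        self._pos_index: Dict[GridPos, int] = {}       # pos -> slot
        self._id_slot: Dict[int, int] = {}             # neuron id -> slot
        self._free: List[int] = list(range(cap - 1, -1, -1))
        self._next_id = 0
        self._occ_cache: Optional[np.ndarray] = None

    # -- occupancy / introspection ------------------------------------

    def __len__(self) -> int:
        return len(self._id_slot)

    def occupied(self, pos: GridPos) -> bool:
        return pos in self._pos_index

    def id_at(self, pos: GridPos) -> int:
        return int(self._ids[self._pos_index[pos]])

    def ids(self) -> List[int]:
        return sorted(self._id_slot)

    def neuron(self, nid: int) -> Neuron:
        s = self._id_slot[nid]
        return Neuron(id=nid, pos=(int(self._rows[s]), int(self._cols[s])),
                      w=self._W[s].copy(), ceq=float(self._ceq[s]),
                      age=int(self._age[s]))

    def neurons(self) -> Iterator[Neuron]:
        for nid in self.ids():
            yield self.neuron(nid)

    def weight(self, nid: int) -> np.ndarray:
        return self._W[self._id_slot[nid]].copy()

    def ceq_of(self, nid: int) -> float:
        return float(self._ceq[self._id_slot[nid]])

    def age_of(self, nid: int) -> int:
        return int(self._age[self._id_slot[nid]])

    def total_ceq(self) -> float:
        return float(self._ceq[self._occupied_slots()].sum())

    def weights_matrix(self) -> np.ndarray:
        """Weights of live neurons, rows ordered by neuron id."""
        slots = [self._id_slot[nid] for nid in self.ids()]
        return self._W[slots].copy()

    # -- structural edits ---------------------------------------------

    def add_neuron(self, pos: GridPos, w: np.ndarray, ceq: float = 0.0,
                   age: int = 0) -> int:
        if pos in self._pos_index:
            raise ValueError(f"position {pos} already occupied")
        w = np.asarray(w, dtype=float)
        if w.shape != (self.dim,):
            raise ValueError(f"weight has shape {w.shape}, expected ({self.dim},)")
        if not self._free:
            self._grow_storage()
        s = self._free.pop()
        nid = self._next_id
        self._next_id += 1
        self._W[s] = w
        self._ceq[s] = ceq
        self._age[s] = age
        self._ids[s] = nid
        self._rows[s], self._cols[s] = pos
        self._pos_index[pos] = s
        self._id_slot[nid] = s
        self._occ_cache = None
        return nid

    def remove_neuron(self, nid: int) -> None:
        s = self._id_slot.pop(nid)
        del self._pos_index[(int(self._rows[s]), int(self._cols[s]))]
        self._ids[s] = -1
        self._free.append(s)
        self._occ_cache = None

    def _grow_storage(self) -> None:
        old = len(self._ids)
        new = old * 2
        self._W = np.vstack([self._W, np.zeros((old, self.dim))])
        self._ceq = np.concatenate([self._ceq, np.zeros(old)])
        self._age = np.concatenate([self._age, np.zeros(old, dtype=np.int64)])
        self._ids = np.concatenate([self._ids, np.full(old, -1, dtype=np.int64)])
        self._rows = np.concatenate([self._rows, np.zeros(old, dtype=np.int64)])
        self._cols = np.concatenate([self._cols, np.zeros(old, dtype=np.int64)])
        self._free.extend(range(new - 1, old - 1, -1))

    def _occupied_slots(self) -> np.ndarray:
        if self._occ_cache is None:
            self._occ_cache = np.flatnonzero(self._ids >= 0)
        return self._occ_cache

    def check_index(self) -> None:
        """Assert the position index and neuron collection agree."""
        assert len(self._pos_index) == len(self._id_slot)
        for pos, s in self._pos_index.items():
            assert self._ids[s] >= 0
            assert (int(self._rows[s]), int(self._cols[s])) == pos
        for nid, s in self._id_slot.items():
            assert int(self._ids[s]) == nid


# ---------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------

def find_winner(state: NetworkState, x: np.ndarray) -> Tuple[int, float]:
    """Best-matching unit: the neuron minimizing squared Euclidean distance.

    Returns ``(neuron id, d)`` with ``d = ||x - w_winner||^2``; exact
    distance ties break toward the lowest neuron id.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (state.dim,):
        raise ValueError(f"input has shape {x.shape}, expected ({state.dim},)")
    if len(state) == 0:
        raise ValueError("network has no neurons")
    slots = state._occupied_slots()
    diff = state._W[slots] - x
    d = np.einsum("ij,ij->i", diff, diff)
    dmin = d.min()
    tied = slots[d == dmin]
    winner = int(state._ids[tied].min())
    return winner, float(dmin)


def decay_eta(eta: float, r: float, n_neurons: int,
              eta_min: float = 1e-4) -> float:
    """One step of learning-rate decay: ``max(eta_min, (1 - r/n) * eta)``.

    Contracts only while r < n; a degenerate configuration with r >= n
    would send eta non-positive, so it is clamped to the floor with a
    warning.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    factor = 1.0 - r / n_neurons
    if factor <= 0.0:
        warnings.warn(
            f"decay constant r={r} >= network size {n_neurons}; "
            "learning rate clamped to eta_min", RuntimeWarning)
        return eta_min
    return max(eta_min, factor * eta)


def accumulate_error(state: NetworkState, winner_id: int, d: float,
                     eta: float) -> None:
    """Add ``eta * d`` to the winner's cumulative quantization error."""
    state._ceq[state._id_slot[winner_id]] += eta * d


def update_weights(state: NetworkState, winner_id: int, x: np.ndarray,
                   eta: float, tau: float = 1.0) -> None:
    """Move the winner toward the input and drag its lattice neighbors along.

    Winner: ``w += eta * (x - w)``.  Each occupied 4-neighbor i moves toward
    the winner's pre-update weight, damped by its own distance to the input:
    ``w_i += eta * (w_winner_old - w_i) * exp(-||x - w_i||^2 / tau)``.
    """
    s = state._id_slot[winner_id]
    w_old = state._W[s].copy()
    pos = (int(state._rows[s]), int(state._cols[s]))
    for npos in occupied_neighbor_positions(state, pos):
        ns = state._pos_index[npos]
        wn = state._W[ns]
        di = float(np.sum((x - wn) ** 2))
        state._W[ns] = wn + eta * (w_old - wn) * math.exp(-di / tau)
    state._W[s] = w_old + eta * (x - w_old)


def growth_threshold(dim: int, sf: float) -> float:
    """Growth threshold ``GT = -D * ln(SF)``; positive, decreasing in SF."""
    if not (0.0 < sf < 1.0):
        raise ValueError(f"spread factor must lie in (0, 1), got {sf}")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return -dim * math.log(sf)


def interpolate_weight(state: NetworkState, winner_id: int, new_pos: GridPos,
                       rng: np.random.Generator) -> np.ndarray:
    """Initial weight for a neuron grown at ``new_pos`` beside the winner.

    Deterministic ladder: extrapolate through the winner from the neuron on
    the opposite side if present (``2 w_winner - w_opp``); else midpoint
    with the lowest-id occupied neighbor; else the winner's weight plus a
    small seeded perturbation (uniform within +-1% of the per-dimension
    data scale).
    """
    if state.occupied(new_pos):
        raise ValueError(f"growth target {new_pos} is occupied")
    s = state._id_slot[winner_id]
    wpos = (int(state._rows[s]), int(state._cols[s]))
    w_winner = state._W[s]
    opp = opposite_position(wpos, new_pos)
    if state.occupied(opp):
        return 2.0 * w_winner - state._W[state._pos_index[opp]]
    occ = occupied_neighbor_positions(state, wpos)
    if occ:
        near = min(state.id_at(p) for p in occ)
        return 0.5 * (w_winner + state._W[state._id_slot[near]])
    delta = rng.uniform(-0.01, 0.01, size=state.dim) * state.data_scale
    return w_winner + delta


def grow_or_redistribute(state: NetworkState, winner_id: int, gt: float,
                         rng: np.random.Generator) -> List[int]:
    """Apply the growth rule if the winner's CEQ has reached the threshold.

    Boundary winner: a new neuron is created in every free neighbor slot
    with an interpolated weight, and the winner's CEQ (now spent on
    growth) resets to zero.  Interior winner: its CEQ is halved and the
    removed half is split equally among its occupied neighbors, conserving
    total CEQ.  Below threshold nothing changes.

    Returns the ids of any neurons created.
    """
    if gt <= 0:
        raise ValueError("growth threshold must be positive")
    s = state._id_slot[winner_id]
    ceq = float(state._ceq[s])
    if ceq < gt:
        return []
    pos = (int(state._rows[s]), int(state._cols[s]))
    free = free_neighbor_positions(state, pos)
    if free:                                   # boundary: grow
        new_ids = []
        for npos in free:
            w = interpolate_weight(state, winner_id, npos, rng)
            new_ids.append(state.add_neuron(npos, w, ceq=0.0, age=0))
        state._ceq[s] = 0.0
        return new_ids
    # interior: halve and redistribute
    occ = occupied_neighbor_positions(state, pos)
    share = ceq / (2 * len(occ))
    for npos in occ:
        state._ceq[state._pos_index[npos]] += share
    state._ceq[s] = ceq / 2.0
    return []


def update_ages(state: NetworkState, winner_id: int,
                new_ids: Sequence[int] = ()) -> None:
    """Reset ages of winner and newborns to 0; everyone else ages by 1."""
    slots = state._occupied_slots()
    state._age[slots] += 1
    state._age[state._id_slot[winner_id]] = 0
    for nid in new_ids:
        state._age[state._id_slot[nid]] = 0


def prune(state: NetworkState, m: float) -> List[int]:
    """Delete every neuron whose age strictly exceeds ``m``.

    Pruning may leave holes and split the lattice into disconnected
    clusters; that is expected.  A prune that would empty the network
    keeps the single youngest neuron (lowest id on ties) and warns.
    """
    slots = state._occupied_slots()
    doomed = slots[state._age[slots] > m]
    if len(doomed) == 0:
        return []
    if len(doomed) == len(slots):
        ages = state._age[slots]
        young = slots[ages == ages.min()]
        keep = int(state._ids[young].min())
        warnings.warn("pruning would empty the network; retaining the "
                      "youngest neuron", RuntimeWarning)
        doomed = [s for s in doomed if int(state._ids[s]) != keep]
    removed = sorted(int(state._ids[s]) for s in doomed)
    for nid in removed:
        state.remove_neuron(nid)
    return removed


def age_threshold(rf: float, batch_size: int) -> int:
    """Age threshold from the ratio factor: ``M = round(RF * batch_size)``.

    RF is defined as M divided by the per-iteration batch size, so e.g.
    RF = 1.25 at batch 4000 gives M = 5000.  Half-up rounding.
    """
    if rf <= 0:
        raise ValueError("rf must be positive")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return int(math.floor(rf * batch_size + 0.5))


# ---------------------------------------------------------------------
# presentation pipeline and training loop
# ---------------------------------------------------------------------

def present_sample(state: NetworkState, x: np.ndarray, config: TrainConfig,
                   rng: np.random.Generator,
                   gt: Optional[float] = None) -> float:
    """Run one sample through the full pipeline; returns the winner distance.

    Order: winner search -> CEQ accumulation -> eta decay (when the decay
    cadence is per-presentation) -> weight update -> growth/redistribution
    (growing modes) -> age update -> pruning (pgsom only).  With the
    default per-iteration cadence the training loop decays eta once per
    batch instead.
    """
    if state.mode != config.mode:
        raise ValueError(f"state mode {state.mode!r} != config mode {config.mode!r}")
    x = np.asarray(x, dtype=float)
    winner, d = find_winner(state, x)
    accumulate_error(state, winner, d, state.eta)
    if config.eta_decay == "presentation":
        state.eta = decay_eta(state.eta, config.r, len(state), config.eta_min)
    update_weights(state, winner, x, state.eta, config.tau_for(state.dim))
    new_ids: List[int] = []
    if state.mode in ("gsom", "pgsom"):
        if gt is None:
            gt = growth_threshold(state.dim, config.sf)
        new_ids = grow_or_redistribute(state, winner, gt, rng)
        update_ages(state, winner, new_ids)
        if state.mode == "pgsom":
            m = config.age_limit()
            if not math.isinf(m):
                prune(state, m)
    state.presentations += 1
    return d


def init_network(X: np.ndarray, config: TrainConfig,
                 rng: np.random.Generator) -> NetworkState:
    """Seed a network for training on data ``X``.

    SOM mode lays out a fixed ``som_rows x som_cols`` grid; the growing
    modes start from the canonical 2x2 seed at (0,0),(0,1),(1,0),(1,1).
    Weights are drawn uniformly within the per-dimension data range.
    """
    X = np.asarray(X, dtype=float)
    dim = X.shape[1]
    lo, hi = X.min(axis=0), X.max(axis=0)
    scale = np.where(hi > lo, hi - lo, 1.0)
    state = NetworkState(dim=dim, mode=config.mode, eta=config.eta0)
    state.data_scale = scale
    if config.mode == "som":
        positions = [(r, c) for r in range(config.som_rows)
                     for c in range(config.som_cols)]
    else:
        positions = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for pos in positions:
        w = lo + rng.uniform(0.0, 1.0, size=dim) * (hi - lo)
        state.add_neuron(pos, w)
    return state


def train(X: np.ndarray, config: TrainConfig) -> NetworkState:
    """Train a network on sample matrix ``X`` (rows = samples).

    Runs ``max_iter`` iterations, each presenting a seeded random batch of
    ``batch_size`` samples (drawn without replacement when the pool is
    large enough, with replacement otherwise).  The learning rate decays
    continuously across the whole run.  The returned state carries a
    per-iteration log in ``state.history`` (iteration, neuron count, mean
    quantization error, eta).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D sample matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    rng = np.random.default_rng(config.seed)
    state = init_network(X, config, rng)
    state.history = []
    gt = None
    if config.mode != "som":
        gt = growth_threshold(X.shape[1], config.sf)
        m = config.age_limit()
        if config.mode == "pgsom" and not math.isinf(m) and m < 1:
            warnings.warn(f"age threshold M={m} < 1 prunes almost everything",
                          RuntimeWarning)
    n = X.shape[0]
    replace = config.batch_size > n
    for it in range(config.max_iter):
        idx = rng.choice(n, size=config.batch_size, replace=replace)
        qe_sum = 0.0
        for i in idx:
            qe_sum += present_sample(state, X[i], config, rng, gt=gt)
        if config.eta_decay == "iteration":
            state.eta = decay_eta(state.eta, config.r, len(state),
                                  config.eta_min)
        state.history.append({
            "iteration": it + 1,
            "neuron_count": len(state),
            "mean_qe": qe_sum / config.batch_size,
            "eta": state.eta,
        })
    return state


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def to_dict(state: NetworkState, config: Optional[TrainConfig] = None,
            label_map: Optional[Dict[int, int]] = None) -> dict:
    doc = {
        "mode": state.mode,
        "dim": state.dim,
        "eta": state.eta,
        "presentations": state.presentations,
        "data_scale": state.data_scale.tolist(),
        "neurons": [
            {"id": n.id, "row": n.pos[0], "col": n.pos[1],
             "age": n.age, "ceq": n.ceq, "w": n.w.tolist()}
            for n in state.neurons()
        ],
    }
    if config is not None:
        doc["config"] = asdict(config)
    if label_map is not None:
        doc["label_map"] = {str(k): int(v) for k, v in label_map.items()}
    return doc


def from_dict(doc: dict) -> Tuple[NetworkState, Optional[Dict[int, int]]]:
    state = NetworkState(dim=doc["dim"], mode=doc["mode"], eta=doc["eta"])
    state.presentations = doc["presentations"]
    state.data_scale = np.asarray(doc.get("data_scale", np.ones(doc["dim"])))
    max_id = -1
    for rec in doc["neurons"]:
        state._next_id = rec["id"]
        state.add_neuron((rec["row"], rec["col"]), np.asarray(rec["w"]),
                         ceq=rec["ceq"], age=rec["age"])
        max_id = max(max_id, rec["id"])
    state._next_id = max_id + 1
    label_map = None
    if "label_map" in doc:
        label_map = {int(k): int(v) for k, v in doc["label_map"].items()}
    return state, label_map


def save_model(path, state: NetworkState, config: Optional[TrainConfig] = None,
               label_map: Optional[Dict[int, int]] = None) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(state, config, label_map), fh, indent=1)


def load_model(path) -> Tuple[NetworkState, Optional[Dict[int, int]]]:
    with open(path) as fh:
        return from_dict(json.load(fh))
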