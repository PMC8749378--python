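import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgsom import core
from pgsom.core import (
    NetworkState,
    TrainConfig,
    accumulate_error,
    age_threshold,
    decay_eta,
    find_winner,
    grow_or_redistribute,
    growth_threshold,
    interpolate_weight,
    present_sample,
    prune,
    train,
    update_ages,
    update_weights,
)
from conftest import build_network


# -- winner search --------------------------------------------------------

def test_winner_identity_and_simple_choice():
    net = build_network([[0.0, 0.0], [3.0, 4.0]], [(0, 0), (0, 1)])
    wid, d = find_winner(net, [3.0, 4.0])
    assert wid == net.ids()[1] and d == 0.0
    wid, d = find_winner(net, [0.0, 1.0])
    assert wid == net.ids()[0] and d == pytest.approx(1.0)


def test_winner_matches_bruteforce_scan(rng):
    W = rng.normal(size=(50, 7))
    net = build_network(list(W), [(i, 0) for i in range(50)])
    for _ in range(20):
        x = rng.normal(size=7)
        wid, d = find_winner(net, x)
        # independent linear scan with explicit id tie-break
        best = min(((float(np.sum((x - n.w) ** 2)), n.id)
                    for n in net.neurons()))
        assert wid == best[1]
        assert d == pytest.approx(best[0])


def test_winner_ties_break_to_lowest_id():
    net = build_network([[1.0, 0.0], [1.0, 0.0]], [(0, 0), (5, 5)])
    wid, _ = find_winner(net, [0.0, 0.0])
    assert wid == min(net.ids())


def test_winner_dimension_mismatch_raises():
    net = build_network([[0.0, 0.0]], [(0, 0)])
    with pytest.raises(ValueError):
        find_winner(net, [1.0, 2.0, 3.0])


# -- learning-rate decay --------------------------------------------------

def test_decay_examples():
    assert decay_eta(0.1, 1.0, 100) == pytest.approx(0.099)
    assert decay_eta(0.5, 0.0, 10) == 0.5


def test_decay_degenerate_config_warns_and_floors():
    with pytest.warns(RuntimeWarning):
        assert decay_eta(0.5, 5.0, 4, eta_min=1e-4) == 1e-4


@settings(deadline=None, max_examples=50, derandomize=True)
@given(eta=st.floats(1e-4, 1.0), r=st.floats(0.0, 0.99),
       n=st.integers(1, 1000))
def test_repeated_decay_monotone_nonincreasing(eta, r, n):
    cur = eta
    for _ in range(5):
        nxt = decay_eta(cur, r, n)
        assert nxt <= cur
        cur = nxt


# -- CEQ accumulation -----------------------------------------------------

def test_accumulate_error_touches_only_winner():
    net = build_network([[0.0], [1.0], [2.0]], [(0, 0), (0, 1), (0, 2)],
                        dim=1)
    ids = net.ids()
    before = net.total_ceq()
    accumulate_error(net, ids[0], d=4.0, eta=0.1)
    assert net.ceq_of(ids[0]) == pytest.approx(0.4)
    assert net.ceq_of(ids[1]) == 0.0
    assert net.total_ceq() - before == pytest.approx(0.4)
    accumulate_error(net, ids[1], d=0.0, eta=0.5)
    assert net.ceq_of(ids[1]) == 0.0


# -- weight update --------------------------------------------------------

def test_update_weights_fixed_points():
    # input equal to all weights: nothing moves
    net = build_network([[1.0, 1.0], [1.0, 1.0]], [(0, 0), (0, 1)])
    W0 = net.weights_matrix()
    update_weights(net, net.ids()[0], np.array([1.0, 1.0]), eta=0.4)
    assert np.allclose(net.weights_matrix(), W0)


def test_update_weights_full_step_moves_winner_to_input():
    net = build_network([[0.0, 0.0]], [(0, 0)])
    x = np.array([2.5, -1.0])
    update_weights(net, net.ids()[0], x, eta=1.0)
    assert np.allclose(net.weight(net.ids()[0]), x)


def test_update_weights_neighbor_at_winner_weight_stays():
    net = build_network([[1.0, 2.0], [1.0, 2.0]], [(0, 0), (0, 1)])
    wid = net.ids()[0]
    update_weights(net, wid, np.array([5.0, 5.0]), eta=0.3)
    # neighbor equals the winner's pre-update weight: delta is zero
    assert np.allclose(net.weight(net.ids()[1]), [1.0, 2.0])


def test_update_weights_neighbor_moves_toward_old_winner():
    net = build_network([[0.0], [4.0]], [(0, 0), (0, 1)], dim=1)
    wid, nid = net.ids()
    x = np.array([0.0])
    update_weights(net, wid, x, eta=0.5, tau=16.0)
    # neighbor: w=4, d=16, factor exp(-1); moves toward old winner weight 0
    expected = 4.0 + 0.5 * (0.0 - 4.0) * math.exp(-1.0)
    assert net.weight(nid)[0] == pytest.approx(expected)
    assert net.weight(wid)[0] == 0.0


# -- growth threshold -----------------------------------------------------

def test_growth_threshold_values_and_monotonicity():
    assert growth_threshold(101, 0.8) == pytest.approx(22.537498682735186)
    assert growth_threshold(1, math.exp(-1.0)) == pytest.approx(1.0)
    assert growth_threshold(10, 0.3) > growth_threshold(10, 0.7)
    with pytest.raises(ValueError):
        growth_threshold(10, 1.5)


# -- growth / redistribution ---------------------------------------------

def test_below_threshold_no_change(rng):
    net = build_network([[0.0, 0.0]], [(0, 0)])
    wid = net.ids()[0]
    accumulate_error(net, wid, d=1.0, eta=1.0)   # ceq = 1 < gt
    assert grow_or_redistribute(net, wid, gt=1.5, rng=rng) == []
    assert len(net) == 1 and net.ceq_of(wid) == 1.0


def test_isolated_winner_grows_four_neurons(rng):
    net = build_network([[0.5, 0.5]], [(0, 0)])
    wid = net.ids()[0]
    accumulate_error(net, wid, d=10.0, eta=1.0)
    new = grow_or_redistribute(net, wid, gt=5.0, rng=rng)
    assert len(new) == 4 and len(net) == 5
    assert net.ceq_of(wid) == 0.0
    assert {net.neuron(n).pos for n in new} == {(-1, 0), (1, 0), (0, -1), (0, 1)}
    for n in new:
        assert net.ceq_of(n) == 0.0 and net.age_of(n) == 0


def test_interior_redistribution_conserves_ceq(block3x3, rng):
    center = block3x3.id_at((1, 1))
    block3x3._ceq[block3x3._id_slot[center]] = 10.0
    total0 = block3x3.total_ceq()
    new = grow_or_redistribute(block3x3, center, gt=8.0, rng=rng)
    assert new == []
    assert block3x3.ceq_of(center) == pytest.approx(5.0)
    for pos in [(0, 1), (2, 1), (1, 0), (1, 2)]:
        assert block3x3.ceq_of(block3x3.id_at(pos)) == pytest.approx(1.25)
    assert block3x3.total_ceq() == pytest.approx(total0)


# -- interpolation ladder -------------------------------------------------

def test_interpolate_extrapolates_through_winner(rng):
    net = build_network([[0.0, 0.0], [1.0, 1.0]], [(0, 0), (0, 1)])
    wid = net.ids()[1]          # winner at (0,1), opposite of (0,2) is (0,0)
    w = interpolate_weight(net, wid, (0, 2), rng)
    assert np.allclose(w, [2.0, 2.0])


def test_interpolate_midpoint_with_nearest_neighbor(rng):
    net = build_network([[0.0, 0.0], [2.0, 0.0]], [(0, 0), (1, 0)])
    wid = net.ids()[1]
    # target (1,1): opposite (1,-1) is empty; occupied neighbor is (0,0)
    w = interpolate_weight(net, wid, (1, 1), rng)
    assert np.allclose(w, [1.0, 0.0])


def test_interpolate_lone_neuron_bounded_and_reproducible():
    net = build_network([[5.0, 5.0]], [(0, 0)])
    net.data_scale = np.array([2.0, 2.0])
    wid = net.ids()[0]
    w1 = interpolate_weight(net, wid, (0, 1), np.random.default_rng(3))
    w2 = interpolate_weight(net, wid, (0, 1), np.random.default_rng(3))
    assert np.array_equal(w1, w2)
    assert np.all(np.abs(w1 - 5.0) <= 0.01 * net.data_scale)


def test_interpolate_on_occupied_slot_is_error(block3x3, rng):
    with pytest.raises(ValueError):
        interpolate_weight(block3x3, block3x3.id_at((1, 1)), (0, 1), rng)


# -- ages and pruning -----------------------------------------------------

def test_update_ages_resets_winner_and_newborns():
    net = build_network([[0.0]] * 3, [(0, 0), (0, 1), (0, 2)], dim=1)
    ids = net.ids()
    for nid, age in zip(ids, (5, 2, 0)):
        net._age[net._id_slot[nid]] = age
    update_ages(net, ids[0])
    assert [net.age_of(n) for n in ids] == [0, 3, 1]


def test_prune_strict_inequality_and_infinity():
    net = build_network([[0.0]] * 3, [(0, 0), (0, 1), (0, 2)], dim=1,
                        mode="pgsom")
    ids = net.ids()
    m = 4
    for nid, age in zip(ids, (0, m, m + 1)):
        net._age[net._id_slot[nid]] = age
    removed = prune(net, m)
    assert removed == [ids[2]]
    assert set(net.ids()) == {ids[0], ids[1]}
    assert prune(net, math.inf) == []


def test_prune_never_empties_network():
    net = build_network([[0.0]] * 3, [(0, 0), (0, 1), (0, 2)], dim=1,
                        mode="pgsom")
    ids = net.ids()
    for nid, age in zip(ids, (9, 7, 8)):
        net._age[net._id_slot[nid]] = age
    with pytest.warns(RuntimeWarning):
        removed = prune(net, 5)
    assert net.ids() == [ids[1]]           # youngest survives
    assert set(removed) == {ids[0], ids[2]}


def test_age_threshold_examples():
    assert age_threshold(1.25, 4000) == 5000
    assert age_threshold(1.0, 100) == 100
    assert age_threshold(1.5, 4000) == 6000


# -- presentation pipeline and training -----------------------------------

def test_som_mode_count_constant(rng):
    X = rng.normal(size=(64, 3))
    cfg = TrainConfig(mode="som", som_rows=4, som_cols=4, batch_size=32,
                      max_iter=3, seed=0)
    state = train(X, cfg)
    assert len(state) == 16
    assert {n.pos for n in state.neurons()} == {(r, c) for r in range(4)
                                                for c in range(4)}


def test_gsom_count_nondecreasing(rng):
    X = rng.normal(size=(200, 4))
    cfg = TrainConfig(mode="gsom", sf=0.5, batch_size=50, max_iter=4, seed=1)
    state = train(X, cfg)
    counts = [rec["neuron_count"] for rec in state.history]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_train_zero_iterations_returns_seed_network(rng):
    X = rng.normal(size=(30, 6))
    cfg = TrainConfig(mode="gsom", sf=0.5, max_iter=0, seed=2)
    state = train(X, cfg)
    assert len(state) == 4
    assert {n.pos for n in state.neurons()} == {(0, 0), (0, 1), (1, 0), (1, 1)}


def test_train_is_deterministic(rng):
    X = rng.normal(size=(120, 5))
    cfg = TrainConfig(mode="pgsom", sf=0.6, rf=1.0, batch_size=60,
                      max_iter=3, seed=7)
    s1 = train(X, cfg)
    s2 = train(X, cfg)
    assert np.array_equal(s1.weights_matrix(), s2.weights_matrix())
    assert s1.ids() == s2.ids()
    assert s1.eta == s2.eta


def test_train_rejects_bad_input():
    with pytest.raises(ValueError):
        train(np.empty((0, 3)), TrainConfig(mode="gsom"))
    with pytest.raises(ValueError):
        train(np.array([[1.0, np.nan]]), TrainConfig(mode="gsom"))


def test_gsom_grows_within_one_iteration_on_two_clusters(two_cluster_data):
    X, _ = two_cluster_data
    cfg = TrainConfig(mode="gsom", sf=0.9, batch_size=len(X), max_iter=1,
                      seed=0)
    state = train(X, cfg)
    assert len(state) > 4


def test_eta_monotone_and_positive_during_training(rng):
    X = rng.normal(size=(100, 3))
    cfg = TrainConfig(mode="gsom", sf=0.5, batch_size=50, max_iter=5, seed=3)
    state = train(X, cfg)
    etas = [rec["eta"] for rec in state.history]
    assert all(e > 0 for e in etas)
    assert all(a >= b for a, b in zip(etas, etas[1:]))


def test_pgsom_age_bound_and_winner_age_after_presentation(rng):
    X = rng.normal(size=(200, 3))
    cfg = TrainConfig(mode="pgsom", sf=0.5, m=25, batch_size=100,
                      max_iter=2, seed=5)
    state = train(X, cfg)
    assert max(n.age for n in state.neurons()) <= 25
    x = X[0]
    wid, _ = find_winner(state, x)
    present_sample(state, x, cfg, np.random.default_rng(0))
    # the most recent winner may have grown neighbors, but its age is 0
    if wid in state.ids():
        assert state.age_of(wid) == 0
    state.check_index()


# -- serialization --------------------------------------------------------

def test_model_json_roundtrip(tmp_path, rng):
    X = rng.normal(size=(80, 4))
    cfg = TrainConfig(mode="pgsom", sf=0.5, rf=1.0, batch_size=40,
                      max_iter=2, seed=11)
    state = train(X, cfg)
    path = tmp_path / "model.json"
    core.save_model(path, state, config=cfg, label_map={0: 3})
    loaded, lm = core.load_model(path)
    assert loaded.mode == state.mode
    assert loaded.ids() == state.ids()
    assert np.array_equal(loaded.weights_matrix(), state.weights_matrix())
    for nid in state.ids():
        assert loaded.neuron(nid).pos == state.neuron(nid).pos
        assert loaded.age_of(nid) == state.age_of(nid)
        assert loaded.ceq_of(nid) == state.ceq_of(nid)
    assert lm == {0: 3}
    # ids continue from the loaded maximum
    new = loaded.add_neuron((99, 99), np.zeros(4))
    assert new == max(state.ids()) + 1
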