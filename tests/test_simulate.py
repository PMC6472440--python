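"""Synthetic-data generators: determinism, logs, and distributional
properties at the default study-like settings."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from radkit.qmatrix import QMatrix
from radkit.ranges import pair_metrics
from radkit.simulate import (simulate_bd, simulate_bm, simulate_mixed_traits,
                             simulate_mk, simulate_ranges,
                             simulate_ranges_on_tree, simulate_tree_sample)


def test_bd_seed_determinism():
    t1, log1 = simulate_bd(0.575, 0.1, n_tips=15, seed=3)
    t2, log2 = simulate_bd(0.575, 0.1, n_tips=15, seed=3)
    assert t1.to_newick() == t2.to_newick()
    assert log1.to_json() == log2.to_json()
    t3, _ = simulate_bd(0.575, 0.1, n_tips=15, seed=4)
    assert t3.to_newick() != t1.to_newick()


def test_bd_tree_is_ultrametric_binary_with_positive_branches():
    tree, _ = simulate_bd(0.575, 0.2, n_tips=20, seed=1)
    assert tree.n_tips == 20
    assert tree.is_binary
    assert tree.is_ultrametric()
    lens = [e.length for e in tree.dendropy_tree.edges()
            if e.length is not None]
    assert min(lens) > 0


def test_bd_event_log_reconstructs_tip_count():
    tree, log = simulate_bd(0.6, 0.2, n_tips=12, seed=5)
    events = log.events
    # replay: births +1, deaths -1, starting from the crown pair
    k = 2
    for ev in events:
        k += 1 if ev["type"] == "speciation" else -1
        assert k >= 1
    # the reconstructed tree keeps only extant survivors
    births = sum(1 for e in events if e["type"] == "speciation")
    deaths = sum(1 for e in events if e["type"] == "extinction")
    assert 2 + births - deaths >= tree.n_tips


def test_bd_crown_age_matches_yule_expectation():
    # E[crown age | n tips] = (H_n - 1)/lambda under the stopping
    # convention used (one extra exponential wait after the nth tip)
    lam, n, reps = 0.575, 20, 150
    H = sum(1.0 / i for i in range(1, n + 1))
    ages = [simulate_bd(lam, 0.0, n_tips=n, seed=s)[0].root_age
            for s in range(reps)]
    expected = (H - 1) / lam
    assert np.mean(ages) == pytest.approx(expected, rel=0.1)


def test_bd_time_stopping():
    tree, _ = simulate_bd(0.8, 0.0, time=4.0, seed=2)
    assert tree.root_age == pytest.approx(4.0, rel=1e-6)


def test_bd_requires_exactly_one_stopping_rule():
    with pytest.raises(ValueError):
        simulate_bd(0.5, 0.0, seed=0)
    with pytest.raises(ValueError):
        simulate_bd(0.5, 0.0, n_tips=5, time=2.0, seed=0)


def test_tree_sample_jitter_and_crown_cv():
    base, _ = simulate_bd(0.575, 0.0, n_tips=25, seed=11)
    sample, _ = simulate_tree_sample(base, n_trees=40, jitter=0.15, seed=0)
    assert len(sample) == 40
    crowns = np.array([t.root_age for t in sample])
    cv = crowns.std() / crowns.mean()
    assert 0.05 < cv < 0.3     # jitter governs crown-age spread
    for t in sample:
        assert t.is_ultrametric()
        assert sorted(t.tip_labels) == sorted(base.tip_labels)


def test_mk_log_reconstructs_tip_states(balanced4, q2):
    trait, log = simulate_mk(balanced4, q2, seed=9, root_state="0")
    # replay events down the tree from the logged root state
    assert log.params["root_state"] == "0"
    by_node = {}
    for ev in log.events:
        by_node.setdefault(ev["node_below"], []).append(ev)
    # determinism
    trait2, _ = simulate_mk(balanced4, q2, seed=9, root_state="0")
    assert (trait == trait2).all()
    assert set(trait.values) <= set(q2.states)


def test_mk_high_rate_mixes_to_stationary(yule33):
    Q = QMatrix.er(("a", "b"), 50.0)
    counts = {"a": 0, "b": 0}
    for s in range(20):
        trait, _ = simulate_mk(yule33, Q, seed=s)
        for v in trait.values:
            counts[v] += 1
    frac = counts["a"] / (counts["a"] + counts["b"])
    assert 0.4 < frac < 0.6


def test_bm_variance_scales_with_tree(balanced4):
    xs = []
    for s in range(300):
        x, _ = simulate_bm(balanced4, sigma2=1.0, seed=s)
        xs.append(x["A"] - x["B"])
    # A and B diverge over 2 branches of length 1 -> Var = 2 sigma^2
    assert np.var(xs) == pytest.approx(2.0, rel=0.25)


def test_ranges_allopatric_no_overlap():
    labels = [f"s{i}" for i in range(10)]
    ranges, occ, _ = simulate_ranges(labels, mode="allopatric", seed=0)
    pm = pair_metrics(ranges)
    assert pm.off_diagonal("O").max() == 0.0
    assert set(occ["species"]) == set(labels)


def test_ranges_sympatric_full_overlap():
    labels = [f"s{i}" for i in range(8)]
    ranges, _, _ = simulate_ranges(labels, mode="sympatric", seed=0)
    pm = pair_metrics(ranges)
    assert pm.off_diagonal("O").min() == pytest.approx(1.0)


def test_ranges_mixed_targets_study_mean_overlap():
    labels = [f"s{i}" for i in range(14)]
    ranges, _, log = simulate_ranges(labels, mode="mixed", seed=0)
    pm = pair_metrics(ranges)
    mean = pm.off_diagonal("O").mean()
    # the default targets the published mean overlap 0.187
    assert abs(mean - 0.187) < 0.12
    assert log.params["mode"] == "mixed"


def test_ranges_on_tree_recent_pairs_overlap_more():
    tree, _ = simulate_bd(0.575, 0.0, n_tips=25, seed=3)
    ranges, _ = simulate_ranges_on_tree(tree, seed=3)
    pm = pair_metrics(ranges)
    D = tree.tip_distance_matrix()
    labs = pm.labels
    dists, overs = [], []
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            dists.append(D.loc[labs[i], labs[j]])
            overs.append(pm.O.loc[labs[i], labs[j]])
    r = np.corrcoef(dists, overs)[0, 1]
    assert r < 0   # closer relatives overlap more


def test_mixed_traits_structure_and_determinism():
    labels = [f"sp{i}" for i in range(20)]
    smap = {l: i % 3 for i, l in enumerate(labels)}
    t1, log = simulate_mixed_traits(labels, n_quant=3, n_qual=2,
                                    syndrome_map=smap, seed=4)
    t2, _ = simulate_mixed_traits(labels, n_quant=3, n_qual=2,
                                  syndrome_map=smap, seed=4)
    pd.testing.assert_frame_equal(t1, t2)
    assert list(t1.columns) == ["q1", "q2", "q3", "c1", "c2"]
    assert t1.shape == (20, 5)
    # zero separation removes recoverable structure between groups
    t0, _ = simulate_mixed_traits(labels, n_quant=3, n_qual=0,
                                  syndrome_map=smap, separation=0.0,
                                  seed=4)
    g0 = t0.loc[[l for l in labels if smap[l] == 0], "q1"]
    g1 = t0.loc[[l for l in labels if smap[l] == 1], "q1"]
    assert abs(g0.mean() - g1.mean()) < 2.0


def test_simulation_log_json_round_trip():
    _, log = simulate_bd(0.5, 0.1, n_tips=8, seed=0)
    blob = json.loads(log.to_json())
    assert blob["seed"] == 0
    assert blob["model"] == "birth-death"
    assert isinstance(blob["events"], list)
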