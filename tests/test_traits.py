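"""Discrete- and continuous-trait models: Mk likelihood, ancestral
states, stochastic mapping, Pagel transforms."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from radkit._treeindex import index_tree
from radkit.qmatrix import QMatrix
from radkit.simulate import simulate_bd, simulate_bm, simulate_mk
from radkit.traits import (StochasticMap, ancestral_marginal, fit_mk,
                           mk_loglik, multiaxis_signal, pagel_continuous,
                           pagel_discrete, shift_histogram, simmap_sample)
from radkit.trees import DatedTree, TreeSample


def test_mk_likelihood_normalises(balanced4, q2):
    # summed over every tip configuration the likelihood is exactly 1
    total = 0.0
    for combo in itertools.product(q2.states, repeat=4):
        trait = pd.Series(dict(zip(["A", "B", "C", "D"], combo)))
        total += math.exp(mk_loglik(balanced4, trait, q2,
                                    root_prior="uniform"))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_mk_cherry_limits():
    cherry = DatedTree.from_newick("(A:1,B:1);")
    same = pd.Series({"A": "0", "B": "0"})
    # q -> 0: tips must match the root state, L -> 1/2 under uniform prior
    slow = QMatrix.er(("0", "1"), 1e-9)
    assert math.exp(mk_loglik(cherry, same, slow, root_prior="uniform")) \
        == pytest.approx(0.5, abs=1e-6)
    # q -> inf: tips independent uniform, L -> 1/4
    fast = QMatrix.er(("0", "1"), 1e4)
    assert math.exp(mk_loglik(cherry, same, fast, root_prior="uniform")) \
        == pytest.approx(0.25, abs=1e-3)


def test_marginal_asr_matches_enumeration(balanced4, q2, mk_trait4):
    idx = index_tree(balanced4)
    P = {i: expm(q2.matrix * idx.branch_length[i])
         for i in range(idx.n_nodes) if i != idx.root}
    tip_state = {i: q2.states.index(mk_trait4[lab])
                 for i, lab in enumerate(idx.labels)}
    internals = list(idx.internal)
    tot = 0.0
    marg = np.zeros((idx.n_nodes, 2))
    for combo in itertools.product(range(2), repeat=len(internals)):
        assign = dict(tip_state)
        assign.update(dict(zip(internals, combo)))
        p = 0.5
        for node in range(idx.n_nodes):
            if node != idx.root:
                p *= P[node][assign[idx.parent[node]], assign[node]]
        tot += p
        for node in internals:
            marg[node, assign[node]] += p
    want = marg[internals] / tot
    got = ancestral_marginal(balanced4, mk_trait4, q2,
                             root_prior="uniform").loc[internals].values
    assert np.allclose(got, want, atol=1e-12)
    assert mk_loglik(balanced4, mk_trait4, q2, root_prior="uniform") == \
        pytest.approx(math.log(tot), abs=1e-10)


def test_asr_rows_are_distributions(yule33, q2):
    trait, _ = simulate_mk(yule33, q2, seed=0)
    probs = ancestral_marginal(yule33, trait, q2)
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert (probs.values >= 0).all()


def test_fit_mk_nesting(yule33):
    Q3 = QMatrix.er(("a", "b", "c"), 0.3)
    trait, _ = simulate_mk(yule33, Q3, seed=2)
    _, l_er, a_er = fit_mk(yule33, trait, "ER")
    _, l_sym, _ = fit_mk(yule33, trait, "SYM")
    _, l_ard, _ = fit_mk(yule33, trait, "ARD")
    assert l_er <= l_sym + 1e-6 <= l_ard + 2e-6
    # AICc uses tip count as sample size
    assert a_er == pytest.approx(-2 * l_er + 2 + 4 / (33 - 2), abs=1e-9)


def test_er_rate_recovery_reduced():
    # full 100-tip/25% criterion lives in the acceptance suite
    tree, _ = simulate_bd(0.5, 0.0, n_tips=100, seed=21)
    Q = QMatrix.er(("a", "b", "c"), 0.3)
    trait, _ = simulate_mk(tree, Q, seed=2)
    Qhat, _, _ = fit_mk(tree, trait, "ER")
    assert Qhat.matrix[0, 1] == pytest.approx(0.3, rel=0.5)


def test_missing_tip_errors(balanced4, q2):
    with pytest.raises(ValueError, match="missing"):
        mk_loglik(balanced4, pd.Series({"A": "0", "B": "1", "C": "0"}), q2)
    with pytest.raises(ValueError):
        mk_loglik(balanced4, pd.Series(
            {"A": "0", "B": "1", "C": "0", "D": "X"}), q2)


def test_simmap_determinism_and_tip_consistency(yule33, q2):
    trait, _ = simulate_mk(yule33, q2, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = simmap_sample(yule33, trait, q2, n_maps=10, seed=5)
        m2 = simmap_sample(yule33, trait, q2, n_maps=10, seed=5)
    for a, b in zip(m1, m2):
        assert np.array_equal(a.node_states, b.node_states)
        assert a.events == b.events
    # sampled tip states equal the observed data
    idx = index_tree(yule33)
    for m in m1:
        for i, lab in enumerate(idx.labels):
            assert m.states[m.node_states[i]] == trait[lab]


def test_simmap_frequencies_approach_marginals(q2):
    # reduced-map version of the consistency criterion (full 500-map
    # version in the acceptance suite)
    tree, _ = simulate_bd(0.5, 0.0, n_tips=20, seed=42)
    trait, _ = simulate_mk(tree, q2, seed=3, root_state="0")
    probs = ancestral_marginal(tree, trait, q2, root_prior="uniform")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps = simmap_sample(tree, trait, q2, n_maps=400,
                             root_prior="uniform", seed=7)
    idx = index_tree(tree)
    freq = np.zeros((idx.n_nodes, 2))
    for m in maps:
        for node in range(idx.n_nodes):
            freq[node, m.node_states[node]] += 1
    freq /= len(maps)
    internal = list(idx.internal)
    assert np.max(np.abs(freq[internal] - probs.loc[internal].values)) \
        < 0.08


def test_shift_histogram_matches_event_log_exactly(yule33, q2):
    # histogram of a map built from the simulation truth reproduces the
    # event log bin-for-bin
    trait, log = simulate_mk(yule33, q2, seed=11)
    events = {}
    for ev in log.events:
        events.setdefault(ev["node_below"], []).append(
            (ev["age"], ev["from"], ev["to"]))
    truth = StochasticMap(states=q2.states, node_states=np.zeros(
        2 * yule33.n_tips - 1, dtype=int), events=events)
    hist = shift_histogram([truth], bin_width=0.5)
    ages = [ev["age"] for ev in log.events]
    manual, _ = np.histogram(ages, bins=hist.bin_edges)
    assert np.array_equal(hist.counts[0], manual)
    assert hist.counts.sum() == len(ages)


def test_histogram_bins_anchored_at_present(yule33, q2):
    trait, _ = simulate_mk(yule33, q2, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps = simmap_sample(yule33, trait, q2, n_maps=20, seed=0)
    hist = shift_histogram(maps, bin_width=0.5)
    assert hist.bin_edges[0] == 0.0
    assert np.allclose(np.diff(hist.bin_edges), 0.5)


# --- Pagel statistics ------------------------------------------------------

def test_lambda_high_on_brownian_low_on_permuted():
    tree, _ = simulate_bd(0.5, 0.0, n_tips=80, seed=11)
    x, _ = simulate_bm(tree, sigma2=1.0, seed=5)
    assert pagel_continuous(tree, x, "lambda").estimate > 0.9
    rng = np.random.default_rng(9)
    xs = pd.Series(rng.permutation(x.values), index=x.index)
    assert pagel_continuous(tree, xs, "lambda").estimate <= 0.2


def test_kappa_near_one_on_brownian():
    tree, _ = simulate_bd(0.5, 0.0, n_tips=80, seed=11)
    x, _ = simulate_bm(tree, sigma2=1.0, seed=5)
    assert 0.6 < pagel_continuous(tree, x, "kappa").estimate < 1.4


def test_pagel_guards(balanced4):
    tiny = DatedTree.from_newick("(A:1,B:1);")
    with pytest.raises(ValueError):
        pagel_continuous(tiny, pd.Series({"A": 0.0, "B": 1.0}), "lambda")
    const = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
    with pytest.raises(ValueError):
        pagel_continuous(balanced4, const, "lambda")


def test_pagel_discrete_identity(yule33, q2):
    # the transformed-tree fit at parameter 1 reduces to the plain fit
    trait, _ = simulate_mk(yule33, q2, seed=4)
    _, logl_plain, _ = fit_mk(yule33, trait, "ER")
    _, logl_k1, _ = fit_mk(yule33.transform_kappa(1.0), trait, "ER")
    assert logl_k1 == pytest.approx(logl_plain, abs=1e-8)
    # profile estimate sits within optimiser tolerance of that reduction
    est = pagel_discrete(yule33, trait, "lambda")
    assert abs(est.logL - logl_plain) < 5e-3
    assert est.estimate > 0.9


def test_multiaxis_signal_shape(yule33):
    x1, _ = simulate_bm(yule33, 1.0, seed=0)
    x2, _ = simulate_bm(yule33, 1.0, seed=1)
    scores = pd.DataFrame({"Axis1": x1, "Axis2": x2})
    out = multiaxis_signal(TreeSample([yule33]), scores, 2, "lambda")
    assert len(out["per_tree"]) == 1
    assert 0 <= out["median"] <= 1.05
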