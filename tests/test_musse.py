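"""State-dependent diversification: factorisation oracle, ODE accuracy,
model roster, fitting, MCMC."""

import math
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from radkit._treeindex import index_tree
from radkit.birthdeath import bd_loglik
from radkit.musse import (ModelConstraint, MusseFit, MusseParams,
                          enumerate_model_set, fit_musse, musse_loglik,
                          musse_mcmc)
from radkit.qmatrix import QMatrix
from radkit.simulate import simulate_bd, simulate_mk
from radkit.traits import mk_loglik


@pytest.fixture(scope="module")
def tree12():
    tree, _ = simulate_bd(0.5, 0.1, n_tips=12, seed=5)
    return tree


@pytest.fixture(scope="module")
def trait12(tree12):
    trait, _ = simulate_mk(tree12, QMatrix.er(("0", "1"), 0.4), seed=1)
    return trait


def _reference_loglik(tree, trait, p, root="obs", cond=True):
    """Adaptive-integrator SSE likelihood, branch by branch."""
    idx = index_tree(tree)
    k = p.k
    lam, mu, q = p.lam, p.mu, p.q
    qrow = q.sum(axis=1)

    def rhs(t, y):
        E, D = y[:k], y[k:]
        dE = mu - (lam + mu + qrow) * E + lam * E * E + q @ E
        dD = -(lam + mu + qrow) * D + 2 * lam * E * D + q @ D
        return np.concatenate([dE, dD])

    logsc = 0.0

    def up(node):
        nonlocal logsc
        if node < idx.n_tips:
            d0 = np.zeros(k)
            d0[p.states.index(str(trait[idx.labels[node]]))] = 1.0
            E0, t0 = np.zeros(k), 0.0
        else:
            c1, c2 = idx.children[node - idx.n_tips]
            d1, E1 = up(c1)
            d2, _ = up(c2)
            d0 = d1 * d2 * lam
            s = d0.sum()
            logsc += math.log(s)
            d0 /= s
            E0, t0 = E1, idx.age[node]
        if node == idx.root:
            return d0, E0
        sol = solve_ivp(rhs, (t0, idx.age[idx.parent[node]]),
                        np.concatenate([E0, d0]), rtol=1e-10, atol=1e-13)
        y = sol.y[:, -1]
        return y[k:], y[:k]

    sys.setrecursionlimit(10_000)
    d_root, E_root = up(idx.root)
    w = d_root / d_root.sum() if root == "obs" else np.full(k, 1 / k)
    val = float(w @ d_root)
    if cond:
        val /= float(w @ (lam * (1 - E_root) ** 2))
    return math.log(val) + logsc


def test_state_independent_factorises(tree12, trait12):
    # state-independent SSE likelihood = birth-death x Mk, both with and
    # without the crown-survival conditioning
    lam, mu, qr = 0.55, 0.12, 0.4
    Q = QMatrix.er(("0", "1"), qr)
    p = MusseParams(("0", "1"), np.array([lam, lam]), np.array([mu, mu]),
                    Q.matrix + np.diag(np.full(2, qr)))
    step = tree12.root_age * 0.001
    mk = mk_loglik(tree12, trait12, Q, root_prior="uniform")
    cond = musse_loglik(tree12, trait12, p, root="flat", step=step)
    assert cond == pytest.approx(
        bd_loglik(tree12, lam, mu, condition="crown_survival") + mk,
        abs=1e-6)
    plain = musse_loglik(tree12, trait12, p, root="flat",
                         condition_survival=False,
                         include_root_speciation=False, step=step)
    assert plain == pytest.approx(
        bd_loglik(tree12, lam, mu, condition="none") + mk, abs=1e-6)


def test_rk4_matches_adaptive_oracle(tree12, trait12):
    p = MusseParams(("0", "1"), np.array([0.8, 0.3]),
                    np.array([0.2, 0.05]),
                    np.array([[0.0, 0.6], [0.15, 0.0]]))
    got = musse_loglik(tree12, trait12, p)
    want = _reference_loglik(tree12, trait12, p)
    assert got == pytest.approx(want, abs=1e-5)


def test_rk4_stable_at_stiff_rates(tree12, trait12):
    # fast transitions used to blow up the fixed-step sweep
    p = MusseParams(("0", "1"), np.array([0.6, 0.2]), np.zeros(2),
                    np.array([[0.0, 40.0], [40.0, 0.0]]))
    got = musse_loglik(tree12, trait12, p)
    want = _reference_loglik(tree12, trait12, p)
    assert got == pytest.approx(want, abs=1e-4)


def test_relabelling_invariance(tree12, trait12):
    p = MusseParams(("0", "1"), np.array([0.8, 0.3]),
                    np.array([0.2, 0.05]),
                    np.array([[0.0, 0.6], [0.15, 0.0]]))
    swapped_trait = trait12.map({"0": "1", "1": "0"})
    p_swapped = MusseParams(("0", "1"), p.lam[::-1].copy(),
                            p.mu[::-1].copy(), p.q[::-1, ::-1].copy())
    assert musse_loglik(tree12, trait12, p) == pytest.approx(
        musse_loglik(tree12, swapped_trait, p_swapped), abs=1e-9)


def test_tiny_tree_oracle():
    from radkit.trees import DatedTree
    cherry = DatedTree.from_newick("(A:2.0,B:2.0);")
    p = MusseParams(("0", "1"), np.array([0.7, 0.4]),
                    np.array([0.1, 0.0]),
                    np.array([[0.0, 0.3], [0.2, 0.0]]))
    trait = pd.Series({"A": "0", "B": "1"})
    got = musse_loglik(cherry, trait, p, root="flat")
    want = _reference_loglik(cherry, trait, p, root="flat")
    assert got == pytest.approx(want, abs=1e-6)


def test_param_validation():
    with pytest.raises(ValueError):
        MusseParams(("0", "1"), np.array([0.5, -0.1]), np.zeros(2),
                    np.zeros((2, 2)))
    with pytest.raises(ValueError):
        MusseParams(("0", "1"), np.array([0.5, 0.5]), np.array([-0.1, 0]),
                    np.zeros((2, 2)))
    with pytest.raises(ValueError):
        MusseParams(("0", "1"), np.array([0.5, 0.5]), np.zeros(2),
                    np.zeros((3, 3)))


def test_unknown_state_errors(tree12):
    p = MusseParams(("0", "1"), np.array([0.5, 0.5]), np.zeros(2),
                    np.full((2, 2), 0.1) - np.diag([0.1, 0.1]))
    bad = pd.Series({lab: "Z" for lab in tree12.tip_labels})
    with pytest.raises(ValueError):
        musse_loglik(tree12, bad, p)


def test_roster_is_seventeen_unique_models():
    roster = enumerate_model_set(3)
    assert len(roster) == 17
    assert len({c.name for c in roster}) == 17
    ks = sorted(c.n_free(3) for c in roster)
    # null model: shared lambda + shared q, zero extinction
    assert min(ks) == 2
    # full model: 3 lambdas + 3 mus + 6 transition rates
    assert max(ks) == 12
    with pytest.raises(ValueError):
        enumerate_model_set(1)


def test_constraint_expansion_round_trip():
    c = ModelConstraint("one", "one_state", "zero", "shared")
    p = c.expand(np.array([0.9, 0.3, 0.2]), ("a", "b", "c"))
    assert p.lam[0] == 0.9 and p.lam[1] == p.lam[2] == 0.3
    assert (p.mu == 0).all()
    off = p.q[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 0.2)


def test_fit_null_model_recovers_rate():
    tree, _ = simulate_bd(0.575, 0.0, n_tips=33, seed=9)
    trait, _ = simulate_mk(tree, QMatrix.er(("0", "1"), 0.4), seed=4)
    c = ModelConstraint("null", "shared", "zero", "shared")
    fit = fit_musse(tree, trait, c, n_starts=2)
    assert fit.k == 2
    assert fit.params.lam[0] == pytest.approx(0.575, rel=0.5)
    assert math.isfinite(fit.AICc)


def test_mcmc_deterministic_and_centred():
    tree, _ = simulate_bd(0.575, 0.0, n_tips=20, seed=9)
    trait, _ = simulate_mk(tree, QMatrix.er(("0", "1"), 0.4), seed=4)
    c = ModelConstraint("null", "shared", "zero", "shared")
    fit = fit_musse(tree, trait, c, n_starts=1)
    ch1 = musse_mcmc(tree, trait, c, ml_fit=fit, n_gen=400, burnin=100,
                     seed=3)
    ch2 = musse_mcmc(tree, trait, c, ml_fit=fit, n_gen=400, burnin=100,
                     seed=3)
    pd.testing.assert_frame_equal(ch1, ch2)
    assert len(ch1) == 300
    # posterior mass near the ML point for the speciation rate
    lam_ml = fit.params.lam[0]
    assert abs(ch1["p0"].median() - lam_ml) / lam_ml < 0.6
    assert ch1.attrs["param_names"] == ["lambda", "q"]
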