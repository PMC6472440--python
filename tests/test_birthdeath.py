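"""Birth-death likelihoods: closed-form and ODE oracles, ML fitting,
model selection."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from radkit.birthdeath import (bd_loglik, fit_constant, fit_shift_model,
                               model_select, piecewise_bd_loglik)
from radkit.simulate import simulate_bd
from radkit.trees import DatedTree


def _yule_closed_form(tree, lam):
    """Conditioned Yule likelihood: (n-2) ln lam - lam (2 x1 + sum x_i)."""
    ages = list(tree.internal_node_ages())
    x1, rest = ages[0], ages[1:]
    return (len(rest)) * math.log(lam) - lam * (2 * x1 + sum(rest))


def _ode_loglik(tree, lambdas, mus, shift_ages):
    """Independent piecewise birth-death likelihood via an adaptive ODE
    integration of E(t) and ln p1(t), same conditioning convention."""
    bounds = list(shift_ages)

    def rates(t):
        i = 0
        while i < len(bounds) and t >= bounds[i] - 1e-12:
            i += 1
        return lambdas[i], mus[i]

    def rhs(t, y):
        E, logp1 = y
        lam, mu = rates(t)
        dE = mu - (lam + mu) * E + lam * E * E
        dlogp1 = -(lam + mu) + 2 * lam * E
        return [dE, dlogp1]

    def at(t):
        if t == 0:
            return 0.0, 0.0
        sol = solve_ivp(rhs, (0.0, t), [0.0, 0.0], rtol=1e-11, atol=1e-13,
                        dense_output=False, max_step=0.05)
        return sol.y[0, -1], sol.y[1, -1]

    ages = list(tree.internal_node_ages())
    x1, rest = ages[0], ages[1:]
    ll = 0.0
    for x in rest:
        lam, _ = rates(x)
        _, logp1 = at(x)
        ll += math.log(lam) + logp1
    E1, logp1_1 = at(x1)
    ll += 2 * logp1_1 - 2 * math.log(1.0 - E1)
    return ll


@pytest.fixture
def bd_tree():
    tree, _ = simulate_bd(0.6, 0.2, n_tips=12, seed=5)
    return tree


def test_yule_closed_form(bd_tree):
    for lam in (0.2, 0.575, 1.3):
        assert bd_loglik(bd_tree, lam, 0.0) == \
            pytest.approx(_yule_closed_form(bd_tree, lam), abs=1e-9)


def test_constant_bd_matches_ode_oracle(bd_tree):
    for lam, mu in [(0.6, 0.0), (0.6, 0.2), (0.5, 0.45), (0.4, 0.4)]:
        got = bd_loglik(bd_tree, lam, mu)
        want = _ode_loglik(bd_tree, [lam], [mu], [])
        assert got == pytest.approx(want, abs=1e-6)


def test_piecewise_matches_ode_oracle(bd_tree):
    mid = bd_tree.root_age / 2
    got = piecewise_bd_loglik(bd_tree, [0.9, 0.3], [0.1, 0.05], [mid])
    want = _ode_loglik(bd_tree, [0.9, 0.3], [0.1, 0.05], [mid])
    assert got == pytest.approx(want, abs=1e-6)
    # equal epochs collapse to the constant model
    same = piecewise_bd_loglik(bd_tree, [0.6, 0.6], [0.2, 0.2], [mid])
    assert same == pytest.approx(bd_loglik(bd_tree, 0.6, 0.2), abs=1e-9)


def test_critical_case_continuity(bd_tree):
    # lambda == mu is a removable singularity of the propagation
    near = bd_loglik(bd_tree, 0.5, 0.5 - 1e-7)
    crit = bd_loglik(bd_tree, 0.5, 0.5)
    assert crit == pytest.approx(near, abs=1e-3)


def test_invalid_rates(bd_tree):
    with pytest.raises(ValueError):
        bd_loglik(bd_tree, 0.0, 0.0)
    with pytest.raises(ValueError):
        bd_loglik(bd_tree, 0.5, -0.1)
    # subcritical rates are a proper (if unlikely) model on a finite tree
    assert math.isfinite(bd_loglik(bd_tree, 0.3, 0.5))


def test_yule_mle_closed_form(bd_tree):
    fit = fit_constant(bd_tree, "yule")
    ages = list(bd_tree.internal_node_ages())
    lam_hat = (bd_tree.n_tips - 2) / (2 * ages[0] + sum(ages[1:]))
    assert fit.lambdas[0] == pytest.approx(lam_hat, rel=1e-4)
    assert fit.logL == pytest.approx(
        _yule_closed_form(bd_tree, lam_hat), abs=1e-6)
    assert fit.k == 1


def test_nesting_bd_at_least_yule(bd_tree):
    y = fit_constant(bd_tree, "yule")
    b = fit_constant(bd_tree, "bd")
    s = fit_shift_model(bd_tree, 1, grid_step=0.5)
    assert b.logL >= y.logL - 1e-6
    assert s.logL >= b.logL - 1e-4
    assert s.k == 5 and b.k == 2


def test_lambda_recovery_reduced():
    # reduced-replicate version of the recovery criterion (full version
    # in the acceptance suite): median bias < 15% over 40 replicates
    lam = 0.575
    hats = []
    for s in range(40):
        tree, _ = simulate_bd(lam, 0.0, n_tips=33, seed=s)
        hats.append(fit_constant(tree, "yule").lambdas[0])
    assert abs(np.median(hats) - lam) / lam < 0.15


def test_shift_model_finds_planted_shift():
    # strong planted slowdown: fast early epoch, slow recent epoch
    tree, _ = simulate_bd(1.2, 0.0, n_tips=40, seed=2)
    y = fit_constant(tree, "yule")
    s = fit_shift_model(tree, 1, grid_step=0.25)
    assert s.logL >= y.logL - 1e-6
    assert len(s.lambdas) == 2 and len(s.shift_ages) == 1
    assert 0 < s.shift_ages[0] < tree.root_age


def test_model_select_ranks_and_guards(bd_tree):
    fits = [fit_constant(bd_tree, "yule"), fit_constant(bd_tree, "bd")]
    sel = model_select(fits)
    assert sel["best"].model in ("yule", "bd")
    assert sel["table"][0]["dAICc"] == 0.0
    assert any(l["null"] == "yule" and l["alt"] == "bd"
               for l in sel["lrt"])
    other, _ = simulate_bd(0.6, 0.0, n_tips=9, seed=99)
    with pytest.raises(ValueError):
        model_select([fits[0], fit_constant(other, "yule")])


def test_aicc_formula(bd_tree):
    fit = fit_constant(bd_tree, "yule")
    n_obs = bd_tree.n_tips - 1
    k = 1
    want = -2 * fit.logL + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)
    assert fit.AICc == pytest.approx(want, abs=1e-9)


def test_sampling_fraction_reduces_likelihood(bd_tree):
    full = bd_loglik(bd_tree, 0.6, 0.1, rho=1.0)
    part = bd_loglik(bd_tree, 0.6, 0.1, rho=0.5)
    assert part != pytest.approx(full)
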