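"""Birth-death likelihoods and ML diversification model fitting.

The likelihood is that of the reconstructed (extant-only) tree under a
constant-rate or piecewise-constant birth-death process, conditioned on
the crown age and on survival of both crown lineages.  Writing E(t) for
the probability that a lineage alive at age t leaves no sampled
descendant and p1(t) for the probability (density factor) that it leaves
exactly one, the log-likelihood of a tree with crown age x1 and internal
node ages x2..x_{n-1} is

    sum_{i=2}^{n-1} [ln lambda(x_i) + ln p1(x_i)]
        + 2 ln p1(x1) - 2 ln(1 - E(x1)).

E and p1 satisfy one-dimensional ODEs whose piecewise-constant-rate
solution is closed-form; shift models simply propagate (E, log p1)
across epoch boundaries.  Model selection uses AICc (sample size = number
of internal nodes) and likelihood-ratio tests for nested pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .trees import DatedTree

__all__ = [
    "DiversificationFit",
    "bd_loglik",
    "piecewise_bd_loglik",
    "fit_constant",
    "fit_shift_model",
    "model_select",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# E / p1 propagation for one constant-rate interval


def _propagate(E0: float, logp1_0: float, lam: float, mu: float,
               dt: float) -> Tuple[float, float]:
    """Advance (E, log p1) backward in time by ``dt`` under rates (lam, mu)."""
    if dt <= 0:
        return E0, logp1_0
    r = lam - mu
    if mu == 0.0 and E0 < 1e-300:
        return 0.0, logp1_0 - lam * dt
    if abs(r) < 1e-10:  # critical case lambda == mu
        v0 = 1.0 - E0
        denom = 1.0 + lam * v0 * dt
        return 1.0 - v0 / denom, logp1_0 - 2.0 * math.log(denom)
    ratio = mu / lam
    if abs(E0 - ratio) < 1e-300:  # fixed point
        return E0, logp1_0 - r * dt
    u0 = (E0 - 1.0) / (E0 - ratio)
    u1 = u0 * math.exp(r * dt)
    E1 = (u1 * ratio - 1.0) / (u1 - 1.0)
    logp1 = logp1_0 + r * dt - 2.0 * math.log(abs((1.0 - u1) / (1.0 - u0)))
    return E1, logp1


class _PiecewiseBD:
    """Piecewise-constant birth-death process, epochs indexed from the
    present: epoch j spans ages [b_j, b_{j+1}) with b_0 = 0."""

    def __init__(self, lambdas: Sequence[float], mus: Sequence[float],
                 shift_ages: Sequence[float], rho: float = 1.0):
        shift_ages = sorted(float(s) for s in shift_ages)
        if len(lambdas) != len(shift_ages) + 1 or len(mus) != len(lambdas):
            raise ValueError("need one (lambda, mu) pair per epoch")
        if any(l <= 0 for l in lambdas):
            raise ValueError("lambda must be > 0 in every epoch")
        if any(m < 0 for m in mus):
            raise ValueError("mu must be >= 0 in every epoch")
        if not 0 < rho <= 1:
            raise ValueError("sampling fraction must lie in (0, 1]")
        self.lam = np.asarray(lambdas, dtype=float)
        self.mu = np.asarray(mus, dtype=float)
        self.bounds = np.array([0.0] + shift_ages)
        # boundary values of (E, log p1) at each epoch start
        E, logp1 = 1.0 - rho, math.log(rho)
        self._E0 = [E]
        self._logp1_0 = [logp1]
        for j in range(len(self.bounds) - 1):
            E, logp1 = _propagate(E, logp1, self.lam[j], self.mu[j],
                                  self.bounds[j + 1] - self.bounds[j])
            self._E0.append(E)
            self._logp1_0.append(logp1)

    def epoch_of(self, age: float) -> int:
        return int(np.searchsorted(self.bounds, age, side="right") - 1)

    def at(self, age: float) -> Tuple[float, float]:
        j = self.epoch_of(age)
        return _propagate(self._E0[j], self._logp1_0[j],
                          self.lam[j], self.mu[j], age - self.bounds[j])

    def lam_at(self, age: float) -> float:
        return float(self.lam[self.epoch_of(age)])


def _node_age_arrays(tree: DatedTree) -> Tuple[float, np.ndarray]:
    tree.require_ultrametric("birth-death likelihood")
    tree.require_binary("birth-death likelihood")
    ages = tree.internal_node_ages()  # descending, root first
    return float(ages[0]), np.asarray(ages[1:], dtype=float)


def piecewise_bd_loglik(tree: DatedTree, lambdas: Sequence[float],
                        mus: Sequence[float], shift_ages: Sequence[float],
                        rho: float = 1.0,
                        condition: str = "crown_survival",
                        include_root_speciation: bool = False) -> float:
    """Log-likelihood of the reconstructed tree under epochal rates.

    ``condition='crown_survival'`` (default) divides by the probability
    that both crown lineages survive to the present; ``'none'`` is the
    plain density given the crown age.  ``include_root_speciation`` adds
    a ln lambda factor at the root (used when cross-checking against
    state-dependent likelihoods that place one there).
    """
    crown, inner = _node_age_arrays(tree)
    proc = _PiecewiseBD(lambdas, mus, shift_ages, rho)
    logL = 0.0
    for x in inner:
        E, logp1 = proc.at(x)
        logL += math.log(proc.lam_at(x)) + logp1
    E1, logp1_crown = proc.at(crown)
    logL += 2.0 * logp1_crown
    if include_root_speciation:
        logL += math.log(proc.lam_at(crown))
    if condition == "crown_survival":
        if E1 >= 1.0 - _EPS:
            return -math.inf
        logL -= 2.0 * math.log(1.0 - E1)
    elif condition != "none":
        raise ValueError(f"unknown conditioning {condition!r}")
    return logL


def bd_loglik(tree: DatedTree, lambda_: float, mu: float,
              rho: float = 1.0, condition: str = "crown_survival",
              include_root_speciation: bool = False) -> float:
    """Constant-rate birth-death log-likelihood (mu=0 is pure birth).

    Defined for any lambda > 0 and mu >= 0, including the critical
    (lambda = mu) and subcritical cases: conditioning on the crown age
    and crown survival keeps the density proper on a finite tree.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return piecewise_bd_loglik(tree, [lambda_], [mu], [], rho, condition,
                               include_root_speciation)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class DiversificationFit:
    model: str                    # yule | bd | shift-K
    lambdas: List[float]          # per epoch, present -> past
    mus: List[float]
    shift_ages: List[float]       # ascending ages, [] for constant models
    logL: float
    k: int                        # free-parameter count
    AICc: float
    n_tips: int
    tree_token: Tuple = field(default_factory=tuple, repr=False)

    @property
    def net_rates(self) -> List[float]:
        return [l - m for l, m in zip(self.lambdas, self.mus)]


def _aicc(logL: float, k: int, n_obs: int) -> float:
    if n_obs - k - 1 <= 0:
        return math.inf
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def _tree_token(tree: DatedTree) -> Tuple:
    ages = tree.internal_node_ages()
    return (tree.n_tips, tuple(np.round(ages, 10)))


def fit_constant(tree: DatedTree, model: str = "yule",
                 rho: float = 1.0) -> DiversificationFit:
    """ML fit of the pure-birth ('yule') or constant birth-death model."""
    crown, inner = _node_age_arrays(tree)
    n = tree.n_tips
    if n < 3:
        raise ValueError("constant-model fitting needs n >= 3 tips")
    n_obs = n - 1
    token = _tree_token(tree)

    if model == "yule":
        res = optimize.minimize_scalar(
            lambda lg: -bd_loglik(tree, math.exp(lg), 0.0, rho),
            bounds=(-12.0, 6.0), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"Yule optimisation failed: {res}")
        lam = math.exp(res.x)
        logL = -res.fun
        k = 1
        return DiversificationFit("yule", [lam], [0.0], [], logL, k,
                                  _aicc(logL, k, n_obs), n, token)

    if model == "bd":
        def negloglik(x):
            r = math.exp(x[0])
            eps = 1.0 / (1.0 + math.exp(-x[1]))  # in (0,1)
            lam = r / (1.0 - eps)
            mu = lam * eps
            ll = bd_loglik(tree, lam, mu, rho)
            return -ll if math.isfinite(ll) else 1e12

        yule = fit_constant(tree, "yule", rho)
        best = None
        for x0 in ([math.log(yule.lambdas[0]), -6.0],
                   [math.log(yule.lambdas[0]), 0.0],
                   [math.log(yule.lambdas[0]) + 0.5, 1.0]):
            res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-9, "fatol": 1e-10,
                                             "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not math.isfinite(best.fun):
            raise RuntimeError("birth-death optimisation failed")
        r = math.exp(best.x[0])
        eps = 1.0 / (1.0 + math.exp(-best.x[1]))
        lam = r / (1.0 - eps)
        mu = lam * eps
        logL = -best.fun
        k = 2
        return DiversificationFit("bd", [lam], [mu], [], logL, k,
                                  _aicc(logL, k, n_obs), n, token)

    raise ValueError(f"unknown model {model!r}")


def _optimize_epochs(tree: DatedTree, shift_ages: List[float],
                     lam0: np.ndarray, mu0: np.ndarray, rho: float,
                     polish: bool) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimise epoch rates at fixed shift ages, starting from (lam0, mu0)."""
    m = len(shift_ages) + 1

    def unpack(x):
        lam = np.exp(x[:m])
        mu = np.exp(x[m:]) - 1e-9
        return lam, np.clip(mu, 0.0, None)

    def nll(x):
        lam, mu = unpack(x)
        try:
            ll = piecewise_bd_loglik(tree, lam, mu, shift_ages, rho)
        except (ValueError, OverflowError):
            return 1e12
        return -ll if math.isfinite(ll) else 1e12

    x0 = np.concatenate([np.log(lam0), np.log(mu0 + 1e-9)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-8,
                                     "maxiter": 4000 if polish else 800})
    lam, mu = unpack(res.x)
    return lam, mu, -res.fun


def fit_shift_model(tree: DatedTree, n_shifts: int,
                    grid_step: float = 0.1, rho: float = 1.0
                    ) -> DiversificationFit:
    """ML fit of a piecewise-constant model with ``n_shifts`` rate shifts.

    Shifts are added sequentially: starting from the constant birth-death
    optimum, each new shift age is scanned over a regular grid (default
    0.1 Myr) with epoch rates re-optimised at each candidate, and the
    winner keeps its rates.  Because every step starts from the previous
    optimum with a duplicated epoch, the log-likelihood is non-decreasing
    in the number of shifts.
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    if grid_step <= 0:
        raise ValueError("grid step must be > 0")
    n = tree.n_tips
    if n_shifts > n - 3:
        raise ValueError(
            f"{n_shifts} shifts exceed the information in {n - 1} internal "
            "nodes"
        )
    crown, _ = _node_age_arrays(tree)
    base = fit_constant(tree, "bd", rho)
    lam = np.array(base.lambdas)
    mu = np.array(base.mus)
    shifts: List[float] = []
    logL = base.logL
    grid = np.arange(grid_step, crown, grid_step)
    for _ in range(n_shifts):
        best = None
        for s in grid:
            if any(abs(s - t) < grid_step / 2 for t in shifts):
                continue
            cand = sorted(shifts + [float(s)])
            j = cand.index(float(s))
            lam_c = np.insert(lam, j, lam[j])
            mu_c = np.insert(mu, j, mu[j])
            lam_n, mu_n, ll = _optimize_epochs(tree, cand, lam_c, mu_c,
                                               rho, polish=False)
            if best is None or ll > best[3]:
                best = (cand, lam_n, mu_n, ll)
        if best is None:
            raise RuntimeError("no admissible shift-age candidate on grid")
        shifts, lam, mu, logL = best
    # polish rates at the selected shift configuration
    lam, mu, ll = _optimize_epochs(tree, shifts, lam, mu, rho, polish=True)
    logL = max(logL, ll)
    if ll >= logL:
        logL = ll
    if logL < base.logL:  # numerical safety: nested model cannot be worse
        lam = np.repeat(base.lambdas[0], n_shifts + 1)
        mu = np.repeat(base.mus[0], n_shifts + 1)
        logL = base.logL
    k = 2 * (n_shifts + 1) + n_shifts
    return DiversificationFit(f"shift-{n_shifts}", list(lam), list(mu),
                              list(shifts), logL, k,
                              _aicc(logL, k, n - 1), n, _tree_token(tree))


# ---------------------------------------------------------------------------
# model selection


_NESTING_ORDER = {"yule": 0, "bd": 1}


def _nested(a: DiversificationFit, b: DiversificationFit) -> bool:
    """Is model a nested in model b (a simpler)?"""
    def rank(f):
        if f.model in _NESTING_ORDER:
            return _NESTING_ORDER[f.model]
        return 2 + int(f.model.split("-")[1])
    return rank(a) < rank(b)


def model_select(fits: Sequence[DiversificationFit]) -> Dict:
    """Rank fits by AICc and report LRT p-values for nested pairs.

    All fits must come from the same tree.  The LRT p-value for a nested
    pair is the chi-square survival function of 2*deltaLogL with delta-k
    degrees of freedom.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    token = fits[0].tree_token
    if any(f.tree_token != token for f in fits):
        raise ValueError("fits come from different trees")
    ranked = sorted(fits, key=lambda f: (f.AICc, f.k))
    table = [{"model": f.model, "logL": f.logL, "k": f.k, "AICc": f.AICc,
              "dAICc": f.AICc - ranked[0].AICc} for f in ranked]
    lrt = []
    for i, a in enumerate(fits):
        for b in fits:
            if _nested(a, b) and b.k > a.k:
                stat = 2.0 * (b.logL - a.logL)
                p = float(stats.chi2.sf(max(stat, 0.0), b.k - a.k))
                lrt.append({"null": a.model, "alt": b.model,
                            "stat": stat, "df": b.k - a.k, "p": p})
    return {"best": ranked[0], "table": table, "lrt": lrt}
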