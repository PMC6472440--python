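# Methods and numerical choices

This document records the statistical models the package implements,
the numerical decisions behind them, and the boundary between what the
test suite reproduces from printed numbers and what requires external
inference.

## Net diversification (`radkit.netdiv`)

The crown-based Magallón–Sanderson estimator solves
`E[n | crown age t, rate r, relative extinction ε]` for `r`; at ε = 0
it reduces to `r = ln(n/2)/t`, and the stem variant to
`r = ln(n(1−ε)+ε)/t_stem`. Printed-table reproduction uses half-up
rounding at the printed precision (`round_half_up`), since banker's
rounding disagrees with the published values at several rows.

Area normalisation divides the rate either by the island area in km²
(`per_area`, reported to 2 significant figures) or by its natural
logarithm (`per_log_area`, 3 decimals): 1.04 species/Myr on Grande
Terre (18,600 km²) gives 0.106 species/Myr per log km² and
5.6 × 10⁻⁵ species/Myr per km².

One published crown-rate row (Chambeyronia–Kentiopsis, 0.12) is only
reproduced from the stem age, not the crown age given in the same row;
`build_comparative_table` computes from crown ages, and the tests
document the discrepancy rather than special-casing the package code.

## Birth–death likelihoods (`radkit.birthdeath`)

The reconstructed-tree likelihood is conditioned on the crown age and
on survival of both crown lineages. Extinction probability `E(t)` and
the log no-change density `log p₁(t)` propagate in closed form through
piecewise-constant epochs, with the critical case λ = μ handled by its
own limit formula. The likelihood stays proper (finite) for λ ≤ μ on a
finite tree, so no positivity-of-net-rate guard is imposed. Model
selection (Yule / constant birth–death / rate-shift epochs) uses AICc
with `n − 1` waiting times as the sample size, plus likelihood-ratio
tests for the nested pairs.

## Trait models (`radkit.traits`)

Mk likelihoods use Felsenstein pruning with per-branch matrix
exponentials; ER/SYM/ARD constraint patterns share the optimiser.
Marginal ancestral states come from the standard two-pass algorithm.
Stochastic mapping samples joint node states from the conditional
distributions and branch paths by rejection sampling with a
uniformisation fallback for long/fast branches. Shift histograms bin
change ages in 0.5-Myr bins anchored at the present.

Pagel λ is profiled on [0, 1.05] and κ on [0, 3] by bounded ML; the
multi-axis summary fits each ordination axis on each tree of a
posterior sample and reports the median with 5–95% quantiles. The
discrete-trait analogue refits the Mk model on the transformed tree.

## State-dependent diversification (`radkit.musse`)

The MuSSE E/D ordinary differential equations are integrated with a
vectorised fixed-step fourth-order Runge–Kutta sweep over a single
global age grid (valid because the tree is ultrametric, so `E(t)` is
shared by all lineages). Two safeguards matter:

- **Stiffness guard.** The step is capped at
  `0.1 / max(λᵢ + μᵢ + Σqᵢⱼ)`. Without it, fixed-step RK4 becomes
  unstable once (rate × step) approaches its stability limit and can
  return likelihoods that are wrong by orders of magnitude while
  looking finite.
- **Rate cap.** Optimisation and MCMC reject proposals with any rate
  above 100/Myr. On trees measured in Myr such rates are biologically
  meaningless, and the cap keeps the optimiser away from the regime
  where step control would make each evaluation arbitrarily expensive.

The model roster for 3 states has 17 members: the 12-model lattice
{λ shared/free} × {μ zero/shared/free} × {q shared/free} plus 5
"one-state-different" variants. A state-independent model factorises
exactly into (birth–death) × (Mk), which the tests exploit as an oracle.
The pipeline defaults to a reduced 4-model roster so a full run stays
affordable on one CPU; `full_roster: true` enables all 17.

## Niche ordination (`radkit.ordination`)

Hill–Smith ordination standardises quantitative columns (population
variance) and expands categorical columns to frequency-weighted
indicators, then takes a weighted SVD. It reduces exactly to
correlation PCA for all-quantitative tables and to (number of
variables) × the correspondence-analysis eigenvalues for
all-categorical tables; both reductions are tested. Syndromes come
from k-means on the leading axes (first-appearance relabelling for
determinism) with silhouette reported.

## Geography and age–range correlation (`radkit.ranges`, `radkit.arc`)

Species ranges are convex hulls of occurrence points, buffered by
0.5 km so singletons and collinear sets have positive area. Overlap is
`area(intersection)/min(areas)` (symmetric, in [0, 1], 1 for nested
ranges); asymmetry is `max(areas)/min(areas)` (≥ 1).

Age–range correlation averages the pairwise metric over all
cross-clade tip pairs at each internal node, weighting each side's
tips by their clade-balanced weights, and regresses the nodal values
on node age by unweighted ordinary least squares. Significance comes
from permuting tip labels on the metric matrix (two-sided on |slope|,
add-one-smoothed p). The `super_p` summary over a posterior tree
sample is the exact proportion of trees with p < α.

A construction detail that matters when simulating null data: tip
labels produced by the tree simulator follow birth order, which is
correlated with topology. A valid null must therefore assign simulated
ranges to tips in randomised order; positional assignment injects real
phylogenetic signal and the permutation test (correctly) rejects it.

## Generators (`radkit.simulate`)

All simulators are seeded and log their settings and event history
sufficient for replay. The birth–death sampler conditions on the tip
count and draws one extra waiting time after the nth tip so that crown
ages match the theoretical `E[t | n] = (H_n − 1)/λ`. Defaults mirror
the study conditions (λ = 0.575/Myr, 33 tips, mixed-range mean overlap
0.187, 3 trait syndromes). Problem sizes in the tests (12–100 tips)
are a package choice to keep the suite fast; the algorithms are
O(n log n)–O(n²) and run comfortably at empirical sizes.

## What is not desk-reproducible

The following published quantities require external inference on the
archived alignments/trees and are treated as *inputs*:

- Bayesian (BEAST) divergence times, e.g. the 4.54 Myr *Oxera* crown
  age and its 2.7–6.92 Myr HPD interval;
- the maximum-likelihood speciation rate 0.575 species/Myr on the
  dated maximum-clade-credibility tree, and BAMM rate-through-time
  curves (~0.71 → 0.31/0.4 species/Myr);
- the empirical mean range overlap 0.187 and the Pagel λ/κ posterior
  quantiles on the real trait data.

The acceptance suite instead verifies (a) exact reproduction of every
closed-form published rate, (b) likelihood agreement with independent
numerical oracles, and (c) statistical calibration of the estimators
on simulated data at the published settings.

## Other decisions

- Natural logarithms throughout (the printed per-log-area value only
  reproduces with ln, not log₁₀).
- MuSSE root state weighting defaults to weighting by the observed
  conditional likelihoods ("obs"); "flat" and "equilibrium" are
  options.
- Overlap uses intersection-over-smaller-range (not union) to match
  the published nested-range behaviour.
- ARC regression is unweighted OLS; nodal values are not reweighted by
  clade size beyond the clade-balanced tip weights.
- Stochastic-map node frequencies are compared to marginals at 500
  maps, where the Monte-Carlo standard error for a 50/50 node is
  ≈ 0.022; the worst node over a 33-tip tree therefore sits near the
  0.05 tolerance by construction. The sampler was additionally checked
  at 4000 maps (max deviation 0.018, consistent with pure Monte-Carlo
  noise).
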