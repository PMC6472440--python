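# radkit

Comparative-phylogenetics toolkit for island plant radiations, built
around the analysis of the *Oxera* (Lamiaceae) radiation on New
Caledonia: net-diversification estimation, birth–death model fitting,
discrete- and continuous-trait models, state-dependent diversification
(MuSSE), mixed-data niche ordination, geographic range metrics, and
age–range correlation, wired together by a reproducible CLI pipeline.

## Scientific background

New Caledonia's main island (Grande Terre, ~18,600 km²) hosts many
endemic plant radiations. Comparing their speciation tempo requires
estimators that work from the only quantities usually available in the
literature — extant species number `n` and crown (or stem) age `t` —
and that bracket the unknown extinction fraction ε = μ/λ. The
Magallón–Sanderson crown estimator does exactly that; at ε = 0 it
reduces to `r = ln(n/2)/t`. For the 33-species NC *Oxera* clade with a
crown age of 4.54 Myr this gives 0.62 species/Myr, rising to 1.04 at
the younger 2.7 Myr bound and falling to 0.20–0.51 under ε = 0.9 —
among the fastest rates recorded for the island, and comparable to
famous oceanic-island radiations (Hawaiian *Bidens*, Macaronesian
*Echium*) once island area is taken into account (0.106 species/Myr
per log km²).

Beyond rates, the package implements the downstream questions of such
studies: did diversification shift through time (piecewise birth–death
fits)? Is the trait syndrome structure real (Hill–Smith mixed-data
ordination plus clustering)? Do traits evolve gradually or in bursts
(Pagel λ and κ, stochastic character mapping)? Does a habitat state
drive speciation (MuSSE model roster with AICc selection and MCMC)?
And did speciation proceed in geographic isolation (range overlap,
asymmetry, and age–range correlation with a permutation null across a
posterior tree sample)?

## Worked example

```python
>>> from radkit import ms_crown_rate, normalize_rate, round_half_up
>>> round_half_up(ms_crown_rate(33, 4.54, 0.0), 2)   # NC Oxera crown rate
0.62
>>> round_half_up(ms_crown_rate(33, 2.7, 0.0), 2)    # younger age bound
1.04
>>> round_half_up(ms_crown_rate(33, 6.92, 0.9), 2)   # high-extinction bound
0.2
>>> r = ms_crown_rate(33, 2.7, 0.0)
>>> round_half_up(normalize_rate(r, 18_600, "per_log_area"), 3)
0.106
```

Run the whole pipeline on a synthetic bundle:

```sh
radkit demo --dir demo --seed 0        # writes inputs + config.yml, runs all stages
cat demo/out/report.md
```

Or stage by stage:

```sh
radkit netdiv --clades demo/clades.csv --hpd --normalize
radkit fitdiv --tree demo/tree.nwk --max-shifts 2
radkit ordinate --traits demo/traits.csv --k 3
radkit arc --trees demo/trees.nwk --pairs demo/out/pairs.tsv --iters 1000
radkit run demo/config.yml
```

## Reproduction

`scripts/acceptance.py` recomputes the headline published rates from
first principles and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out rates.json
```

Every value is closed-form (Magallón–Sanderson at the printed `n`, `t`,
ε, rounded half-up at the printed precision), so the output is
identical for any seed. The test suite additionally re-derives both
published comparison tables row by row, checks every likelihood against
independent numerical oracles, and verifies estimator calibration on
simulated data; see `docs/methods.md` for what is — and deliberately is
not — reproducible from the printed numbers alone (externally inferred
inputs such as the 4.54 Myr Bayesian crown age, the 0.575 species/Myr
maximum-likelihood speciation rate on the dated tree, and the 0.187
mean range overlap are consumed as inputs, not recomputed).
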