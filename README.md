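# pollendiv

**Pollen-host trait coding and trait-dependent diversification analysis
for bees.**

Many bee lineages differ in where they collect pollen: from flowers whose
anthers present pollen openly (*accessible* rewards — many Asteraceae,
Malvaceae, Cucurbitaceae) or from structurally complex "bee-flowers" that
conceal it (*restricted* rewards — many Fabaceae, Lamiaceae,
Boraginaceae). Whether shifts to restricted hosts changed macroevolutionary
diversification is a question that joins quantitative palynology to
phylogenetic comparative methods, and `pollendiv` implements that full
chain for people working on bee–flower macroevolution:

1. **Trait coding** — per-sample scopal pollen compositions are cleaned
   with the 5%-per-sample contamination filter, pooled with load-size
   weights, and coded as accessible (`A`), restricted (`R`), polymorphic
   (`AR`) or data-deficient; a parallel coding separates oligolectic
   specialists (≥ 95% of pollen from one plant family) from polylectic
   generalists. Four tip-state partitions (PA1/PA2/PA3 differing in how
   `AR` resolves, plus PS) feed the comparative analyses.
2. **Ancestral states** — a 2-state Mk model with Bayesian rate
   integration gives marginal ancestral-state posteriors per node, and
   per-node Bayes factors (stepping-stone marginal likelihoods of the two
   "fossilised" node states; BF > 5 significant).
3. **Diversification** — a state-dependent speciation–extinction (SSE)
   engine over observed × hidden state spaces with per-state sampling
   fractions ρ powers (a) a six-model maximum-likelihood ladder
   (`Mase`, `Mas`, `Mahse`, `M0`, `M0h2`, `M0h4`; all with the same
   three-rate transition structure) compared by AIC, and (b) Bayesian MCMC
   under exponential priors summarised as PP(d_R > d_A) — the posterior
   probability that restricted-state net diversification d = λ − μ
   exceeds the accessible-state value.
4. **Calibration** — a Gillespie simulator of trees + binary characters,
   an incomplete-sampling emulator parameterised by f (the assumed
   accessible share among unsampled species), a synthetic pollen-table
   generator, and orchestrated power / false-positive / sensitivity
   studies.

The likelihood core follows the standard D/E formulation: per-lineage
clade density `D_i` and extinction/non-sampling probability `E_i` per
combined state, propagated root-ward by

    dD_i/dt = −(λ_i + μ_i + Σ_j q_ij) D_i + Σ_j q_ij D_j + 2 λ_i E_i D_i
    dE_i/dt = μ_i − (λ_i + μ_i + Σ_j q_ij) E_i + Σ_j q_ij E_j + λ_i E_i²

with `D_parent = λ D_left D_right` at nodes and optional root conditioning
by `λ(1−E)²`. See `docs/methods.md` for the numerical choices and model
details.

## Worked example

Simulate a 150-tip clade in which restricted-state lineages speciate twice
as fast (λ_A = 0.1, λ_R = 0.2, μ = 0.03, q = 0.02 per Myr), then run the
Bayesian contrast (`examples/05_mcmc_contrast.py`):

```python
from pollendiv import (SimConfig, SSEParameters, simulate_bisse_tree,
                       run_mcmc, summarize_diversification)
from pollendiv.pollen import CharacterMatrix

rep = simulate_bisse_tree(SimConfig(
    params=SSEParameters.bisse(0.1, 0.2, 0.03, 0.03, 0.02, 0.02),
    stop=("n_tips", 150), seed=3))
chars = CharacterMatrix("PA1", {l: str(s) for l, s in rep.tip_states.items()})
trace = run_mcmc(rep.tree, chars, model="five_param_equal_mu",
                 n_iter=2000, burn_in_frac=0.2, seed=1)
summ = summarize_diversification(trace)
```

printing

```
retained samples: 1600 (2000 generations, 20% burn-in)
PP(d_R > d_A) = 0.986
median d_A = 0.0511, median d_R = 0.1516
95% CI of d_R - d_A: [0.0118, 0.1709]
```

PP(d_R > d_A) = 0.986 exceeds the 0.975 decision threshold: the posterior
puts 98.6% of its mass on faster net diversification of restricted-pollen
lineages, and the 95% credible interval of the difference excludes zero —
the analysis recovers the simulated two-fold effect. The ML ladder on a
similar replicate (`examples/04_fit_model_ladder.py`) prints

```
model  k      lnL     AIC  dAIC    d_A   d_R  supported_over_null
  Mas  6 -349.581 711.163 0.000 -0.027 0.187                 True
 Mase  7 -348.677 711.354 0.192  0.032 0.167                 True
   M0  5 -353.317 716.633 5.470  0.164 0.164                False
 M0h2  7 -351.971 717.941 6.779  0.163 0.163                False
```

— the state-dependent models undercut the best null by more than 2 AIC
points (`supported_over_null`), with the higher net diversification on the
restricted state.

Each script in `examples/` is a short narrative of one capability:
tree I/O and validation, pollen coding, ancestral states with Bayes
factors, the ML ladder, the MCMC contrast, the power/false-positive study,
and the f-sensitivity sweep.

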