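# Methods

`pollendiv` implements the full inference chain linking a bee clade's
pollen-host traits to its diversification: quantitative coding of scopal
pollen loads into binary characters, Bayesian ancestral-state
reconstruction with per-node Bayes factors, state-dependent
speciation–extinction (SSE) likelihoods over observed-by-hidden state
spaces with incomplete taxon sampling, maximum-likelihood model comparison,
MCMC posterior contrasts of net diversification, and the simulation studies
that calibrate those inferences. This note records the models, the
numerical choices, and the limits of what the synthetic-data tests show.

## Trait coding from pollen loads

Each pollen sample is a percentage composition over pollen types from one
female's scopa, with an original load-size class used as a pooling weight
(literature records without load sizes default to weight 1). Types below
5% *of each individual sample* are treated as contamination and removed
before renormalisation; filtering precedes pooling so that combining many
samples cannot dilute a real contaminant below detection. Pooled
load-weighted profiles are then coded twice:

* **Accessibility** — every pollen type is catalogued as *accessible*
  (openly presented anthers: many Asteraceae, Malvaceae, Cucurbitaceae) or
  *restricted* (concealed in structurally complex bee-flowers: many
  Fabaceae, Lamiaceae, Boraginaceae). A species is `A` or `R` when one
  category effectively exhausts its profile and polymorphic `AR` when both
  categories exceed a threshold share of the pooled profile. No explicit
  polymorphism threshold accompanies the 5% contamination rule in the
  source protocols, so the same 5% level is reused — the only threshold
  the protocol states. Types of unknown accessibility above that level
  make the species data-deficient.
* **Specificity** — a species is an oligolectic *specialist* when at least
  95% (inclusive) of its carried pollen belongs to a single plant family
  (optionally genus), otherwise a polylectic *generalist*.

Accessibility states resolve to tip states under three partitions that
differ only in how `AR` is scored — `PA1` (AR→restricted), `PA2`
(AR→ambiguous), `PA3` (AR→accessible) — plus the specificity partition
`PS` (specialist 0, generalist 1). Data-deficient species are coded
missing everywhere; ambiguous and missing tips enter every likelihood as
flat partials.

## Ancestral states (Mk)

The binary character evolves by a 2-state continuous-time Markov chain
with rates `q01`, `q10` per Myr; transition probabilities use the closed
2×2 form and likelihoods use Felsenstein pruning. The root prior defaults
to uniform (stationary is available). Bayesian machinery:

* **Rates** get independent exponential priors with mean = parsimony
  change count / total tree length, floored at 0.01 per Myr — a scale the
  data themselves suggest; sampling is coordinate-wise slice sampling on
  log-rates (tuning-free in two dimensions).
* **Node posteriors**: for each retained rate draw, marginal state
  probabilities at every node come from the analytic down/up two-pass
  algorithm; reported posteriors are their Monte-Carlo average. With rates
  fixed the analytic marginals are returned directly.
* **Node Bayes factors**: the node's state is fossilised to 0 and to 1;
  each constrained marginal likelihood is estimated by stepping-stone
  sampling over the rate prior with 10 power-posterior rungs spaced by
  Beta(0.3, 1) quantiles (rungs concentrated near the prior, where the
  integrand moves fastest); the harmonic-mean estimator was rejected as
  unstable. BF = 2·(ln mL(best) − ln mL(other)); BF > 5, strictly, counts
  as significant. A fixation with zero likelihood reports an infinite BF
  with a flag.

## SSE likelihood engine

The combined state space is the product of the two observed states
(`A`=0, `R`=1) and 1, 2 or 4 hidden classes, ordered `[A0, R0, A1, R1,
…]`. Per-lineage clade densities `D` and no-sampled-descendant
probabilities `E` follow the standard coupled ODEs; at internal nodes
`D_parent = λ · D_left · D_right`; at the root the per-state terms are
combined with weights (equal, or proportional to root `D` — the default)
and optionally divided by `λ(1−E)²` to condition on survival of both crown
lineages (default on). Both root options are runtime flags because the
original analyses do not pin them down. Incomplete sampling enters only at
the tips: `D = ρ_s`, `E = 1 − ρ_s`, with per-observed-state `ρ`.
Transition structure is deliberately sparse: two observed-state rates
within each hidden class, one hidden-class rate shared by every pair of
classes, and no dual (simultaneous observed + hidden) transitions.

**Integration.** The production integrator is a compiled fixed-substep
classical RK4 along each branch with substep `h = 0.02 / L`, where `L` is
the largest per-state total rate (λ+μ+outflow). At that setting the
accumulated per-path error is below 1e-7 on 300-tip trees — verified in
the test suite against an adaptive Dormand–Prince reference path (scipy,
rtol 1e-10) that remains available as `method="reference"`. For rates
above 1/Myr the substep is held at `h = h_factor` rather than shrunk
further: such regions are visited only transiently by optimisers and
samplers, RK4 remains stable there (hL ≤ 1 at the 20/Myr rate cap the
fitter enforces), and precision in biologically absurd corners is
irrelevant to the estimates. Optimisation uses `h_factor = 0.05` and MCMC
`0.1–0.2`; the induced log-likelihood perturbations (≤ ~1e-4) are orders
of magnitude below both the AIC decision margin and Monte-Carlo noise. `D`
is log-rescaled at nodes and on underflowing branches.

A closed-form constant-rate birth–death likelihood (`bd_loglik`, the exact
1-state specialisation with sampling fraction and optional conditioning)
is kept ODE-free; it provides starting points, the MCMC prior scale, and
the independent side of the factorisation test
`SSE(equal rates) = birth–death + Mk`.

## The six-model ladder and ML fitting

All models share three transition rates (`q01`, `q10`, `q_hidden`) and
differ in how λ and μ are tied over observed × hidden states: `Mase`
(state-dependent λ, μ; 7 free parameters), `Mas` (state-dependent λ,
shared μ; 6), `Mahse` (λ, μ free over all four combinations; 11), and the
nulls `M0` (5), `M0h2` (hidden-dependent only; 7), `M0h4` (four hidden
classes; 11). `Mase`, `Mas` and `M0` formally carry two hidden classes
with tied rates; such a space is exactly lumpable onto the plain 2-state
model — the likelihood is independent of `q_hidden` — and the fitter
evaluates them collapsed. The alternative reading (no hidden channel at
all) is numerically identical; the tied-channel construction was chosen
because it gives every model the same uniform three-rate structure.

Fitting is Nelder–Mead on log parameters: five starting points (the first
from the character-independent birth–death MLE with a parsimony-informed
transition rate; the rest jittered by lognormal(0, 0.5²) noise), a short
exploration from each, then a full polish from the best (simplex tolerance
1e-8, 5000-iteration cap). Callers can add `extra_starts`, e.g. a nested
model's MLE embedded in a richer model, which makes the ladder's
`lnL(M0) ≤ lnL(Mas) ≤ lnL(Mase)` monotonicity robust in practice. Models
are ranked by AIC = 2k − 2 lnL, ties broken toward fewer parameters; a
trait model is *supported* when it undercuts the best null by ≥ 2 AIC
points. Net diversification is reported per observed state as λ−μ averaged
over hidden classes with equal weights.

## MCMC diversification contrast

Two 2-state models: `five_param_equal_mu` (λ0, λ1, shared μ, q01, q10) and
`full_bisse` (adds μ1). Every parameter has an exponential prior with mean
2·r̂, where r̂ is the character-independent net-diversification MLE — the
convention of the standard BiSSE MCMC tooling. Sampling is coordinate-wise
slice sampling on the natural scale (positivity enforced by the prior
support), bracket widths tuned during burn-in from observed move sizes and
then frozen; slice sampling remains exact regardless of the widths. The
default empirical-analysis schedule is 10 000 generations with the first
20% discarded. The headline summary is PP(d_R > d_A): the fraction of
retained samples in which restricted-state net diversification strictly
exceeds the accessible-state value (ties count against), with the full
difference and ratio sample sets exposed for plotting. A `prior_only` mode
replaces the likelihood with a constant, which must reproduce the prior —
the standard sampler-correctness check, enforced in the tests.

## Simulation studies

The forward simulator is a Gillespie birth–death process started from a
crown pair sharing a root state drawn from the stationary transition
frequencies, with per-state speciation, extinction and flip events;
extinct lineages are pruned and the stopping rule is either elapsed time
or an extant-tip target (the present placed just before the next event
would fire). Survivorship is handled by acceptance–rejection so the
stopping rule stays exact. Incomplete sampling is emulated by pruning to a
target tip count with the unsampled composition controlled by `f` (the
assumed accessible-state share among unsampled species), and per-state
sampling fractions `ρ_0 = n_0/(n_0 + f·N_u)`, `ρ_1 = n_1/(n_1 +
(1−f)·N_u)`.

Study conditions follow the empirical design they probe: parameter
recovery uses 100 replicates of 300-tip trees at λ = (0.1, 0.2), μ = 0.03,
q = 0.01 (a two-fold speciation effect); false-positive control uses 40
state-independent replicates at λ = 0.15, μ = 0.03, q = 0.02 with the
PP > 0.975 decision threshold; the sensitivity analysis sweeps f over
{0.1, …, 0.9} by default. Within the power/false-positive studies the
per-replicate chains default to 1 000 generations (20% burn-in) — a
per-replicate inference setting, chosen so the multi-replicate studies run
at desk scale; the 10 000-generation schedule remains the default for
single empirical analyses. Decision thresholds (PP > 0.975; ΔAIC ≥ 2) are
configurable but default to the two-sided-5% and standard
information-criterion conventions.

The synthetic pollen generator is constructed so coding recovery is
provable, not incidental: category shares match the true state (both ≥
0.25 for `AR` before contamination), within-category splits over one or
two types are Dirichlet with bounded concentration, and the single
opposite-category contaminant is capped strictly below the 5% filter. It
emulates the *structure* of real pollen tables (1–22 replicates per
species, load-size weights, mixed hosts), not their hard parts: real data
carry identification uncertainty, unknown-accessibility types,
continuous gradations of mixed carriage near the thresholds, and
correlated contamination across samples. Passing the 100%-recovery test
therefore certifies the coding pipeline's logic (filter → pool →
threshold), not robustness to borderline empirical profiles — those
surface as `AR` or data-deficient calls that the partitions PA1–PA3 are
designed to bracket.

## Degenerate inputs and edge cases

Impossible data (e.g. discordant tips with zero transition rates) return
−∞ log-likelihood rather than raising; conditioning degeneracies (zero
`λ(1−E)²` against positive `D`) raise a flagged likelihood error carrying
the parameters. Zero-length branches are identities. Trees must be
strictly binary with finite non-negative branch lengths; ultrametricity is
validated with relative tolerance 1e-4 by default (chronogram rounding
makes stricter checks reject valid published trees). Slice-sampling chains
that cannot move shrink to the current point after a bounded number of
contractions. The `M0`-family collapse, label-swap and hidden-permutation
symmetries are enforced as property tests.

## Known limitations

* Hidden-state models are fit with the same three-rate structure
  throughout; cladogenetic change, time-varying rates and >2 observed
  states are out of scope.
* The Bayes-factor machinery integrates over rates but conditions on the
  tree; phylogenetic uncertainty is not propagated.
* Ratio summaries d_R/d_A are unstable when the denominator crosses zero
  in the posterior; the difference summary is the robust one.
* The trait-associated sequence-rate confound (a state with elevated
  molecular rates mimicking lower diversification) is acknowledged but not
  tested here; it requires a separate sequence-level method.
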