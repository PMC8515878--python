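"""Bayesian MCMC contrast of net diversification between host-use states.

Runs the 5-parameter equal-extinction model (state-dependent speciation,
shared extinction, free transition rates) with exponential priors, and
summarises PP(d_R > d_A): the posterior probability that restricted-pollen
lineages diversify faster.
"""

from pollendiv import (
    SimConfig,
    SSEParameters,
    run_mcmc,
    simulate_bisse_tree,
    summarize_diversification,
)
from pollendiv.pollen import CharacterMatrix

rep = simulate_bisse_tree(
    SimConfig(
        params=SSEParameters.bisse(0.1, 0.2, 0.03, 0.03, 0.02, 0.02),
        stop=("n_tips", 150),
        seed=3,
    )
)
chars = CharacterMatrix("PA1", {l: str(s) for l, s in rep.tip_states.items()})

trace = run_mcmc(rep.tree, chars, model="five_param_equal_mu",
                 n_iter=2000, burn_in_frac=0.2, seed=1)
print(f"retained samples: {len(trace.retained)} "
      f"({trace.n_iter} generations, {trace.burn_in_frac:.0%} burn-in)")

summ = summarize_diversification(trace)
lo, hi = summ.credible_interval(0.95)
print(f"PP(d_R > d_A) = {summ.pp_greater:.3f}")
print(f"median d_A = {summ.median_d0:.4f}, median d_R = {summ.median_d1:.4f}")
print(f"95% CI of d_R - d_A: [{lo:.4f}, {hi:.4f}]")
# PP above 0.975 is the two-sided-5% decision threshold used by the
# power and false-positive studies
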