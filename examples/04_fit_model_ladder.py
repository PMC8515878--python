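"""Fit the six-model SSE ladder by ML and compare by AIC.

Simulates a 120-tip tree with a genuine two-fold speciation effect of the
restricted state, fits the trait-dependent and null models under a global
sampling fraction, and prints the AIC table.  A trait model is "supported"
when it undercuts the best null by at least 2 AIC points.
"""

from pollendiv import (
    SamplingFractions,
    SimConfig,
    SSEParameters,
    build_model_spec,
    compare_aic,
    fit_ml,
    simulate_bisse_tree,
)
from pollendiv.pollen import CharacterMatrix

rep = simulate_bisse_tree(
    SimConfig(
        params=SSEParameters.bisse(0.1, 0.2, 0.03, 0.03, 0.02, 0.02),
        stop=("n_tips", 120),
        seed=7,
    )
)
chars = CharacterMatrix("PA1", {l: str(s) for l, s in rep.tip_states.items()})
sampling = SamplingFractions.global_fraction(0.6)

fits = [
    fit_ml(rep.tree, chars, build_model_spec(name), sampling, seed=1)
    for name in ("Mase", "Mas", "M0", "M0h2")
]
table = compare_aic(fits)
cols = ["model", "k", "lnL", "AIC", "dAIC", "d_A", "d_R", "supported_over_null"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# d_A / d_R are per-state net diversification (lambda - mu); under the
# simulated effect the restricted state should carry the larger d and the
# trait models should outrank the nulls
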