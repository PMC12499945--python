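"""Propagate LQ-parameter uncertainty into a per-fraction EQD2.

A uniform 3 Gy fraction has EUD = 3 Gy regardless of the LQ parameters, so
all of its EQD2 uncertainty enters through the alpha/beta ratio in the
2 Gy-equivalent conversion. With 30% normal uncertainty on alpha and beta
the Monte Carlo spread exceeds the first-order (delta-method) prediction,
because the sampled ratio alpha/beta is heavy-tailed.
"""

from stepgrad import LQParams, MCConfig, eqd2_per_fraction, propagate
from stepgrad.montecarlo import delta_method_sd_eqd2

params = LQParams()
for cv in (0.05, 0.10, 0.30):
    est = propagate(
        lambda p: eqd2_per_fraction(3.0, p),
        params,
        MCConfig(n_samples=10_000, seed=1, cv=cv),
    )
    pred = delta_method_sd_eqd2(3.0, params, cv)
    print(
        f"cv={cv:.2f}: EQD2/fr = {est.mean:.3f} +/- {est.sd:.4f} Gy "
        f"(first-order prediction {pred:.4f}, ratio {est.sd / pred:.2f})"
    )
print()
print(
    "At small CV the Monte Carlo SD matches the linear prediction; at the\n"
    "30% CV used for reporting, the ratio's nonlinearity inflates the true\n"
    "spread by roughly a quarter — the reason uncertainties here are always\n"
    "quoted from the Monte Carlo, not from linear error propagation."
)
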