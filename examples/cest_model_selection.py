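"""CEST profile fitting and exchange-vs-null model selection.

Simulates a proton CEST profile with a 0.4% excited state dipping at -2.8 ppm,
fits it both with and without exchange, and compares the two by Akaike and
Bayesian information-criterion weights.  A second, exchange-free profile shows
the null model winning when there is nothing to find.
"""

import protonex as px

probe = px.Probe("U38-H3", 600.0)
relax = px.RelaxParams(2.0, 20.0)
scheme = px.CESTScheme.default_grid((250.0, 500.0), span_ppm=6.0, step_ppm=0.5,
                                    n_quad=3)

for label, model in [
    ("0.4% excited state", px.two_state(0.004, 470.0, -2.8)),
    ("no exchange", px.two_state(0.0, 0.0, 0.0)),
]:
    data = px.gen_cest_profile(model, relax, probe, scheme,
                               px.NoiseModel(sigma=0.01, seed=3))
    fit_exch = px.fit_cest(data, "with-exchange", n_quad=3)
    fit_null = px.fit_cest(data, "no-exchange", n_quad=3)
    w = px.model_weights(fit_exch, fit_null)
    print(f"{label}:")
    print(f"  with-exchange fit: p = {fit_exch.params['p']:.4f}, "
          f"k_ex = {fit_exch.params['kex']:.0f} /s, "
          f"dw = {fit_exch.params['dw']:+.2f} ppm")
    print(f"  wAIC(exchange) = {w['waic_exchange']:.3f}   "
          f"wAIC(null) = {w['waic_null']:.3f}")
print("A weight near 1 for the exchange model flags a real minor-state dip;")
print("for featureless data the extra parameters are penalized and null wins.")
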