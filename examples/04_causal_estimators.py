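"""IPTW, instrumental-variable 2SLS and difference-in-differences on a
structural benchmark with a known treatment effect.

The benchmark injects a constant effect of 42.154 pad-test points, so each
estimator can be judged against the truth under its own identifying
assumption: IPTW removes observed confounding, IV removes unobserved
confounding through a randomized-encouragement instrument, and DiD removes
level (parallel-trends) confounding via the pre/post panel.
"""

from suipath import (
    did_effect,
    fit_propensity,
    generate_causal_benchmark,
    iptw_effect,
    iv_2sls,
    naive_effect,
)

TRUTH = 42.154

obs = generate_causal_benchmark(n=10_000, effect=TRUTH, seed=1, confounding=0.8)
pm = fit_propensity(obs, ["x1", "x2"], arm="treat")
iptw = iptw_effect(obs, pm, "y", arm="treat")
naive = naive_effect(obs, "y", arm="treat")
print(f"truth                 : {TRUTH}")
print(f"naive arm difference  : {naive.estimate:7.3f}  (biased by observed confounding)")
print(f"IPTW                  : {iptw.estimate:7.3f} ± {iptw.se:.3f}")

endo = generate_causal_benchmark(n=10_000, effect=TRUTH, seed=2,
                                 confounding=0.5, unobserved=1.0, instrument_strength=2.0)
iv = iv_2sls(endo, "y", "treat", "z")
print(f"IV / 2SLS             : {iv.estimate:7.3f} ± {iv.se:.3f}  "
      f"(first-stage F = {iv.extra['first_stage_f']:.0f})")

panel = generate_causal_benchmark(n=10_000, effect=TRUTH, seed=3, trend_confounding=0.0)
did = did_effect(panel, "pre", "post", arm="treat")
print(f"DiD (on improvements) : {-did.estimate:7.3f} ± {did.se:.3f}")
print()
print("Each adjusted estimator lands within a few SEs of 42.154 while the")
print("naive contrast is pulled away by confounding.")
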