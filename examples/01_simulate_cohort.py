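"""Generate a synthetic two-arm cohort and inspect its structure.

The generator emulates a matched observational study of laser therapy plus
pelvic-floor training (treatment arm, aq=1) versus training alone: per-arm
means/SDs for every baseline variable, a latent correlation structure, and
structural outcome models with configurable treatment effects.
"""

from suipath import CohortSpec, generate_cohort

spec = CohortSpec(n_treat=41, n_ctrl=41, seed=7)
cohort = generate_cohort(spec)

df = cohort.df
print(f"cohort: {df.shape[0]} patients x {df.shape[1]} variables (codes a..bj)")
print(f"constant columns (no variability, kept and flagged): {cohort.constant_columns}")
print()
print("per-arm means of key baseline variables:")
key = {"d": "age", "b": "bladder neck descent (cm)", "ai": "testosterone", "ao": "1-hr pad test (g)"}
summary = df.groupby("aq")[list(key)].mean().rename(columns=key).round(2)
print(summary)
print()
print("one-year outcomes (bi = dry, bj = returned to elite sport):")
print(df.groupby("aq")[["bi", "bj"]].mean().round(3))
print()
print("The treated arm shows higher testosterone and pad-test severity at")
print("baseline (the study's selection pattern) and much higher dryness and")
print("return rates at one year (the injected treatment effect).")
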