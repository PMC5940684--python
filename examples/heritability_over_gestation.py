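"""Estimate how heritability changes over gestation, end to end.

Simulates a large cohort (200 MZ + 600 DZ pairs keeps this example quick;
the generator defaults encode heritability rising to a late-second-trimester
peak while the shared-environment share declines), fits the spline mixed
growth model for estimated fetal weight, predicts each fetus at the four
anchor ages and decomposes the variance at each anchor into A/C/E.
"""

from twingrowth import ANCHOR_GAS, CohortConfig, fit_growth_lmm, predict_anchor_dataset, simulate_cohort
from twingrowth.pipeline import ace_at_anchor

config = CohortConfig(n_mz=200, n_dz=600, seed=7)
measurements, covariates, truth = simulate_cohort(config)
fit = fit_growth_lmm(measurements, covariates, "EFW")
anchors = predict_anchor_dataset({"EFW": fit}, ANCHOR_GAS)

print("EFW variance decomposition (estimate vs generative truth):")
print(f"{'anchor':>8} {'h2':>6} {'c2':>6} {'e2':>6}   {'true h2':>7} {'true c2':>7}")
for k, ga in enumerate(ANCHOR_GAS):
    res = ace_at_anchor(anchors, covariates, "EFW", ga)
    h2_t, c2_t, _ = truth.variance_plan["EFW"][k]
    print(f"{ga:7.2f}w {res.h2:6.2f} {res.c2:6.2f} {res.e2:6.2f}   "
          f"{h2_t:7.2f} {c2_t:7.2f}")
print("h2 should rise toward the late-second-trimester anchor while c2 "
      "falls from its first-trimester peak; estimates wobble by a few "
      "points at this cohort size.")
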