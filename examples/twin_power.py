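"""Power of a twin design to detect genetic and shared-environment variance.

Computes power by the expected-LRT non-centrality method for the 15 MZ +
133 DZ design under a truth of 25% additive-genetic and 50% shared-
environment variance, then shows how power grows with the number of pairs.
"""

from twingrowth import PowerSpec, power_ncp, power_sim

spec = PowerSpec(n_mz=15, n_dz=133, a2=0.25, c2=0.50, alpha=0.05,
                 component="AC-joint")
res = power_ncp(spec)
print(f"joint familial-variance test (ACE vs E-only): power = {res.power:.3f}, "
      f"non-centrality = {res.ncp:.1f}, critical value = {res.critical_value:.2f}")
print("the familial signal (co-twin correlation 0.75 in MZ, 0.625 in DZ) is "
      "strong, so even 148 pairs give essentially certain detection.")

print("\nsingle-component test for A alone (boundary 50:50 mixture):")
for n in (50, 148, 400):
    p = power_ncp(PowerSpec(n_mz=n // 10, n_dz=n - n // 10, a2=0.25, c2=0.50,
                            alpha=0.05, component="A")).power
    print(f"  {n:4d} pairs: power = {p:.3f}")

sim = power_sim(PowerSpec(n_mz=60, n_dz=60, a2=0.5, c2=0.0, alpha=0.05,
                          component="A", method="simulation", n_reps=400, seed=1))
ncp = power_ncp(PowerSpec(n_mz=60, n_dz=60, a2=0.5, c2=0.0, component="A"))
print(f"\nsimulation cross-check at 120 pairs, a2=0.5: "
      f"sim {sim.power:.3f} vs ncp {ncp.power:.3f}")
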