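"""Two-way ANOVA, heritability and treatment effects on a simulated trial.

Simulates protein content for 43 genotypes x 4 environments x 2
replicates around the study's treatment means (20.26 % normal, 22.19 %
heat, 21.94 % combined stress), then partitions the variance, estimates
entry-mean broad-sense heritability per environment, and summarizes the
treatment effect as a signed percent change.
"""

import stresskit as sk

trial = sk.simulate_preset("paper_protein", seed=1)

aov = sk.two_way_anova(trial, "protein")
print("Two-way ANOVA, protein content (%):")
print(aov.table.round(4).to_string())

print("\nEntry-mean broad-sense heritability H2 = s2_g / (s2_g + s2_e/r):")
for env in trial.environments:
    h = sk.broad_sense_heritability(trial, env, "protein")
    print(f"  {env:>3}: H2 = {h.h2:.3f}  (s2_g = {h.sigma2_g:.3f}, s2_e = {h.sigma2_e:.3f})")

normal = trial.subset("N2", "protein")["value"].mean()
for env in ("SI", "SNI"):
    stress = trial.subset(env, "protein")["value"].mean()
    print(
        f"\n{env}: mean {stress:.2f} % vs normal {normal:.2f} % "
        f"-> {sk.percent_change(normal, stress):+.2f} % change"
    )
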