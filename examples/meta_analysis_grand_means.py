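"""First-level meta-analysis: overall driver effects and bias diagnostics.

Generates a synthetic literature with known grand means, fits the weighted
multilevel meta-model (driver as moderator, case-study random intercept) for
each response variable, and runs Egger's regression per driver.
"""

import befmeta as b
from befmeta.meta import MetaSpec

truth = b.TruthConfig(seed=42)
effects = b.generate_effect_table(truth).effects

for response in ("diversity", "abundance", "decomposition"):
    sub = effects[effects["response"] == response]
    fit = b.fit_meta(
        sub,
        MetaSpec(outcome="z", variance_column="var_z", moderators=("driver",),
                 random=("study",)),
    )
    print(f"\n{response} (k = {sub['case_study_id'].nunique()} studies, "
          f"{len(sub)} effects; tau2 = {fit.sigma2['study']:.4f})")
    print(b.grand_means(fit, "driver").round(3).to_string(index=False))
    for driver, dsub in sub.groupby("driver"):
        e = b.egger_test(dsub)
        print(f"  Egger {driver}: intercept {e.intercept:+.3f} "
              f"(t = {e.t:+.2f}, p = {e.p:.3f})")

print(f"\ngenerating grand means were mu_diversity = {truth.mu_diversity}, "
      f"mu_abundance = {truth.mu_abundance}")
# The stressor grand means come out clearly negative (CIs excluding zero)
# and the nutrient means near zero, matching the generating parameters;
# with no selection applied the Egger intercepts stay non-significant.
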