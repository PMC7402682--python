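"""Run the whole analysis chain on a synthetic raw-study dataset.

Raw group summaries -> effect sizes (with SD approximation where SDs are
missing) -> standardized intensities -> first-level meta-analysis -> four
mediation SEMs -> moderator tables -> sensitivity rerun with log-response
ratios. All tables are written to ./pipeline_output/.
"""

import befmeta as b

config = b.PipelineConfig(
    simulate_mode="raw",
    truth=b.TruthConfig(n_studies=40, seed=12),
    iterations=100,
    seed=12,
    lnRR_rerun=True,
    output_dir="pipeline_output",
)
report = b.run_all(config)

print(f"{report.metadata['n_effects']} effect sizes from "
      f"{report.metadata['n_studies']} case studies "
      f"({report.metadata['n_exclusions']} logged exclusions, mostly gradient "
      "records that have no log response ratio in the sensitivity rerun; see "
      "pipeline_output/exclusions.csv)")

print("\ngrand mean effects (z scale):")
cols = ["response", "group", "estimate", "ci_low", "ci_high", "signif"]
print(report.grand_means[cols].round(3).to_string(index=False))

print("\nmediation verdicts per dataset:")
cols = ["driver", "family", "supported", "reduced_C_p",
        "delta_AIC_reduced_minus_full", "indirect_effect", "direct_effect"]
print(report.mediation[cols].round(3).to_string(index=False))

print("\ntables written to pipeline_output/")
# Stressor grand means are negative across responses while nutrient means
# hover near zero, and the mediation test recovers the generating
# biodiversity->decomposition path in each dataset with enough links.
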