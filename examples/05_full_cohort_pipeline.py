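"""Full pipeline on a simulated responder/non-responder cohort.

Simulates a cohort where responder-like patients maintain their
expanded clones and non-responders replace them, then runs every stage
(metrics -> dynamics -> clustering -> group comparison) and prints the
responder vs non-responder rank-sum comparisons.
"""

from tcrdyn import AnalysisConfig, CohortConfig, run_pipeline

cfg = AnalysisConfig(
    cohort=CohortConfig(
        n_responders=4, n_nonresponders=6, n_clones=1500, depth=12_000,
        n_expanded_truth=25, seed=5,
    ),
    seed=5,
    out_dir="scratch/example_pipeline",
)
result = run_pipeline(cfg)

print("per-patient summary (head):")
cols = ["patient_id", "response", "prop_maintained", "longitudinal_cosine",
        "mean_frequency_ratio", "normalized_cluster_count"]
print(result.patient_summary[cols].round(3).to_string(index=False))

print("\nresponder vs non-responder comparisons (exact two-sided rank-sum):")
print(result.comparisons.round(4).to_string(index=False))
print("\nlow p on longitudinal_cosine / prop_maintained reflects the generating contrast:"
      "\nresponders maintain expanded clones, non-responders replace them.")
print(f"\nreport tables written to {result.out_dir}/")
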