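"""Run the full bioprocess-prediction pipeline on a synthetic screen.

Pipeline: align strains, L2-normalize query profiles, generate resampled
null profiles, score similarities, aggregate to process scores, compute
z / empirical p against three nulls, combine conservatively, and estimate
FDR against both control types.
"""

from chemgen import pipeline, synthetic

gi, ann = synthetic.generate_genetic_network(seed=1)
cg, truth = synthetic.generate_screen(gi, ann, seed=2)

config = pipeline.PredictConfig(n_resampled=5000, n_permutations=2000, seed=3)
result = pipeline.run_predict(cg, gi, ann, config)

table = result.predictions_table()
best = table.sort_values(["p", "z"], ascending=[True, False]).head(5)
print("five strongest compound-process predictions:")
print(best[["condition_id", "term_id", "z", "p", "source",
            "fdr_resampled"]].to_string(index=False))

counts = result.discovery_counts()
print("\ncompounds discovered at FDR cutoffs (resampled-profile map):")
for cutoff, n in counts.items():
    print(f"  FDR <= {cutoff:4.2f}: {n} of {cg.n_conditions('treatment')}")
# 'source' names the null that supplied the (least significant) combined
# p-value; discoveries are treatments whose best prediction passes the cutoff.
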