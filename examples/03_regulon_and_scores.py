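"""Extract a TF's rescue target genes and score them per cell.

The rescue target genes of a transcription factor are its predicted
regulon targets intersected with a cluster's down-rescue genes, ranked by
the network-inference importance. The resulting gene set is scored per
cell against expression-bin-matched control genes; a positive score means
the set is expressed above matched background in that cell.
"""

import screscue as sr

adata, truth = sr.simulate_counts(
    sr.SimConfig(n_clusters=2, cells_per_group_per_cluster=150, n_genes=1000), seed=3
)
norm = sr.normalize_cp10k(sr.apply_qc(adata, min_genes=200))

cl = truth.clusters[0]
regulons = sr.simulate_regulons(truth, n_tfs=6, target_overlap=0.8, seed=3)
targets = sr.rescue_target_genes(regulons, "TF01", truth.planted_rescue_down[cl], top_n=20)
print(f"TF01 rescue target genes (top {len(targets)} by importance): {targets[:5]} ...")

scores = sr.module_score(norm, targets, n_bins=24, n_ctrl=100, seed=3,
                         gene_set_id="TF01_rescue_targets")
by_group = scores.scores.groupby(norm.obs["group"], observed=True).mean()
print("mean module score per group:")
print(by_group.round(3).to_string())

p_eau = sr.score_group_test(scores, norm.obs, "disease", "naive")
p_prg = sr.score_group_test(scores, norm.obs, "treated", "disease")
print(f"two-sided Wilcoxon p, disease vs naive: {p_eau:.2e} (program induced by disease)")
print(f"two-sided Wilcoxon p, treated vs disease: {p_prg:.2e} (induction reversed by treatment)")
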