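"""Derive rescue-DEGs: genes whose disease-induced change is reversed by treatment.

Per cluster, two Wilcoxon contrasts are thresholded at |log2FC| > 0.25 and
p < 0.05: disease-vs-naive ("EAU-DEGs") and treated-vs-disease
("PRG-DEGs"). A down-rescue gene is up in disease and down after
treatment. The rescue ratio is the fraction of direction-matched disease
DEGs that are rescued; the frequency table counts in how many clusters
each gene is rescued.
"""

import screscue as sr

adata, truth = sr.simulate_counts(
    sr.SimConfig(n_clusters=3, cells_per_group_per_cluster=150, n_genes=1000), seed=2
)
norm = sr.normalize_cp10k(sr.apply_qc(adata, min_genes=200))

rescue_sets = {}
for ct in sr.comparable_celltypes(norm.obs, "disease", "naive"):
    eau = sr.threshold_degs(sr.find_markers(norm, ct, "disease", "naive"),
                            contrast="EAU", cell_type=ct)
    prg = sr.threshold_degs(sr.find_markers(norm, ct, "treated", "disease"),
                            contrast="PRG", cell_type=ct)
    rs = sr.derive_rescue_degs(eau, prg)
    rescue_sets[ct] = rs
    down_ratio, up_ratio = sr.rescue_ratio(rs, eau)
    planted = truth.planted_rescue_down[ct]
    tp = len(rs.down_rescue & planted)
    print(f"{ct}: {len(eau.up)} disease-up DEGs, {len(rs.down_rescue)} down-rescued "
          f"(ratio {down_ratio:.2f}); recovered {tp}/{len(planted)} planted rescue genes")

freq, top = sr.rescue_frequency(rescue_sets, direction="down", top_k=10)
print("\nmost widely rescued genes (gene: number of clusters):")
print({g: int(freq[g]) for g in top[:5]})

comp = sr.composition_table(norm.obs)
lfc = sr.proportion_log2fc(comp, truth.clusters[0], "disease", "naive")
print(f"\ncluster-composition log2FC (disease/naive) for {truth.clusters[0]}: {lfc:+.3f} "
      "(0 means the cluster's share of cells is unchanged)")
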