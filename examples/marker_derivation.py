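"""Derive subtype-enriched marker genes by all-pairs DE intersection.

Each subtype is compared with every other subtype individually (rank-sum on
log2(TPM+1), BH-corrected per pair); a gene counts as a marker only if it is
up against every other subtype. Also shows dot-plot statistics (fraction of
cells at TPM >= 1 and mean log2(TPM+1)) for the top marker of each subtype,
and the abundance estimate scaled to a 400-neuron ganglion.
"""

from psn_atlas.markers import dotplot_stats, intersect_markers, pairwise_de, scale_abundance
from psn_atlas.qc import apply_qc
from psn_atlas.sim.atlas import default_atlas_config, simulate_atlas

adata = simulate_atlas(default_atlas_config(seed=0))
kept, _ = apply_qc(adata)
labels = kept.obs.truth_label
labels = labels[labels != "PSN-H"]  # the hybrid class has no unique genes

de = pairwise_de(kept[labels.index], labels)
markers = intersect_markers(de, alpha=0.01, min_effect=1.0)
print("enriched genes per subtype:")
print(markers.groupby("subtype").size().to_string())

top = markers.sort_values("rank").groupby("subtype").head(1)
stats = dotplot_stats(kept[labels.index], labels, list(top.gene))
print("\ntop marker expression in its own subtype:")
for _, row in top.iterrows():
    own = stats[(stats.gene == row.gene) & (stats.subtype == row.subtype)].iloc[0]
    print(
        f"  {row.subtype:>5} {row.gene:<10} frac expressing={own.frac_expressing:.2f} "
        f"mean log2(TPM+1)={own.mean_log_expr:.1f}"
    )

ab = scale_abundance(labels.value_counts().to_dict())
print("\nestimated neurons per ganglion (scaled to 400 total):")
print(ab.scaled_count.round(0).to_string())
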