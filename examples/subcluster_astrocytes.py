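"""Consensus k-means sub-clustering of astrocytes with silhouette widths.

Consensus clustering averages co-clustering indicators over a grid of
distance measures (Euclidean/Pearson/Spearman) x spectral transforms x
dimensionalities, then cuts the consensus matrix hierarchically at k.
"""

from sklearn.metrics import adjusted_rand_score

from snanno import consensus_subcluster, generate_cohort
from snanno.normalize import normalize_counts
from snanno.sim import small_config

adata, truth = generate_cohort(small_config(seed=4, doublet_rate=0.0))
astro = adata[(truth["true_class"] == "Astrocyte").to_numpy()]
log_expr, _, _ = normalize_counts(astro, min_size=30)

res = consensus_subcluster(log_expr, k=4, seed=0)
planted = truth.loc[astro.obs_names, "true_state"].astype(str)
print(f"astrocytes sub-clustered: {astro.n_obs}, k = 4")
print(f"ARI vs planted reactivity states: {adjusted_rand_score(planted, res.labels):.3f}")
print("average silhouette width per cluster (consensus distances):")
for c, v in sorted(res.silhouette.items()):
    print(f"  cluster {c}: {v:.3f}")
# Silhouettes above 0.5 indicate sub-clusters that the consensus ensemble
# reproduces stably; an ARI near 1 means they coincide with the planted
# reactivity states.
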