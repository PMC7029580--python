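"""Embedding, SNN pre-clustering and consensus k-means sub-clustering.

Pre-clustering builds a shared-nearest-neighbour graph on a low-dimensional
embedding (tSNE by default, mirroring the study's choice; PCA available)
and partitions it with walktrap community detection.  Sub-clustering within
a master class uses consensus k-means: k-means is run over a grid of
distance measures (Euclidean, Pearson, Spearman) x spectral transforms
(PCA, graph-Laplacian eigenvectors) x dimensionalities, the binary
co-clustering matrices are averaged into a consensus matrix, and the final
labels come from a hierarchical cut of the consensus at k.  Cluster quality
is reported as average silhouette width on consensus distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)


def embed(
    expr: ad.AnnData | np.ndarray,
    method: str = "tsne",
    n_components: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2–3D embedding of nuclei; deterministic under a fixed seed.

    ``pca`` returns the exact top principal components; ``tsne`` requires
    perplexity < (n - 1) / 3.
    """
    x = _dense(expr.X) if isinstance(expr, ad.AnnData) else np.asarray(expr, float)
    n = x.shape[0]
    if method == "pca":
        return PCA(n_components=n_components, svd_solver="full", random_state=seed).fit_transform(x)
    if method != "tsne":
        raise ValueError(f"unknown embedding method {method!r}")
    max_perp = (n - 1) / 3
    if perplexity >= max_perp:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; must be < {max_perp:.1f}"
        )
    ts = TSNE(
        n_components=n_components,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    )
    return ts.fit_transform(x)


def snn_precluster(coords: np.ndarray, k_snn: int = 6, seed: int = 0) -> np.ndarray:
    """SNN-graph communities on embedded coordinates.

    Edge weight between two nuclei that appear in each other's k-NN
    neighbourhood union is the number of shared neighbours in their k-NN
    lists; the graph is partitioned by walktrap.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k_snn < 2:
        raise ValueError("k_snn must be >= 2")
    if k_snn >= n:
        raise ValueError(f"k_snn={k_snn} must be < number of nuclei ({n})")
    nn = NearestNeighbors(n_neighbors=k_snn).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = [set(row) for row in idx]  # k-NN list including the nucleus itself

    # candidate pairs: any two nuclei appearing in a common k-NN list
    candidates: set[tuple[int, int]] = set()
    members: dict[int, list[int]] = {}
    for i, row in enumerate(idx):
        for v in row:
            members.setdefault(int(v), []).append(i)
    for group in members.values():
        group.sort()
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                candidates.add((group[a], group[b]))

    edges, weights = [], []
    for i, j in candidates:
        shared = len(neigh[i] & neigh[j])
        if shared > 0:
            edges.append((i, j))
            weights.append(shared)
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    # walktrap is deterministic for a fixed graph; seed kept for interface parity
    communities = g.community_walktrap(weights="weight").as_clustering()
    return np.asarray(communities.membership, dtype=int)


@dataclass
class ConsensusResult:
    consensus: np.ndarray  # nucleus x nucleus in [0, 1], diagonal 1
    labels: np.ndarray
    silhouette: dict[int, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def consensus_matrix(labelings: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Mean of binary co-clustering indicators over an ensemble of labelings.

    Identical labelings therefore give entries in {0, 1} exactly; the
    diagonal is always 1.
    """
    labelings = np.atleast_2d(np.asarray(labelings))
    n = labelings.shape[1]
    cons = np.zeros((n, n))
    for lab in labelings:
        cons += lab[:, None] == lab[None, :]
    cons /= labelings.shape[0]
    np.fill_diagonal(cons, 1.0)
    return cons


def _distance_matrices(x: np.ndarray) -> dict[str, np.ndarray]:
    d_euc = squareform(pdist(x, metric="euclidean"))
    with np.errstate(invalid="ignore"):
        d_pear = squareform(pdist(x, metric="correlation"))
        d_spear = squareform(pdist(rankdata(x, axis=1), metric="correlation"))
    for d in (d_pear, d_spear):
        np.nan_to_num(d, copy=False, nan=1.0)
        np.fill_diagonal(d, 0.0)
    return {"euclidean": d_euc, "pearson": d_pear, "spearman": d_spear}


def _transform_eigs(dist: np.ndarray, kind: str, d_max: int) -> np.ndarray:
    """Spectral coordinates of a distance matrix (PCA or Laplacian)."""
    n = dist.shape[0]
    if kind == "pca":
        return PCA(n_components=min(d_max, n - 1), svd_solver="full").fit_transform(dist)
    # symmetric normalized Laplacian of a similarity derived from distances
    sim = np.exp(-dist / dist.max()) if dist.max() > 0 else np.ones_like(dist)
    deg = sim.sum(axis=1)
    d_inv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(n) - d_inv[:, None] * sim * d_inv[None, :]
    vals, vecs = np.linalg.eigh(lap)
    return vecs[:, : min(d_max, n)]  # smallest eigenvalues first


def consensus_subcluster(
    expr: ad.AnnData | np.ndarray,
    k: int,
    d_range: tuple[int, ...] | None = None,
    seed: int = 0,
    exclude_genes: tuple[str, ...] = (),
) -> ConsensusResult:
    """SC3-style consensus k-means within one master class.

    ``d_range`` defaults to 4–7% of n (at least spanning two values).
    ``exclude_genes`` drops the named genes before clustering (used e.g. to
    remove astrocytic GFAP/AQP4 from neuronal sub-clustering) — the matrix
    is used as-is otherwise; pass re-normalized input when required.
    """
    if isinstance(expr, ad.AnnData):
        if exclude_genes:
            keep = [g for g in expr.var_names if g not in set(exclude_genes)]
            expr = expr[:, keep]
        x = _dense(expr.X)
    else:
        x = np.asarray(expr, dtype=float)
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n / 2:
        raise ValueError(f"k={k} too large for n={n} nuclei")
    if n < 5 * k:
        raise ValueError(f"need at least 5k={5 * k} nuclei, got {n}")
    if d_range is None:
        lo = max(2, int(np.floor(0.04 * n)))
        hi = max(lo + 1, int(np.ceil(0.07 * n)))
        d_range = tuple(range(lo, hi + 1))

    rng = np.random.default_rng(seed)
    labelings = []
    for dist in _distance_matrices(x).values():
        for kind in ("pca", "laplacian"):
            coords = _transform_eigs(dist, kind, max(d_range))
            for d in d_range:
                km = KMeans(
                    n_clusters=k,
                    n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
                labelings.append(km.fit_predict(coords[:, :d]))
    consensus = consensus_matrix(labelings)

    cons_dist = 1.0 - consensus
    z = linkage(squareform(cons_dist, checks=False), method="complete")
    labels = fcluster(z, t=k, criterion="maxclust") - 1

    sil = {}
    if len(np.unique(labels)) > 1:
        widths = silhouette_samples(cons_dist, labels, metric="precomputed")
        for c in np.unique(labels):
            sil[int(c)] = float(widths[labels == c].mean())
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        silhouette=sil,
        params={"k": k, "d_range": tuple(d_range), "seed": seed},
    )
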