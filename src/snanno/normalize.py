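"""Size-factor normalization with coarse pre-grouping.

Nuclei are first grouped coarsely by hierarchical clustering on a
rank-correlation distance (so that composition differences between cell
classes do not bias the factors), then per-nucleus size factors are
estimated by pooling-based deconvolution within each group and rescaled
across groups so that the global geometric mean of the factors is 1.
Expression used downstream is log2(count / factor + 1).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.sparse.linalg import lsqr
from scipy.stats import rankdata

POOL_SIZES = (5, 11, 21, 31, 41, 61)
_LIB_WEIGHT = 0.1  # weight of the library-size anchor equations


def quick_cluster(adata: ad.AnnData, min_size: int = 50) -> np.ndarray:
    """Coarse grouping by average-linkage on Spearman correlation distance.

    The tree is cut at the largest number of groups for which every group
    has at least ``min_size`` members; too few nuclei yields a single group
    with a warning.
    """
    n = adata.n_obs
    if n < 2 * min_size:
        warnings.warn(
            f"{n} nuclei < 2*min_size={2 * min_size}; returning a single group",
            stacklevel=2,
        )
        return np.zeros(n, dtype=int)
    x = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)
    ranks = rankdata(x, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    norms[norms == 0] = 1.0
    rho = (ranks / norms[:, None]) @ (ranks / norms[:, None]).T
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    for k in range(n // min_size, 0, -1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if np.bincount(labels)[1:].min() >= min_size:
            return labels - 1
    return np.zeros(n, dtype=int)


def _deconvolve_group(counts: np.ndarray) -> np.ndarray:
    """Pool-and-deconvolve size factors for one group (factors vs group ref)."""
    m = counts.shape[0]
    lib = counts.sum(axis=1)
    ref = counts.mean(axis=0)
    expressed = ref > 0
    # ring order: sort by library size, then interleave ends for balance
    order = np.argsort(lib, kind="stable")
    ring = np.empty(m, dtype=int)
    ring[0::2] = order[: (m + 1) // 2]
    ring[1::2] = order[(m + 1) // 2 :][::-1]

    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    seen_sizes: set[int] = set()
    for size in POOL_SIZES:
        size = min(size, m)
        if size in seen_sizes:
            continue
        seen_sizes.add(size)
        for start in range(m):
            members = ring[(start + np.arange(size)) % m]
            pooled = counts[members].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.median(pooled[expressed] / ref[expressed])
            rows += [eq] * size
            cols += list(members)
            vals += [1.0] * size
            rhs.append(ratio)
            eq += 1
        if size == m:
            break
    # low-weight anchors: factor_c ~ lib_c / mean(lib), pins scale & sign
    mean_lib = lib.mean() or 1.0
    for c in range(m):
        rows.append(eq)
        cols.append(c)
        vals.append(_LIB_WEIGHT)
        rhs.append(_LIB_WEIGHT * lib[c] / mean_lib)
        eq += 1
    a = sp.csr_matrix((vals, (rows, cols)), shape=(eq, m))
    sol = lsqr(a, np.asarray(rhs), atol=1e-10, btol=1e-10)[0]
    return sol


def size_factors(
    adata: ad.AnnData, labels: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-nucleus size factors by within-group deconvolution.

    Returns (factors, notes).  Non-positive deconvolved factors fall back to
    the nucleus's library-size factor and are noted.  Factors are rescaled
    across groups against the global mean profile and finally scaled so
    their geometric mean is exactly 1.
    """
    x = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)
    n = x.shape[0]
    lib = x.sum(axis=1)
    if (lib == 0).any():
        raise ValueError("all-zero nuclei present; filter before normalization")
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels)

    factors = np.empty(n)
    notes: list[str] = []
    global_ref = x.mean(axis=0)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = x[idx]
        if len(idx) == 1:
            fac = np.array([1.0])
        else:
            fac = _deconvolve_group(sub)
        bad = fac <= 0
        if bad.any():
            lib_sub = sub.sum(axis=1)
            fac[bad] = lib_sub[bad] / lib_sub.mean()
            for i in np.flatnonzero(bad):
                notes.append(
                    f"negative deconvolved factor for {adata.obs_names[idx[i]]}; "
                    "library-size fallback"
                )
        # rescale this group against the global reference profile
        ref = sub.mean(axis=0)
        both = (ref > 0) & (global_ref > 0)
        scale = float(np.median(ref[both] / global_ref[both])) if both.any() else 1.0
        factors[idx] = fac * scale
    factors /= np.exp(np.mean(np.log(factors)))
    return factors, notes


def log_normalize(
    adata: ad.AnnData,
    factors: np.ndarray,
    quick_labels: np.ndarray | None = None,
) -> ad.AnnData:
    """log2(count / size factor + 1); zeros stay zero so sparsity survives."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (adata.n_obs,) or (factors <= 0).any():
        raise ValueError("need one positive size factor per nucleus")
    x = adata.X
    if sp.issparse(x):
        x = x.tocsr().astype(float)
        scaled = sp.diags(1.0 / factors) @ x
        scaled.data = np.log2(scaled.data + 1.0)
        logx = scaled
    else:
        logx = np.log2(np.asarray(x, float) / factors[:, None] + 1.0)
    out = ad.AnnData(X=logx, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns))
    out.obs["size_factor"] = factors
    if quick_labels is not None:
        out.obs["quick_cluster"] = pd.Categorical(np.asarray(quick_labels))
    return out


def normalize_counts(
    adata: ad.AnnData, min_size: int = 50
) -> tuple[ad.AnnData, np.ndarray, list[str]]:
    """Convenience wrapper: quick_cluster -> size_factors -> log_normalize."""
    labels = quick_cluster(adata, min_size=min_size)
    factors, notes = size_factors(adata, labels)
    return log_normalize(adata, factors, labels), factors, notes
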