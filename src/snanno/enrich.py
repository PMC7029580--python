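"""Rank-based gene-set scoring of cluster profiles and over-representation.

``gsva_scores`` is a contract-level implementation of kernel-CDF /
rank-random-walk gene-set variation scoring: per gene, expression across
clusters is converted to a Gaussian-kernel CDF estimate; per cluster, genes
are ranked by that statistic and a Kolmogorov–Smirnov-like random walk over
the ranked list (weighted up-steps on set genes, constant down-steps
elsewhere) yields the enrichment score.  With the ``mx.diff = FALSE``
convention the score is the walk's maximum deviation from zero (signed).

``hypergeom_enrich`` is the generic over-representation test used for
marker and module gene lists.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def kernel_cdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry within its row.

    ``values`` is gene x cluster; bandwidth per gene is sd / n^(1/5)
    (degenerate rows fall back to a tiny bandwidth, giving tied mid-ranks).
    Scale-equivariant: multiplying a row by a positive constant leaves the
    result unchanged.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[1]
    sd = v.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / n**0.2, 1.0)
    diff = (v[:, :, None] - v[:, None, :]) / h[:, None, None]
    return stats.norm.cdf(diff).mean(axis=2)


def _walk_scores(order: np.ndarray, in_set: np.ndarray) -> float:
    """Signed maximum deviation of the KS-like walk for one cluster.

    ``order`` indexes genes by decreasing statistic; up-steps on set genes
    are weighted by the symmetric rank magnitude |p/2 - r + 1/2|.
    """
    p = len(order)
    member = in_set[order]
    ranks = np.arange(1, p + 1)
    weight = np.abs(p / 2.0 - ranks + 0.5)
    up = np.where(member, weight, 0.0)
    n_out = p - member.sum()
    down = np.where(member, 0.0, 1.0)
    up_total = up.sum()
    if up_total == 0 or n_out == 0:
        return 0.0
    walk = np.cumsum(up / up_total - down / n_out)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def gsva_scores(
    cluster_means: pd.DataFrame,
    genesets: Mapping[str, Sequence[str]],
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Gene-set x cluster enrichment scores from a gene x cluster matrix.

    Requires at least 3 clusters (columns).  Sets with fewer than
    ``min_set_size`` genes in the universe are skipped with a warning.
    """
    if cluster_means.shape[1] < 3:
        raise ValueError("gene-set scoring needs at least 3 clusters")
    genes = list(cluster_means.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    z = kernel_cdf(cluster_means.to_numpy(float))
    # rank genes per cluster by decreasing CDF statistic
    orders = np.argsort(-z, axis=0, kind="stable")

    rows = {}
    for name, members in genesets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if len(idx) < min_set_size:
            warnings.warn(
                f"gene set {name!r} has {len(idx)} universe genes; skipped",
                stacklevel=2,
            )
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[idx] = True
        rows[name] = [
            _walk_scores(orders[:, c], in_set) for c in range(z.shape[1])
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cluster_means.columns)
    out.index.name = "gene_set"
    return out


def zscale_rows(scores: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scaled view for display; constant rows map to zero."""
    v = scores.to_numpy(float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((v - mu) / sd, index=scores.index, columns=scores.columns)


def hypergeom_enrich(
    query: Sequence[str],
    genesets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    p = P(overlap >= observed) under sampling |query| genes from the
    universe; BH-adjusted across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    q = set(query) & uni
    if set(query) - uni:
        raise ValueError("query genes outside the universe")
    rows = []
    for name, members in genesets.items():
        s = set(members) & uni
        k = len(q & s)
        p = stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)) if s else 1.0
        rows.append((name, k, len(s), float(p)))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p_value"])
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out.set_index("gene_set")


def cluster_mean_profiles(log_expr, labels) -> pd.DataFrame:
    """Average log-normalized expression per gene per cluster."""
    import scipy.sparse as sp

    x = log_expr.X
    x = x.toarray() if sp.issparse(x) else np.asarray(x, float)
    labels = pd.Series(np.asarray(labels), index=log_expr.obs_names)
    cols = {}
    for c in labels.unique():
        cols[c] = x[(labels == c).to_numpy()].mean(axis=0)
    return pd.DataFrame(cols, index=log_expr.var_names)
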