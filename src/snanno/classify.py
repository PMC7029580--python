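"""Identity-score cell classification with ambiguity handling.

Each nucleus receives, for each of six broad cell classes, an identity
score: the percentage of that class's marker-gene list (intersected with
the matrix's gene universe) detected (raw count > 0) in the nucleus.  The
nucleus is assigned the argmax class.  An ambiguity flag marks nuclei whose
score curve is flat: with top-three scores s1 >= s2 >= s3, the nucleus is
ambiguous when s2 + s3 > rho * s1.

The published form of the rule uses rho = 2, which can never fire for
strictly ordered scores (s2 + s3 <= 2*s1 always); the default here is
rho = 1, with ``literal_mode`` preserving the printed behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_CLASSES = (
    "Neuron",
    "Astrocyte",
    "Oligodendrocyte",
    "OPC",
    "Microglia",
    "Endothelial",
)


@dataclass(frozen=True)
class AmbiguityRule:
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    @classmethod
    def literal(cls) -> "AmbiguityRule":
        """The printed '2X the highest score' rule (arithmetically inert)."""
        return cls(rho=2.0)


def identity_scores(
    adata: ad.AnnData, genesets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-nucleus identity scores (percent of class list detected).

    Detection means raw count > 0, so scores are invariant to any monotone
    transform preserving zero versus non-zero; log-normalized input is
    therefore equally valid.
    """
    universe = set(adata.var_names)
    gene_pos = {g: i for i, g in enumerate(adata.var_names)}
    x = adata.X
    detected = (x > 0) if sp.issparse(x) else sp.csr_matrix(np.asarray(x) > 0)
    detected = sp.csr_matrix(detected)

    scores = {}
    for cls, genes in genesets.items():
        members = sorted(set(genes) & universe)
        if not members:
            raise ValueError(f"gene set {cls!r} has no genes in the matrix universe")
        idx = [gene_pos[g] for g in members]
        hits = np.asarray(detected[:, idx].sum(axis=1)).ravel()
        scores[cls] = 100.0 * hits / len(members)
    return pd.DataFrame(scores, index=adata.obs_names)


def assign_class(
    scores: pd.DataFrame,
    rule: AmbiguityRule | None = None,
    identity_min: float = 20.0,
    class_order: Sequence[str] = CELL_CLASSES,
) -> pd.DataFrame:
    """Argmax class, ambiguity flag and quality flag per nucleus.

    Ties at the maximum are broken by the fixed ``class_order`` (columns
    not in the order are appended alphabetically).  Nuclei with all scores
    zero are labelled ``Unknown`` and flagged ambiguous.  ``quality_pass``
    is max score >= ``identity_min`` (percent).
    """
    rule = rule or AmbiguityRule()
    ordered = [c for c in class_order if c in scores.columns]
    ordered += sorted(c for c in scores.columns if c not in ordered)
    s = scores[ordered].to_numpy(float)
    n = s.shape[0]

    argmax = s.argmax(axis=1)  # first max under the fixed order
    top3 = -np.sort(-s, axis=1)[:, :3] if s.shape[1] >= 3 else None
    if top3 is None:
        pad = np.zeros((n, 3 - s.shape[1]))
        top3 = np.hstack([-np.sort(-s, axis=1), pad])
    s1, s2, s3 = top3[:, 0], top3[:, 1], top3[:, 2]
    ambiguous = (s2 + s3) > rule.rho * s1

    assigned = np.array(ordered, dtype=object)[argmax]
    all_zero = s1 == 0
    assigned[all_zero] = "Unknown"
    ambiguous = ambiguous | all_zero

    return pd.DataFrame(
        {
            "assigned_class": assigned.astype(str),
            "ambiguous": ambiguous,
            "max_score": s1,
            "quality_pass": s1 >= identity_min,
        },
        index=scores.index,
    )


def flag_mixed(
    cluster_enrichment: pd.DataFrame, delta: float = 0.1
) -> pd.Series:
    """Flag clusters whose class-enrichment profile has no clear winner.

    ``cluster_enrichment`` is a cluster x class score matrix.  A cluster is
    mixed when two or more classes score within ``delta`` x (global score
    range) of the cluster's maximum.
    """
    e = cluster_enrichment.to_numpy(float)
    span = float(e.max() - e.min()) or 1.0
    tol = delta * span
    near_top = (e >= (e.max(axis=1, keepdims=True) - tol)).sum(axis=1)
    return pd.Series(near_top >= 2, index=cluster_enrichment.index, name="mixed")


def resolve_mixed_preclusters(
    preclusters: pd.Series,
    mixed: pd.Series,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Split mixed preclusters by each nucleus's argmax class.

    Nuclei in a mixed precluster ``c`` move to new clusters named
    ``<Class>_r<c>``; clean preclusters keep their labels.  Returns a table
    with columns ``precluster``, ``cluster`` (post-resolution) and
    ``reassigned``.
    """
    preclusters = preclusters.astype(str)
    out = pd.DataFrame(
        {
            "precluster": preclusters,
            "cluster": preclusters.copy(),
            "reassigned": False,
        },
        index=preclusters.index,
    )
    mixed_ids = {str(c) for c, flag in mixed.items() if flag}
    in_mixed = preclusters.isin(mixed_ids)
    cls = assignments.loc[preclusters.index, "assigned_class"]
    out.loc[in_mixed, "cluster"] = (
        cls[in_mixed].astype(str) + "_r" + preclusters[in_mixed]
    )
    out.loc[in_mixed, "reassigned"] = True
    return out


def master_classes(
    clusters: pd.Series, assignments: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Agglomerate clusters into master classes by majority argmax class.

    Returns (per-cluster class, per-nucleus class).
    """
    cls = assignments.loc[clusters.index, "assigned_class"]
    per_cluster = (
        pd.DataFrame({"cluster": clusters, "cls": cls})
        .groupby("cluster", observed=True)["cls"]
        .agg(lambda s: s.value_counts().idxmax())
    )
    per_nucleus = clusters.map(per_cluster)
    per_nucleus.name = "master_class"
    return per_cluster, per_nucleus
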