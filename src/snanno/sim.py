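"""Synthetic droplet-style snRNA-seq cohorts with known ground truth.

The generator emulates the structure of a two-condition (control vs disease)
cortical single-nucleus experiment: six broad cell classes (neurons,
astrocytes, oligodendrocytes, OPCs, microglia, endothelial cells) each with
an elevated marker-gene program, negative-binomial counts, astrocyte
reactivity sub-states planted through three sentinel genes (SLC1A2, MT2A,
GFAP) plus small per-state gene programs, a configurable doublet fraction
(doublets are sums of two singlets' counts), and per-nucleus exonic and
mitochondrial read fractions drawn from Beta distributions.

Counts are NB with mean mu and inverse-dispersion ``dispersion`` (variance
mu + mu^2/dispersion); ``dispersion=inf`` gives the Poisson limit.  Sentinel
genes of an astrocyte are drawn Poisson around the planted state's target
log-expression so that, after size-factor normalization, the nucleus's
log2 triplet falls inside its state's rule region with probability >= 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .states import SENTINEL_GENES, STATE_LABELS, StateRuleSet, classify_state

CELL_CLASSES = (
    "Neuron",
    "Astrocyte",
    "Oligodendrocyte",
    "OPC",
    "Microglia",
    "Endothelial",
)

#: Published state proportions renormalized over the four planted states
#: (the remainder of real astrocytes fall in unknown/ambiguous regions that
#: a rule-consistent generator cannot plant).
DEFAULT_STATE_MIX: dict[str, dict[str, float]] = {
    "control": {"Quiescent": 0.664, "State1Q": 0.283, "State2R": 0.019, "State3R": 0.034},
    "HD": {"Quiescent": 0.026, "State1Q": 0.614, "State2R": 0.230, "State3R": 0.130},
}

#: Target log2(normalized+1) triplets, each comfortably inside its rule
#: region (thresholds 2/4/3) so Poisson count noise rarely crosses a border.
DEFAULT_STATE_MEANS: dict[str, tuple[float, float, float]] = {
    "Quiescent": (3.5, 1.5, 1.0),
    "State1Q": (3.5, 5.0, 1.0),
    "State2R": (0.8, 5.0, 4.2),
    "State3R": (0.8, 1.5, 4.2),
}


@dataclass
class SimConfig:
    """Parameters of a simulated cohort; defaults are the study conditions."""

    n_nuclei_per_class: int = 100  # per (class, condition)
    n_genes: int = 2000
    class_marker_sets: Mapping[str, Sequence[str]] | None = None
    marker_effect: float = 8.0  # fold elevation of class-marker means
    baseline_mean: float = 0.3  # mean raw count of a background gene
    dispersion: float = 2.0  # NB inverse-dispersion; inf = Poisson
    conditions: tuple[str, ...] = ("control", "HD")
    state_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STATE_MIX.items()}
    )
    state_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_MEANS)
    )
    state_marker_genes: int = 25  # per-state elevated program size
    state_marker_effect: float = 6.0
    doublet_rate: float = 0.05
    exonic_beta: tuple[float, float] = (20.0, 20.0)
    mito_beta: tuple[float, float] = (2.0, 38.0)
    depth_sigma: float = 0.15  # lognormal sd of per-nucleus depth factor
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ValueError("doublet_rate must be in [0, 1]")
        if self.baseline_mean <= 0 or self.marker_effect <= 0:
            raise ValueError("means and effects must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf allowed)")
        rules = StateRuleSet()
        for cond, mix in self.state_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"state_mix[{cond!r}] sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"state_mix[{cond!r}] has negative weight")
        for state, triplet in self.state_means.items():
            if classify_state(triplet, rules) != state:
                raise ValueError(
                    f"state_means[{state!r}]={triplet} lies outside the "
                    f"{state} rule region — inconsistent configuration"
                )


def default_gene_names(n_genes: int) -> list[str]:
    names = list(SENTINEL_GENES)
    names += [f"G{i:04d}" for i in range(n_genes - len(names))]
    return names


def default_marker_sets(genes: Sequence[str]) -> dict[str, list[str]]:
    """Six 40-gene class programs on consecutive blocks, overlapping by 5.

    The astrocyte program additionally contains its two canonical sentinel
    genes, SLC1A2 and GFAP, mirroring curated literature marker lists.
    """
    start = len(SENTINEL_GENES)
    sets: dict[str, list[str]] = {}
    block, overlap = 40, 5
    for i, cls in enumerate(CELL_CLASSES):
        lo = start + i * (block - overlap)
        members = list(genes[lo : lo + block])
        if cls == "Astrocyte":
            members = ["SLC1A2", "GFAP"] + members
        sets[cls] = members
    return sets


def default_state_marker_sets(
    genes: Sequence[str], n_per_state: int
) -> dict[str, list[str]]:
    """Disjoint per-state programs placed after the class-marker blocks."""
    start = len(SENTINEL_GENES) + 5 * 35 + 40  # past the last class block
    sets = {}
    for i, state in enumerate(STATE_LABELS):
        lo = start + i * n_per_state
        sets[state] = list(genes[lo : lo + n_per_state])
    return sets


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(mu)
    # NB as gamma-Poisson mixture keeps the mean exact for array-valued mu
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def generate_cohort(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a cohort; returns (counts AnnData, truth table).

    The truth table is indexed by barcode with columns ``true_class``,
    ``true_state`` (astrocytes only, else NA), ``is_doublet`` and
    ``condition``.  Reproducible: a fixed config (including seed) yields
    byte-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = default_gene_names(config.n_genes)
    if config.n_genes < 350:
        raise ValueError("n_genes too small to host marker and state programs")
    marker_sets = (
        {k: list(v) for k, v in config.class_marker_sets.items()}
        if config.class_marker_sets is not None
        else default_marker_sets(genes)
    )
    state_sets = default_state_marker_sets(genes, config.state_marker_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    sentinel_idx = np.array([gene_index[g] for g in SENTINEL_GENES])

    classes, conditions, states = [], [], []
    for cond in config.conditions:
        mix = config.state_mix.get(cond) or config.state_mix[
            "HD" if cond != "control" else "control"
        ]
        for cls in marker_sets:
            n = config.n_nuclei_per_class
            classes += [cls] * n
            conditions += [cond] * n
            if cls == "Astrocyte":
                probs = np.array([mix.get(s, 0.0) for s in STATE_LABELS])
                states += list(rng.choice(STATE_LABELS, size=n, p=probs / probs.sum()))
            else:
                states += [None] * n
    n_singlets = len(classes)

    depth = (
        rng.lognormal(-config.depth_sigma**2 / 2, config.depth_sigma, n_singlets)
        if config.depth_sigma > 0
        else np.ones(n_singlets)
    )

    counts = np.empty((n_singlets, config.n_genes), dtype=np.int64)
    base = np.full(config.n_genes, config.baseline_mean)
    marker_idx = {
        cls: np.array([gene_index[g] for g in gs if g in gene_index])
        for cls, gs in marker_sets.items()
    }
    state_idx = {
        st: np.array([gene_index[g] for g in gs]) for st, gs in state_sets.items()
    }
    for i in range(n_singlets):
        mu = base.copy()
        mu[marker_idx[classes[i]]] *= config.marker_effect
        if states[i] is not None:
            mu[state_idx[states[i]]] *= config.state_marker_effect
        mu *= depth[i]
        row = _nb_counts(rng, mu, config.dispersion)
        if states[i] is not None:
            target = np.asarray(config.state_means[states[i]])
            row[sentinel_idx] = rng.poisson((2.0**target - 1.0) * depth[i])
        counts[i] = row

    pct_exonic = rng.beta(*config.exonic_beta, n_singlets)
    pct_mito = rng.beta(*config.mito_beta, n_singlets)

    # doublets: extra barcodes that are sums of two random distinct singlets;
    # metadata and truth class follow the first member of the pair
    n_doub = (
        int(round(config.doublet_rate / (1 - config.doublet_rate) * n_singlets))
        if config.doublet_rate < 1
        else 0
    )
    doub_rows = []
    doub_meta = []
    for _ in range(n_doub):
        a, b = rng.choice(n_singlets, size=2, replace=False)
        doub_rows.append(counts[a] + counts[b])
        doub_meta.append((classes[a], states[a], conditions[a], pct_exonic[a], pct_mito[a]))

    total = n_singlets + n_doub
    barcodes = [f"BC{i:05d}" for i in range(total)]
    all_counts = np.vstack([counts] + [np.asarray(doub_rows)]) if n_doub else counts

    truth = pd.DataFrame(
        {
            "true_class": classes + [m[0] for m in doub_meta],
            "true_state": pd.array(
                [s if s is not None else pd.NA for s in states]
                + [m[1] if m[1] is not None else pd.NA for m in doub_meta]
            ),
            "is_doublet": [False] * n_singlets + [True] * n_doub,
            "condition": conditions + [m[2] for m in doub_meta],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    obs = pd.DataFrame(
        {
            "condition": truth["condition"].values,
            "pct_exonic": np.concatenate([pct_exonic, [m[3] for m in doub_meta]])
            if n_doub
            else pct_exonic,
            "pct_mito": np.concatenate([pct_mito, [m[4] for m in doub_meta]])
            if n_doub
            else pct_mito,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(all_counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["class_marker_sets"] = {k: list(v) for k, v in marker_sets.items()}
    adata.uns["state_marker_sets"] = {k: list(v) for k, v in state_sets.items()}
    return adata, truth


def small_config(**overrides) -> SimConfig:
    """A reduced cohort (600 nuclei, 1200 genes) for quick runs and tests."""
    cfg = SimConfig(n_nuclei_per_class=50, n_genes=1200)
    return replace(cfg, **overrides)
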