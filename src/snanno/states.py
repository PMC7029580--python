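"""Rule-based astrocyte reactivity-state classification.

Astrocytes are labelled by thresholding the log-expression of three sentinel
genes: the glutamate transporter SLC1A2 (high in protoplasmic/quiescent
astrocytes), the metallothionein MT2A (stress-inducible, elevated early in
reactivity), and the intermediate filament GFAP (the classical reactivity
marker).  Four states are defined:

========  =========  ========  ========
state     SLC1A2     MT2A      GFAP
========  =========  ========  ========
Quiescent >= 2       < 4       < 3
State1Q   >= 2       >= 4      < 3
State2R   < 2        >= 4      >= 3
State3R   < 2        < 4       >= 3
========  =========  ========  ========

Triplets matching no rule are ``Unknown``; matching more than one,
``Ambiguous``.  Thresholds are in log2(normalized count + 1) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATE_LABELS = ("Quiescent", "State1Q", "State2R", "State3R")
ALL_LABELS = STATE_LABELS + ("Unknown", "Ambiguous")
SENTINEL_GENES = ("SLC1A2", "MT2A", "GFAP")


@dataclass(frozen=True)
class StateRuleSet:
    """Threshold rules mapping a (SLC1A2, MT2A, GFAP) triplet to a state.

    Each rule is a triple of booleans giving the *side* of the threshold the
    state occupies: True means "at or above" the threshold for that gene,
    False means "strictly below".  Boundary conventions follow the printed
    inequalities: >= on the high side, strict < on the low side.
    """

    slc1a2_t: float = 2.0
    mt2a_t: float = 4.0
    gfap_t: float = 3.0
    rules: Mapping[str, tuple[bool, bool, bool]] = field(
        default_factory=lambda: {
            "Quiescent": (True, False, False),
            "State1Q": (True, True, False),
            "State2R": (False, True, True),
            "State3R": (False, False, True),
        }
    )

    def __post_init__(self) -> None:
        for name, sides in self.rules.items():
            if len(sides) != 3:
                raise ValueError(f"rule {name!r} must give three threshold sides")
        # distinct side-patterns guarantee pairwise mutual exclusivity: two
        # rules differing in any coordinate cannot both match one triplet.
        patterns = list(self.rules.values())
        if len(set(patterns)) != len(patterns):
            raise ValueError("state rules are not mutually exclusive")

    @property
    def thresholds(self) -> tuple[float, float, float]:
        return (self.slc1a2_t, self.mt2a_t, self.gfap_t)

    def matches(self, triplet: Sequence[float]) -> list[str]:
        """All states whose rule the triplet satisfies (0, 1, or more)."""
        sides = tuple(
            float(v) >= t for v, t in zip(triplet, self.thresholds, strict=True)
        )
        return [name for name, want in self.rules.items() if sides == want]


def classify_state(
    triplets: np.ndarray | Sequence[Sequence[float]],
    rules: StateRuleSet | None = None,
) -> np.ndarray:
    """Classify (SLC1A2, MT2A, GFAP) log-expression triplets into states.

    Parameters
    ----------
    triplets
        Array-like of shape (n, 3) or a single triplet of length 3, in
        log2(normalized count + 1) units.
    rules
        Threshold rule set; defaults to the published thresholds (2, 4, 3).

    Returns
    -------
    numpy array of state labels (a single label for a single triplet).
    """
    rules = rules or StateRuleSet()
    arr = np.asarray(triplets, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 3:
        raise ValueError("expected triplets of (SLC1A2, MT2A, GFAP)")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite value in expression triplet")

    sides = arr >= np.asarray(rules.thresholds)  # (n, 3) boolean
    labels = np.full(arr.shape[0], "Unknown", dtype=object)
    n_hits = np.zeros(arr.shape[0], dtype=int)
    for name, want in rules.rules.items():
        hit = (sides == np.asarray(want)).all(axis=1)
        labels[hit] = name
        n_hits += hit
    labels[n_hits > 1] = "Ambiguous"
    labels = labels.astype(str)
    return labels[0] if single else labels


def classify_state_matrix(
    log_expr,
    rules: StateRuleSet | None = None,
    sentinel_genes: Sequence[str] = SENTINEL_GENES,
) -> pd.Series:
    """State calls for every nucleus of a log-expression AnnData.

    Pulls the three sentinel genes from ``log_expr`` (obs = nuclei,
    var = genes) and applies :func:`classify_state`.
    """
    missing = [g for g in sentinel_genes if g not in log_expr.var_names]
    if missing:
        raise KeyError(f"sentinel genes absent from matrix: {missing}")
    sub = log_expr[:, list(sentinel_genes)].X
    if hasattr(sub, "toarray"):
        sub = sub.toarray()
    calls = classify_state(np.asarray(sub, dtype=float), rules)
    return pd.Series(calls, index=log_expr.obs_names, name="state")


def state_composition(
    calls: pd.Series, conditions: pd.Series, warn_empty: bool = True
) -> pd.DataFrame:
    """Per-condition state proportions (rows sum to 1; empty rows stay 0).

    Returns a condition x label DataFrame over all six possible labels.
    """
    calls, conditions = calls.align(conditions, join="inner")
    tab = pd.crosstab(conditions, calls)
    tab = tab.reindex(columns=list(ALL_LABELS), fill_value=0)
    if isinstance(conditions.dtype, pd.CategoricalDtype):
        tab = tab.reindex(index=conditions.cat.categories, fill_value=0)
    totals = tab.sum(axis=1)
    if warn_empty and (totals == 0).any():
        import warnings

        empty = list(totals.index[totals == 0])
        warnings.warn(f"conditions with no astrocytes: {empty}", stacklevel=2)
    out = tab.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    out.index.name = "condition"
    return out


def cluster_state_crosstab(calls: pd.Series, clusters: pd.Series) -> pd.DataFrame:
    """Sub-cluster x state contingency counts (row sums = cluster sizes)."""
    calls, clusters = calls.align(clusters, join="inner")
    tab = pd.crosstab(clusters, calls)
    tab.index.name = "cluster"
    return tab
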