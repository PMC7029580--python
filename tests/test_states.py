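"""Astrocyte state rules: grid enumeration oracle, composition, crosstabs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snanno.states import (
    StateRuleSet,
    classify_state,
    cluster_state_crosstab,
    state_composition,
)


def oracle_state(s, m, g):
    """The printed rule table written out directly, as an independent check."""
    hits = []
    if s >= 2 and m < 4 and g < 3:
        hits.append("Quiescent")
    if s >= 2 and m >= 4 and g < 3:
        hits.append("State1Q")
    if s < 2 and m >= 4 and g >= 3:
        hits.append("State2R")
    if s < 2 and m < 4 and g >= 3:
        hits.append("State3R")
    if len(hits) == 0:
        return "Unknown"
    if len(hits) > 1:
        return "Ambiguous"
    return hits[0]


class TestClassifyState:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((3.0, 1.0, 0.5), "Quiescent"),
            ((3.0, 5.0, 0.5), "State1Q"),
            ((1.0, 5.0, 4.0), "State2R"),
            ((1.0, 1.0, 4.0), "State3R"),
            ((3.0, 1.0, 5.0), "Unknown"),  # high SLC1A2 with high GFAP
            ((2.0, 4.0, 3.0), "Unknown"),  # boundary: >= on all three
        ],
    )
    def test_printed_rule_examples(self, triplet, expected):
        assert classify_state(triplet) == expected

    def test_exhaustive_grid_matches_oracle(self):
        grid = np.arange(7.0)
        triplets, expected = [], []
        for s in grid:
            for m in grid:
                for g in grid:
                    triplets.append((s, m, g))
                    expected.append(oracle_state(s, m, g))
        got = classify_state(np.array(triplets))
        assert list(got) == expected
        assert "Ambiguous" not in got  # rules are mutually exclusive as printed
        assert (got == "Unknown").sum() > 0  # e.g. high SLC1A2 + high GFAP

    def test_nan_is_error(self):
        with pytest.raises(ValueError, match="non-finite"):
            classify_state((np.nan, 1.0, 1.0))

    def test_overlapping_rules_rejected_at_load(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            StateRuleSet(
                rules={"A": (True, False, False), "B": (True, False, False)}
            )

    def test_raising_gfap_threshold_moves_calls_monotonically(self, rng):
        """Raising gfap_t may only move reactive calls toward the low-GFAP
        states or Unknown, never create new reactive calls."""
        triplets = rng.uniform(0, 6, (500, 3))
        lo = classify_state(triplets, StateRuleSet(gfap_t=3.0))
        hi = classify_state(triplets, StateRuleSet(gfap_t=4.5))
        reactive = {"State2R", "State3R"}
        newly_reactive = (~np.isin(lo, list(reactive))) & np.isin(hi, list(reactive))
        assert not newly_reactive.any()


class TestComposition:
    def test_simple_fraction(self):
        calls = pd.Series(
            ["Quiescent"] * 10 + ["State1Q"] * 10, index=[f"n{i}" for i in range(20)]
        )
        cond = pd.Series(["control"] * 20, index=calls.index)
        comp = state_composition(calls, cond)
        assert comp.loc["control", "Quiescent"] == pytest.approx(0.5)
        assert comp.loc["control"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_condition_warns(self):
        calls = pd.Series(["Quiescent"], index=["a"])
        cond = pd.Series(["control"], index=["a"]).astype(
            pd.CategoricalDtype(["control", "HD"])
        )
        with pytest.warns(UserWarning, match="no astrocytes"):
            comp = state_composition(calls, cond)
        assert comp.loc["HD"].sum() == 0.0

    def test_multinomial_recovery(self, rng):
        probs = {"Quiescent": 0.5, "State1Q": 0.3, "State2R": 0.15, "State3R": 0.05}
        n = 2000
        draws = rng.choice(list(probs), p=list(probs.values()), size=n)
        calls = pd.Series(draws, index=[f"n{i}" for i in range(n)])
        cond = pd.Series(["HD"] * n, index=calls.index)
        comp = state_composition(calls, cond)
        for state, p in probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(comp.loc["HD", state] - p) <= 3 * se


class TestCrosstab:
    def test_single_state_cluster(self):
        calls = pd.Series(["State1Q"] * 5, index=[f"n{i}" for i in range(5)])
        clus = pd.Series(["c1"] * 5, index=calls.index)
        tab = cluster_state_crosstab(calls, clus)
        assert tab.loc["c1", "State1Q"] == 5
        assert (tab.to_numpy() > 0).sum() == 1

    def test_row_sums_equal_cluster_sizes(self, rng):
        n = 200
        calls = pd.Series(
            rng.choice(["Quiescent", "State1Q"], n), index=[f"n{i}" for i in range(n)]
        )
        clus = pd.Series(rng.choice(["a", "b", "c"], n), index=calls.index)
        tab = cluster_state_crosstab(calls, clus)
        assert (tab.sum(axis=1) == clus.value_counts().sort_index()).all()

    def test_shuffled_labels_show_no_association(self, rng):
        n = 300
        base = rng.choice(["Quiescent", "State1Q", "State2R"], n)
        ps = []
        for _ in range(20):
            calls = pd.Series(base, index=[f"n{i}" for i in range(n)])
            clus = pd.Series(rng.permutation(np.repeat(["a", "b", "c"], n // 3)), index=calls.index)
            tab = cluster_state_crosstab(calls, clus)
            ps.append(stats.chi2_contingency(tab)[1])
        assert np.mean(ps) > 0.01

    def test_planted_coupling_has_high_cramers_v(self, rng):
        n = 300
        states = np.array(["Quiescent", "State1Q", "State2R"])[
            np.repeat([0, 1, 2], n // 3)
        ]
        clusters = np.char.add("c", np.repeat(["0", "1", "2"], n // 3))
        flip = rng.random(n) < 0.05
        clusters[flip] = "c0"
        calls = pd.Series(states, index=[f"n{i}" for i in range(n)])
        clus = pd.Series(clusters, index=calls.index)
        tab = cluster_state_crosstab(calls, clus)
        chi2 = stats.chi2_contingency(tab)[0]
        v = np.sqrt(chi2 / (n * (min(tab.shape) - 1)))
        assert v >= 0.5
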