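"""Identity scoring, ambiguity rule, and mixed-precluster resolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snanno.classify import (
    AmbiguityRule,
    assign_class,
    flag_mixed,
    identity_scores,
    master_classes,
    resolve_mixed_preclusters,
)

from conftest import make_adata


class TestIdentityScores:
    def test_direct_ratio(self):
        genes = [f"g{i}" for i in range(30)]
        counts = np.zeros((1, 30), dtype=int)
        counts[0, :5] = 1  # 5 of the 20-gene astro list detected
        adata = make_adata(counts, genes=genes)
        scores = identity_scores(adata, {"Astrocyte": genes[:20]})
        assert scores.iloc[0, 0] == pytest.approx(25.0)

    def test_everything_expressed_scores_100(self):
        adata = make_adata(np.ones((2, 10), dtype=int))
        sets = {"A": [f"g{i}" for i in range(5)], "B": [f"g{i}" for i in range(10)]}
        scores = identity_scores(adata, sets)
        assert (scores.to_numpy() == 100.0).all()

    def test_random_binary_matches_set_intersection_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        detected = rng.random((40, 50)) < 0.3
        adata = make_adata(detected.astype(int), genes=genes)
        sets = {
            f"C{k}": list(rng.choice(genes, size=rng.integers(5, 20), replace=False))
            for k in range(6)
        }
        scores = identity_scores(adata, sets)
        for i in range(40):
            expressed = {genes[j] for j in range(50) if detected[i, j]}
            for name, members in sets.items():
                expected = 100 * len(expressed & set(members)) / len(set(members))
                assert scores.iloc[i][name] == pytest.approx(expected)

    def test_empty_intersected_set_names_the_class(self):
        adata = make_adata(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="Microglia"):
            identity_scores(adata, {"Microglia": ["absent_gene"]})

    def test_scores_invariant_to_monotone_zero_preserving_transform(self, rng):
        counts = rng.poisson(2, (20, 30))
        adata = make_adata(counts)
        sets = {"A": [f"g{i}" for i in range(10)]}
        s1 = identity_scores(adata, sets)
        s2 = identity_scores(make_adata(counts * 7 + (counts > 0)), sets)
        pd.testing.assert_frame_equal(s1, s2)


class TestAssignClass:
    def _scores(self, vals):
        cols = ["Neuron", "Astrocyte", "Oligodendrocyte", "OPC", "Microglia", "Endothelial"]
        return pd.DataFrame([dict(zip(cols, vals))])

    def test_clear_winner_unambiguous(self):
        s = self._scores([10, 40, 5, 0, 0, 0])
        out = assign_class(s, AmbiguityRule(rho=1.0))
        assert out.iloc[0]["assigned_class"] == "Astrocyte"
        assert not out.iloc[0]["ambiguous"]  # 10 + 5 < 40

    def test_flat_curve_is_ambiguous_at_rho_one(self):
        out = assign_class(self._scores([30, 20, 15, 0, 0, 0]), AmbiguityRule(1.0))
        assert out.iloc[0]["ambiguous"]  # 35 > 30

    def test_literal_mode_cannot_fire_on_same_vector(self):
        out = assign_class(self._scores([30, 20, 15, 0, 0, 0]), AmbiguityRule.literal())
        assert not out.iloc[0]["ambiguous"]  # 35 < 60

    def test_all_zero_scores_are_unknown_and_ambiguous(self):
        out = assign_class(self._scores([0, 0, 0, 0, 0, 0]))
        assert out.iloc[0]["assigned_class"] == "Unknown"
        assert out.iloc[0]["ambiguous"]

    def test_argmax_ties_broken_by_fixed_class_order(self):
        out = assign_class(self._scores([50, 50, 0, 0, 0, 0]))
        assert out.iloc[0]["assigned_class"] == "Neuron"

    def test_quality_flag_uses_max_score(self):
        out = assign_class(self._scores([15, 19.9, 0, 0, 0, 0]), identity_min=20.0)
        assert not out.iloc[0]["quality_pass"]
        out = assign_class(self._scores([15, 20.0, 0, 0, 0, 0]), identity_min=20.0)
        assert out.iloc[0]["quality_pass"]


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
        min_size=6,
        max_size=6,
        unique=True,
    )
)
def test_literal_rule_never_fires_on_strict_vectors(vals):
    """s2 + s3 <= 2*s1 always holds, so rho=2 cannot flag ordered scores."""
    cols = ["Neuron", "Astrocyte", "Oligodendrocyte", "OPC", "Microglia", "Endothelial"]
    scores = pd.DataFrame([dict(zip(cols, vals))])
    out = assign_class(scores, AmbiguityRule.literal())
    assert not out.iloc[0]["ambiguous"]


class TestMixedPreclusters:
    def test_dominant_class_is_clean_tied_is_mixed(self):
        enr = pd.DataFrame(
            {"Neuron": [1.0, 0.8], "Astrocyte": [0.1, 0.79], "OPC": [0.0, 0.1]},
            index=["c0", "c1"],
        )
        mixed = flag_mixed(enr, delta=0.1)
        assert not mixed["c0"] and mixed["c1"]

    def test_mixed_precluster_splits_by_argmax(self):
        idx = [f"n{i}" for i in range(10)]
        pre = pd.Series(["5"] * 10, index=idx)
        assigns = pd.DataFrame(
            {"assigned_class": ["Astrocyte"] * 6 + ["Neuron"] * 4}, index=idx
        )
        mixed = pd.Series({"5": True})
        out = resolve_mixed_preclusters(pre, mixed, assigns)
        counts = out["cluster"].value_counts()
        assert counts["Astrocyte_r5"] == 6 and counts["Neuron_r5"] == 4
        assert out["reassigned"].all()

    def test_clean_precluster_untouched(self):
        idx = ["a", "b"]
        pre = pd.Series(["2", "2"], index=idx)
        assigns = pd.DataFrame({"assigned_class": ["Neuron", "Astrocyte"]}, index=idx)
        out = resolve_mixed_preclusters(pre, pd.Series({"2": False}), assigns)
        assert list(out["cluster"]) == ["2", "2"]
        assert not out["reassigned"].any()

    def test_planted_merged_precluster_resolves_to_pure_clusters(self, rng):
        # two classes deliberately merged into one precluster
        genes = [f"g{i}" for i in range(40)]
        a = (rng.random((50, 40)) < 0.05).astype(int)
        a[:, :15] = (rng.random((50, 15)) < 0.9).astype(int)
        b = (rng.random((50, 40)) < 0.05).astype(int)
        b[:, 20:35] = (rng.random((50, 15)) < 0.9).astype(int)
        adata = make_adata(np.vstack([a, b]), genes=genes)
        sets = {"Neuron": genes[:15], "Astrocyte": genes[20:35]}
        scores = identity_scores(adata, sets)
        assigns = assign_class(scores)
        pre = pd.Series(["0"] * 100, index=adata.obs_names)
        out = resolve_mixed_preclusters(pre, pd.Series({"0": True}), assigns)
        truth = np.array(["Neuron"] * 50 + ["Astrocyte"] * 50)
        purity = np.mean(
            [
                (truth[(out["cluster"] == c).to_numpy()] == truth[(out["cluster"] == c).to_numpy()][0]).mean()
                for c in out["cluster"].unique()
            ]
        )
        assert purity >= 0.95

    def test_master_classes_majority_vote(self):
        idx = ["a", "b", "c", "d"]
        clusters = pd.Series(["x", "x", "x", "y"], index=idx)
        assigns = pd.DataFrame(
            {"assigned_class": ["Neuron", "Neuron", "Astrocyte", "OPC"]}, index=idx
        )
        per_cluster, per_nucleus = master_classes(clusters, assigns)
        assert per_cluster["x"] == "Neuron" and per_cluster["y"] == "OPC"
        assert list(per_nucleus) == ["Neuron", "Neuron", "Neuron", "OPC"]


def test_adding_expressed_gene_never_decreases_score(rng):
    """Weak monotonicity of the identity score in the gene list."""
    genes = [f"g{i}" for i in range(30)]
    counts = (rng.random((10, 30)) < 0.5).astype(int)
    adata = make_adata(counts, genes=genes)
    base_set = genes[:10]
    s0 = identity_scores(adata, {"A": base_set})["A"]
    for extra in genes[10:15]:
        s1 = identity_scores(adata, {"A": base_set + [extra]})["A"]
        expressed = counts[:, genes.index(extra)] > 0
        assert (s1[expressed] >= s0[expressed] - 1e-9).all()
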