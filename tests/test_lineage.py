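import numpy as np
import pandas as pd
import pytest

from chromstate import SignatureSet
from chromstate.lineage import (
    UNASSIGNED,
    assign_cell_type,
    derive_markers,
    flag_epithelial_clusters,
    normalize_cp10k,
    score_signature,
    signature_from_markers,
)

from conftest import make_counts


class TestEpithelialFlagging:
    def test_fifty_percent_rule_is_inclusive(self):
        clusters = np.array(["A"] * 10 + ["B"] * 10)
        epcam = np.array([True] * 5 + [False] * 5 + [True] * 4 + [False] * 6)
        assert flag_epithelial_clusters(clusters, epcam) == {"A"}

    def test_all_positive_flags_every_cluster(self):
        clusters = np.array(["A", "B", "B", "C"])
        assert flag_epithelial_clusters(clusters, np.ones(4, bool)) == {"A", "B", "C"}

    def test_invariant_to_cell_order_and_label_renaming(self):
        rng = np.random.default_rng(0)
        clusters = rng.choice(["x", "y", "z"], size=60)
        epcam = rng.random(60) < 0.6
        base = flag_epithelial_clusters(clusters, epcam)
        perm = rng.permutation(60)
        assert flag_epithelial_clusters(clusters[perm], epcam[perm]) == base
        renamed = np.char.add("new_", clusters.astype(str))
        assert flag_epithelial_clusters(renamed, epcam) == {
            f"new_{c}" for c in base
        }


class TestSignatureScoring:
    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(3.0, index=["g1", "g2"], columns=["c1", "c2", "c3"])
        scores = score_signature(expr, SignatureSet("s", ("g1", "g2")))
        assert (scores == 0).all()

    def test_exclusive_expression_gives_strict_maximum(self):
        expr = pd.DataFrame(
            [[0.0, 0.0, 5.0, 0.0]], index=["g1"], columns=list("abcd")
        )
        scores = score_signature(expr, SignatureSet("s", ("g1",)))
        assert scores.idxmax() == "c"
        assert scores["c"] > scores.drop("c").max()

    def test_matches_hand_computed_mean_zscore(self):
        values = np.array(
            [[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0]]
        )
        expr = pd.DataFrame(values, index=["g1", "g2", "g3"], columns=list("abcd"))
        scores = score_signature(expr, SignatureSet("s", ("g1", "g2", "g3")))
        z1 = (values[0] - values[0].mean()) / values[0].std()
        z2 = (values[1] - values[1].mean()) / values[1].std()
        z3 = np.zeros(4)  # zero-variance gene contributes 0
        expected = (z1 + z2 + z3) / 3
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.random((4, 8)), index=list("wxyz"), columns=[f"c{i}" for i in range(8)]
        )
        sig = SignatureSet("s", ("w", "x", "y"))
        shifted = score_signature(expr + 7.5, sig)
        np.testing.assert_allclose(
            score_signature(expr, sig).to_numpy(), shifted.to_numpy(), atol=1e-12
        )

    def test_missing_all_genes_raises_with_signature_name(self):
        expr = pd.DataFrame([[1.0]], index=["g1"], columns=["c1"])
        with pytest.raises(ValueError, match="mysig"):
            score_signature(expr, SignatureSet("mysig", ("absent",)))


class TestAssignment:
    def test_strict_maximum_wins_in_flagged_cluster(self):
        scores = pd.DataFrame(
            [[2.0, 0.0, 0.0, 0.0]], columns=["basal", "L1", "L2", "L3"], index=["c"]
        )
        out = assign_cell_type(scores, np.array([True]))
        assert out.loc["c", "label"] == "basal"
        assert bool(out.loc["c", "epithelial"])

    def test_exact_tie_is_unassigned(self):
        scores = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0]], columns=["basal", "L1", "L2", "L3"], index=["c"]
        )
        out = assign_cell_type(scores, np.array([True]))
        assert out.loc["c", "label"] == UNASSIGNED
        assert not bool(out.loc["c", "epithelial"])

    def test_unflagged_cells_are_unassigned(self):
        scores = pd.DataFrame([[5.0, 0.0]], columns=["basal", "L1"], index=["c"])
        out = assign_cell_type(scores, np.array([False]))
        assert out.loc["c", "label"] == UNASSIGNED


class TestMarkers:
    @staticmethod
    def _planted_expression(seed=0, n_genes=50, n_per_group=20):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5.0, size=(n_genes, 2 * n_per_group))
        counts[0, :n_per_group] += 50  # gene0 exclusive to label A
        counts[0, n_per_group:] = 0
        labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
        return make_counts(counts), labels

    def test_planted_exclusive_gene_is_top_ranked_significant(self):
        counts, labels = self._planted_expression()
        markers = derive_markers(normalize_cp10k(counts), labels)
        top_a = markers[(markers["label"] == "A") & (markers["rank"] == 1)]
        assert list(top_a["gene"]) == ["peak0"]
        assert (top_a["fdr"] < 0.05).all()

    def test_permuting_cell_order_gives_identical_tables(self):
        counts, labels = self._planted_expression(seed=3)
        expr = normalize_cp10k(counts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.shape[1])
        permuted = derive_markers(expr.iloc[:, perm], labels[perm])
        original = derive_markers(expr, labels)
        for lab in ("A", "B"):
            a = original[original["label"] == lab].set_index("gene")
            b = permuted[permuted["label"] == lab].set_index("gene")
            np.testing.assert_allclose(
                a[["log2fc", "p_value", "fdr"]].to_numpy(),
                b.loc[a.index, ["log2fc", "p_value", "fdr"]].to_numpy(),
                atol=1e-12,
            )

    def test_label_below_min_cells_is_skipped(self):
        counts, labels = self._planted_expression()
        labels = labels.copy()
        labels[:2] = "C"  # 2-cell label
        markers = derive_markers(normalize_cp10k(counts), labels)
        assert "C" not in set(markers["label"])


class TestSignatureFromMarkers:
    @staticmethod
    def _table(fdr, fc):
        return pd.DataFrame(
            {
                "label": "A",
                "gene": [f"g{i}" for i in range(len(fdr))],
                "log2fc": np.log2(fc),
                "fold_change": fc,
                "p_value": fdr,
                "fdr": fdr,
                "rank": np.arange(1.0, len(fdr) + 1),
            }
        )

    def test_cutoffs_are_strict(self):
        table = self._table(
            fdr=np.array([0.049, 0.051, 0.049, 0.049]),
            fc=np.array([2.1, 2.1, 2.0, 3.0]),
        )
        sig = signature_from_markers(table, "A")
        assert set(sig.genes) == {"g0", "g3"}

    def test_empty_input_gives_empty_signature(self):
        table = self._table(fdr=np.array([0.5]), fc=np.array([1.0]))
        sig = signature_from_markers(table, "A")
        assert len(sig) == 0
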