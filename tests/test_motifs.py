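import numpy as np
import pandas as pd
import pytest

from chromstate import (
    celltype_motif_enrichment,
    correlation_filter,
    differential_accessibility,
    expression_filter,
    reduce_motif_family,
)
from chromstate.motifs import normalize_depth

from oracles import hypergeom_sf_enumeration, spearman_rank_pearson


@pytest.fixture
def membership():
    return pd.DataFrame(
        {
            "ERG": [1, 0, 0, 0],
            "ETS": [0, 1, 0, 0],
            "ETV": [0, 0, 0, 0],
            "FLI": [0, 0, 1, 0],
        },
        index=[f"p{i}" for i in range(4)],
    )


class TestFamilyReduction:
    def test_family_is_logical_or(self, membership):
        out = reduce_motif_family(membership, ["ERG", "ETS", "ETV", "FLI"], "fam")
        assert list(out["fam"]) == [1, 1, 1, 0]
        assert set(membership.columns) < set(out.columns)

    def test_family_count_bounds_member_counts(self, membership):
        out = reduce_motif_family(membership, ["ERG", "ETS"], "fam")
        assert out["fam"].sum() >= out[["ERG", "ETS"]].sum().max()

    def test_unknown_member_raises(self, membership):
        with pytest.raises(KeyError):
            reduce_motif_family(membership, ["NOPE"], "fam")


class TestEnrichment:
    def test_exact_toy_probability(self):
        """Population 10, cell type 5, 5 accessible, overlap 5:
        p = C(5,5) C(5,0) / C(10,5) = 1/252."""
        z = pd.DataFrame(
            [[1.0] * 5 + [-1.0] * 5], index=["m"], columns=[f"c{i}" for i in range(10)]
        )
        labels = np.array(["T"] * 5 + ["O"] * 5)
        table = celltype_motif_enrichment(z, labels)
        row = table[(table["motif"] == "m") & (table["cell_type"] == "T")].iloc[0]
        np.testing.assert_allclose(row["p_value"], 1 / 252, atol=1e-15)

    def test_all_cells_accessible_gives_p_one(self):
        z = pd.DataFrame([[2.0] * 8], index=["m"], columns=[f"c{i}" for i in range(8)])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        table = celltype_motif_enrichment(z, labels)
        np.testing.assert_allclose(table["p_value"], 1.0)

    def test_matches_enumeration_oracle_small_populations(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            population = int(rng.integers(4, 31))
            accessible = int(rng.integers(0, population + 1))
            type_size = int(rng.integers(1, population))
            z = np.full(population, -1.0)
            z[:accessible] = 1.0
            labels = np.array(["O"] * population, dtype=object)
            idx = rng.choice(population, size=type_size, replace=False)
            labels[idx] = "T"
            table = celltype_motif_enrichment(
                pd.DataFrame([z], index=["m"], columns=[f"c{i}" for i in range(population)]),
                labels,
            )
            row = table[table["cell_type"] == "T"].iloc[0]
            expected = hypergeom_sf_enumeration(
                int(row["overlap"]), population, accessible, type_size
            )
            np.testing.assert_allclose(row["p_value"], expected, atol=1e-12)

    def test_invariant_to_cell_and_motif_ordering(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(
            rng.standard_normal((3, 40)),
            index=["m1", "m2", "m3"],
            columns=[f"c{i}" for i in range(40)],
        )
        labels = rng.choice(["A", "B"], size=40)
        base = celltype_motif_enrichment(z, labels).set_index(["motif", "cell_type"])
        perm = rng.permutation(40)
        shuffled = celltype_motif_enrichment(
            z.iloc[[2, 0, 1], perm], labels[perm]
        ).set_index(["motif", "cell_type"])
        np.testing.assert_allclose(
            base["p_value"].sort_index(), shuffled["p_value"].sort_index(), atol=1e-12
        )

    def test_null_balanced_design_is_not_enriched(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(
            rng.standard_normal((1, 400)),
            index=["m"],
            columns=[f"c{i}" for i in range(400)],
        )
        labels = np.repeat(["A", "B"], 200)
        table = celltype_motif_enrichment(z, labels)
        assert not table["enriched"].any()
        assert (table["fdr"] > 0.01).all()


class TestRetentionFilters:
    def test_expression_cutoff_is_strict(self):
        mean_expr = pd.DataFrame(
            {"IM": [1.01, 1.00], "L1": [0.0, 5.0]}, index=["gA", "gB"]
        )
        kept = expression_filter({"mA": "gA", "mB": "gB"}, mean_expr)
        assert bool(kept.loc["mA", "IM"]) and not bool(kept.loc["mB", "IM"])
        assert not bool(kept.loc["mA", "L1"]) and bool(kept.loc["mB", "L1"])

    def test_absent_gene_drops_motif_everywhere(self):
        mean_expr = pd.DataFrame({"IM": [2.0]}, index=["gA"])
        kept = expression_filter({"mX": "missing"}, mean_expr)
        assert not kept.loc["mX"].any()

    def test_identity_and_antitone_correlations(self):
        z = np.arange(12, dtype=float)
        rho, kept = correlation_filter(z, z)
        assert rho == pytest.approx(1.0) and kept
        rho, kept = correlation_filter(z, -z)
        assert rho == pytest.approx(-1.0) and not kept

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(12)
        g = z + rng.standard_normal(12)
        rho, _ = correlation_filter(z, g)
        np.testing.assert_allclose(rho, spearman_rank_pearson(z, g), atol=1e-12)

    def test_constant_vector_not_retained(self):
        rho, kept = correlation_filter(np.ones(12), np.arange(12.0))
        assert np.isnan(rho) and not kept

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            correlation_filter(np.arange(5.0), np.arange(5.0))


class TestDifferentialAccessibility:
    def test_planted_amplified_peak_is_flagged(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5.0, size=(50, 100)).astype(float)
        X[0, :50] *= 4
        table = differential_accessibility(
            normalize_depth(X), np.arange(50), np.arange(50, 100)
        )
        assert bool(table.loc[0, "is_dar"])

    def test_null_split_rarely_yields_dars(self):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.poisson(5.0, size=(60, 60)).astype(float)
            table = differential_accessibility(
                normalize_depth(X), np.arange(30), np.arange(30, 60)
            )
            clean += int(table["is_dar"].sum() == 0)
        assert clean >= 18

    def test_log2fc_rule_is_inclusive_at_half(self):
        table = pd.DataFrame(
            {"log2fc": [0.49, 0.5], "fdr": [0.001, 0.001]}
        )
        flags = (table["fdr"] < 0.05) & (table["log2fc"] >= 0.5)
        rng = np.random.default_rng(5)
        X = rng.poisson(20.0, size=(10, 40)).astype(float)
        out = differential_accessibility(X, np.arange(20), np.arange(20, 40))
        # strictness of the implemented rule mirrors the hand rule above
        assert list(flags) == [False, True]
        assert ((out["fdr"] < 0.05) & (out["log2fc"] >= 0.5)).equals(out["is_dar"])

    def test_overlapping_groups_raise(self):
        with pytest.raises(ValueError):
            differential_accessibility(
                np.ones((5, 10)), np.arange(5), np.arange(4, 9)
            )
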