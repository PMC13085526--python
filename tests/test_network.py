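"""Inter-organ correlation, pair filtering, Venn decomposition, network export."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from splitroot import (
    build_network,
    condition_venn,
    filter_pairs_by_deg,
    filter_pairs_by_mobility,
    interorgan_correlation,
)
from splitroot.network import (
    AlignmentError,
    correlation_grid,
    export_graphml,
    export_sif,
)

from conftest import make_matrix


def pair_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["shoot_gene", "root_gene", "condition", "r", "p", "fdr", "sign",
                 "mobility_support"],
    )


def simple_pair(s, r, cond="C.NO3", sign="positive"):
    return (s, r, cond, 0.95 if sign == "positive" else -0.95, 1e-9, 1e-6, sign, "unknown")


class TestCorrelationGrid:
    def test_worked_product_moment_example(self):
        r, p = correlation_grid(
            np.array([[1.0, 2.0, 3.0, 4.0]]), np.array([[1.0, 3.0, 2.0, 4.0]])
        )
        assert np.isclose(r[0, 0], 0.8)

    def test_affine_and_negated_series(self):
        x = np.array([[1.0, 2.0, 5.0, 3.0]])
        y = np.vstack([2 * x[0] + 3, -x[0]])
        r, p = correlation_grid(x, y)
        np.testing.assert_allclose(r[0], [1.0, -1.0])
        assert (p[0] < 1e-6).all()

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(3, 10)), rng.normal(size=(4, 10))
        r, p = correlation_grid(x, y)
        from scipy.stats import pearsonr

        for i in range(3):
            for j in range(4):
                ref = pearsonr(x[i], y[j])
                assert np.isclose(r[i, j], ref.statistic)
                assert np.isclose(p[i, j], ref.pvalue)


class TestInterorganCorrelation:
    def _matrices(self, seed=0, n_genes=30):
        rng = np.random.default_rng(seed)
        times = [0.0, 2.0, 4.0, 8.0]
        shoot = make_matrix(
            rng.uniform(50, 500, (n_genes, 3 * 4 * 3)), organ="shoot",
            times=times, n_rep=3,
        )
        root = make_matrix(
            rng.uniform(50, 500, (n_genes, 4 * 4 * 3)), organ="root",
            times=times, n_rep=3,
        )
        return shoot, root

    def test_planted_affine_pair_retained_with_sign(self):
        shoot, root = self._matrices()
        # make root gene 0 an affine copy of shoot gene 0 under C.NO3 and a
        # negated copy of shoot gene 1 under C.Cl
        s = shoot.select(condition="C.NO3").ordered(("time_h", "replicate"))
        r_cols = root.select(condition="C.NO3").ordered(("time_h", "replicate"))
        root.values.loc["G00000", r_cols.samples.index] = (
            2.0 * s.values.loc["G00000"].to_numpy() + 7.0
        )
        s2 = shoot.select(condition="C.Cl").ordered(("time_h", "replicate"))
        r2 = root.select(condition="C.Cl").ordered(("time_h", "replicate"))
        root.values.loc["G00001", r2.samples.index] = (
            1000.0 / s2.values.loc["G00001"].to_numpy() ** 0  # keep positive
            + 600.0
            - s2.values.loc["G00001"].to_numpy()
        )
        pairs = interorgan_correlation(shoot, root, fdr_cutoff=0.001)
        key = set(zip(pairs.shoot_gene, pairs.root_gene, pairs.condition, pairs.sign))
        assert ("G00000", "G00000", "C.NO3", "positive") in key
        # log2 breaks exact linearity of the negated copy; it must still be
        # strongly negative if retained, so check sign on the raw grid
        sub = pairs[(pairs.shoot_gene == "G00001") & (pairs.condition == "C.Cl")]
        assert (sub["sign"] == "negative").all()

    def test_misaligned_series_rejected_with_unmatched_samples(self):
        shoot, root = self._matrices()
        drop = root.samples.index[
            (root.samples["condition"] == "C.NO3") & (root.samples["replicate"] == 3)
        ]
        root = root.subset_samples(~root.samples.index.isin(drop))
        with pytest.raises(AlignmentError, match="C.NO3"):
            interorgan_correlation(shoot, root)

    def test_collapse_replicates_uses_time_means(self):
        shoot, root = self._matrices()
        pairs = interorgan_correlation(
            shoot, root, fdr_cutoff=1.0, collapse_replicates=True
        )
        # all pair p-values computed at N=4: r=1 boundary cases aside, the
        # grid is exhaustive
        assert len(pairs) == 30 * 30 * 4


class TestPairFilters:
    def test_deg_filter_requires_both_members(self):
        pairs = pair_frame([
            simple_pair("s1", "r1"), simple_pair("s1", "r2"), simple_pair("s2", "r1"),
        ])
        out = filter_pairs_by_deg(pairs, {"s1"}, {"r1"})
        assert list(zip(out.shoot_gene, out.root_gene)) == [("s1", "r1")]
        assert filter_pairs_by_deg(pairs, set(), set()).empty

    def test_mobility_filter_annotates_support(self):
        pairs = pair_frame([
            simple_pair("s1", "r1"), simple_pair("s2", "r2"), simple_pair("s3", "r3"),
        ])
        out = filter_pairs_by_mobility(pairs, {"s1", "r2", "s3", "r3"})
        support = dict(zip(out.shoot_gene, out.mobility_support))
        assert support == {"s1": "shoot_mobile", "s2": "root_mobile", "s3": "both"}
        assert filter_pairs_by_mobility(pairs, set()).empty

    def test_filters_commute(self, small_experiment):
        _, shoot, root, truth = small_experiment
        pairs = interorgan_correlation(shoot, root, fdr_cutoff=0.01)
        sdeg = set(list(truth.gene_class)[:100])
        rdeg = set(list(truth.gene_class)[50:150])
        a = filter_pairs_by_mobility(
            filter_pairs_by_deg(pairs, sdeg, rdeg), truth.mobile_set
        )
        b = filter_pairs_by_deg(
            filter_pairs_by_mobility(pairs, truth.mobile_set), sdeg, rdeg
        )
        pd.testing.assert_frame_equal(
            a.sort_values(["shoot_gene", "root_gene", "condition"]).reset_index(drop=True),
            b.sort_values(["shoot_gene", "root_gene", "condition"]).reset_index(drop=True),
        )


class TestConditionVenn:
    def test_disjoint_sets_fill_singleton_regions(self):
        rows = []
        sizes = {"C.NO3": 2, "Sp.NO3": 3, "Sp.Cl": 4, "C.Cl": 5}
        i = 0
        for cond, n in sizes.items():
            for _ in range(n):
                rows.append(simple_pair(f"s{i}", f"r{i}", cond))
                i += 1
        venn = condition_venn(pair_frame(rows))["all"]
        for cond, n in sizes.items():
            assert venn[cond] == n
        assert sum(v for k, v in venn.items() if "&" in k) == 0

    def test_identical_sets_fill_only_four_way_region(self):
        rows = [
            simple_pair("s1", "r1", cond)
            for cond in ("C.NO3", "Sp.NO3", "Sp.Cl", "C.Cl")
        ]
        venn = condition_venn(pair_frame(rows))["all"]
        assert venn["C.NO3&Sp.NO3&Sp.Cl&C.Cl"] == 1
        assert sum(venn.values()) == 1

    def test_partial_overlap_enumeration(self):
        rows = [
            simple_pair("p", "p", "C.NO3"),
            simple_pair("q", "q", "C.NO3"),
            simple_pair("q", "q", "Sp.NO3"),
            simple_pair("r", "r", "Sp.NO3"),
        ]
        venn = condition_venn(pair_frame(rows))["all"]
        assert venn["C.NO3"] == 1 and venn["Sp.NO3"] == 1
        assert venn["C.NO3&Sp.NO3"] == 1

    def test_split_by_sign_separates_decompositions(self):
        rows = [
            simple_pair("a", "b", "C.NO3", "positive"),
            simple_pair("c", "d", "C.NO3", "negative"),
        ]
        venn = condition_venn(pair_frame(rows), split_by_sign=True)
        assert venn["positive"]["C.NO3"] == 1
        assert venn["negative"]["C.NO3"] == 1


class TestNetwork:
    def test_shared_shoot_gene_gives_three_nodes_two_edges(self):
        g = build_network(pair_frame([
            simple_pair("s1", "r1"), simple_pair("s1", "r2"),
        ]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2

    def test_condition_set_merged_on_one_edge(self):
        g = build_network(pair_frame([
            simple_pair("s1", "r1", "C.NO3", "positive"),
            simple_pair("s1", "r1", "C.Cl", "negative"),
        ]))
        assert g.number_of_edges() == 1
        data = g.edges["shoot:s1", "root:r1"]
        assert data["conditions"] == "C.Cl,C.NO3"
        assert "C.Cl:negative" in data["signs"] and "C.NO3:positive" in data["signs"]

    def test_same_gene_across_organs_is_not_a_self_edge(self):
        g = build_network(pair_frame([simple_pair("g", "g")]))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_empty_network_exports_are_valid(self, tmp_path):
        g = build_network(pair_frame([]))
        export_sif(g, tmp_path / "net.sif")
        export_graphml(g, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == 0

    def test_graphml_round_trip_counts(self, tmp_path):
        g = build_network(pair_frame([
            simple_pair("s1", "r1"), simple_pair("s1", "r2"), simple_pair("s2", "r2"),
        ]))
        export_graphml(g, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
        sif = (tmp_path / "net.sif")
        export_sif(g, sif)
        assert len(sif.read_text().splitlines()) == g.number_of_edges()
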