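"""Rank-product contrasts, RP codes, and the interdependency diagnostic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splitroot import (
    SimulationConfig,
    generate_splitroot_experiment,
    interdependency_diagnostic,
    rank_product_contrast,
    root_deg_pipeline,
    rp_code_assemble,
    systemic_signal_sets,
)
from splitroot.root import RankProductError

from conftest import make_matrix


def brute_force_rp_pfp(a, b):
    """Independent oracle: exhaustive PFP over all joint rank permutations.

    Ranks each replicate's fold changes descending (up) / ascending (down),
    computes geometric-mean rank products, and enumerates every joint
    assignment of the per-replicate rank vectors to genes for the null.
    """
    d = np.asarray(b, float) - np.asarray(a, float)
    G, k = d.shape

    def ranks(mat):
        out = np.empty_like(mat)
        for i in range(mat.shape[1]):
            order = np.argsort(-mat[:, i])
            r = np.empty(G)
            r[order] = np.arange(1, G + 1)
            # average ties
            for val in np.unique(mat[:, i]):
                sel = mat[:, i] == val
                r[sel] = r[sel].mean()
            out[:, i] = r
        return out

    def pfp(rank_mat):
        rp = np.prod(rank_mat, axis=1) ** (1.0 / k)
        n_joint = math.factorial(G) ** k
        null = []
        for cols in itertools.product(
            *(itertools.permutations(rank_mat[:, i]) for i in range(k))
        ):
            null.extend(np.prod(np.array(cols).T, axis=1) ** (1.0 / k))
        null = np.sort(null)
        out = np.empty(G)
        for g in range(G):
            expected = np.searchsorted(null, rp[g] * (1 + 1e-12), side="right") / n_joint
            j = (rp <= rp[g] * (1 + 1e-12)).sum()
            out[g] = expected / j
        return rp, out

    rp_up, pfp_up = pfp(ranks(d))
    rp_down, pfp_down = pfp(ranks(-d))
    return rp_up, pfp_up, rp_down, pfp_down


class TestRankProduct:
    def test_consistent_top_rank_gives_minimum_rp(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (6, 3))
        b = a.copy()
        b[2] += 10  # gene 2 most up in every replicate
        res = rank_product_contrast(a, b, mode="sample", n_perm=10, seed=0)
        assert res["rp_up"].iloc[2] == 1.0

    def test_geometric_mean_of_ranks(self):
        # one gene with up-ranks (1, 2, 4): RP = (1*2*4)^(1/3) = 2 exactly
        a = np.zeros((4, 3))
        # replicate up-ranks of gene 0 are 1, 2, 4 by construction
        b = np.array(
            [
                [9.0, 8.0, 2.0],  # rank 1, 2, 4
                [8.0, 9.0, 5.0],
                [7.0, 7.0, 6.0],
                [6.0, 6.0, 7.0],
            ]
        )
        res = rank_product_contrast(a, b, mode="sample", n_perm=10, seed=0)
        assert np.isclose(res["rp_up"].iloc[0], 2.0)

    @pytest.mark.parametrize("G,k", [(3, 2), (4, 2), (4, 1)])
    def test_exhaustive_pfp_matches_independent_oracle(self, G, k):
        rng = np.random.default_rng(5)
        a = rng.normal(5, 1, (G, k))
        b = a + rng.normal(0, 1, (G, k))
        res = rank_product_contrast(a, b, mode="exhaustive")
        rp_up, pfp_up, rp_down, pfp_down = brute_force_rp_pfp(a, b)
        np.testing.assert_allclose(res["rp_up"], rp_up, rtol=1e-9)
        np.testing.assert_allclose(res["pfp_up"], pfp_up, atol=1e-9)
        np.testing.assert_allclose(res["pfp_down"], pfp_down, atol=1e-9)

    def test_rp_values_within_bounds_and_relabeling_equivariant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        res = rank_product_contrast(a, b, mode="sample", n_perm=50, seed=1)
        assert ((res["rp_up"] >= 1) & (res["rp_up"] <= 8)).all()
        perm = rng.permutation(8)
        res_p = rank_product_contrast(a[perm], b[perm], mode="sample", n_perm=50, seed=1)
        np.testing.assert_allclose(res_p["rp_up"], res["rp_up"].to_numpy()[perm])

    def test_shape_and_nperm_validation(self):
        with pytest.raises(RankProductError):
            rank_product_contrast(np.zeros((3, 2)), np.zeros((3, 3)))
        with pytest.raises(RankProductError):
            rank_product_contrast(np.zeros((3, 2)), np.zeros((3, 2)), n_perm=0)


class TestRPCode:
    def _results(self, digits_wanted):
        """Fabricate per-contrast results with chosen significance."""
        genes = [f"G{i}" for i in range(len(digits_wanted))]
        results = {}
        for c in range(1, 7):
            pfp_up = [0.01 if d[c - 1] == 1 else 0.9 for d in digits_wanted]
            pfp_down = [0.01 if d[c - 1] == -1 else 0.9 for d in digits_wanted]
            results[c] = pd.DataFrame(
                {
                    "rp_up": 1.0,
                    "rp_down": 1.0,
                    "pfp_up": pfp_up,
                    "pfp_down": pfp_down,
                },
                index=genes,
            )
        return results

    def test_digit_assembly_and_groups(self):
        codes = rp_code_assemble(
            self._results([(0, 0, 0, 0, 0, 0), (1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, -1)])
        )
        assert codes.loc["G0", [f"r{i}" for i in range(1, 7)]].tolist() == [0] * 6
        assert pd.isna(codes.loc["G0", "group_id"])
        assert codes.loc["G1", "r1"] == 1
        assert codes.loc["G2", "r6"] == -1
        assert codes.loc["G1", "group_id"] != codes.loc["G2", "group_id"]

    def test_both_tails_passing_resolved_by_smaller_pfp(self):
        results = self._results([(1, 0, 0, 0, 0, 0)])
        results[1].loc["G0", ["pfp_up", "pfp_down"]] = (0.02, 0.01)
        codes = rp_code_assemble(results)
        assert codes.loc["G0", "r1"] == -1
        results[1].loc["G0", ["pfp_up", "pfp_down"]] = (0.01, 0.01)
        assert rp_code_assemble(results).loc["G0", "r1"] == 0

    def test_missing_contrast_rejected(self):
        results = self._results([(0, 0, 0, 0, 0, 0)])
        del results[4]
        with pytest.raises(RankProductError, match="4"):
            rp_code_assemble(results)

    def test_systemic_signal_sets(self):
        codes = rp_code_assemble(
            self._results(
                [(1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, -1), (1, 0, 0, 0, 0, 1), (0, 0, 1, 0, 0, 0)]
            )
        )
        demand, supply = systemic_signal_sets(codes)
        assert demand == {"G0", "G2"}
        assert supply == {"G1", "G2"}


class TestRootPipeline:
    def test_planted_r1_sign_recovered(self, small_experiment):
        _, _, root, truth = small_experiment
        from splitroot import filter_low_expression

        m = filter_low_expression(root)
        rec = root_deg_pipeline(
            m.subset_samples(m.samples["time_h"] == 8.0), n_perm=500, seed=3
        )
        rec = rec.set_index("gene_id")
        hits, total = 0, 0
        for cls in ("split_induced", "split_repressed"):
            want = 1 if cls == "split_induced" else -1
            for g in truth.genes_of_class(cls):
                if g in rec.index:
                    total += 1
                    hits += rec.loc[g, "r1"] == want
        assert total > 0 and hits / total >= 0.8

    def test_missing_condition_named(self):
        vals = np.random.default_rng(0).uniform(40, 100, (5, 6))
        m = make_matrix(vals, organ="root", conditions=("C.NO3", "Sp.NO3"), n_rep=3)
        with pytest.raises(RankProductError, match="C.Cl|Sp.Cl"):
            root_deg_pipeline(m)


class TestInterdependency:
    def _root(self, n_genes=300, pool_sd=0.15, seed=5):
        cfg = SimulationConfig(n_genes=n_genes, pool_effect_sd=pool_sd, seed=seed)
        _, root, _ = generate_splitroot_experiment(cfg)
        return root

    def test_identical_halves_maximal_statistic(self):
        root = self._root(n_genes=50)
        vals = root.values.copy()
        spno3 = root.samples.index[root.samples["condition"] == "Sp.NO3"]
        spcl = root.samples.index[root.samples["condition"] == "Sp.Cl"]
        vals[spcl] = vals[spno3].to_numpy()
        from dataclasses import replace

        stat, _ = interdependency_diagnostic(
            replace(root, values=vals), n_perm=20, seed=0
        )
        assert np.isclose(stat, 1.0)

    def test_planted_pool_effect_detected(self):
        stat, p = interdependency_diagnostic(self._root(), n_perm=300, seed=1)
        assert stat > 0.1 and p < 0.05

    def test_independent_halves_not_flagged(self):
        stat, p = interdependency_diagnostic(
            self._root(pool_sd=1e-9), n_perm=300, seed=1
        )
        assert p > 0.05

    def test_single_replicate_rejected(self):
        root = self._root(n_genes=20)
        sub = root.subset_samples(root.samples["replicate"] == 1)
        with pytest.raises(RankProductError):
            interdependency_diagnostic(sub, n_perm=10, seed=0)
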