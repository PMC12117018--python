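"""Single-cell layer: barcode resolution, metacell graph, modules, DE."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from clonetrack import plasticity


def assign(rows):
    return pd.DataFrame(rows, columns=["cell_id", "barcode", "reads"])


class TestResolveMultibarcode:
    def test_unique_pattern_is_doublet(self):
        df = assign([("c1", "AAA", 10), ("c1", "CCC", 5), ("c2", "AAA", 20)])
        table, rate = plasticity.resolve_multibarcode_cells(df)
        row = table.set_index("cell_id").loc["c1"]
        assert row.status == plasticity.STATUS_DOUBLET
        assert row.resolved_barcode is None
        assert rate == pytest.approx(0.5)

    def test_repeated_pattern_is_multi_integration(self):
        rows = [(f"c{i}", b, r) for i in range(5) for b, r in [("AAA", 10), ("CCC", 50)]]
        table, _ = plasticity.resolve_multibarcode_cells(assign(rows))
        assert (table.status == plasticity.STATUS_MULTI).all()
        # CCC has the higher aggregate read count -> representative
        assert (table.resolved_barcode == "CCC").all()

    def test_tie_broken_lexicographically(self):
        rows = [(f"c{i}", b, 10) for i in range(3) for b in ("TTT", "AAA")]
        table, _ = plasticity.resolve_multibarcode_cells(assign(rows))
        assert (table.resolved_barcode == "AAA").all()

    def test_single_barcode_cells_unchanged(self):
        df = assign([("c1", "AAA", 5), ("c2", "GGG", 7)])
        table, rate = plasticity.resolve_multibarcode_cells(df)
        assert (table.status == plasticity.STATUS_SINGLE).all()
        assert rate == 0.0

    def test_planted_rates_recovered(self, sc_fixture):
        table, rate = plasticity.resolve_multibarcode_cells(sc_fixture.cell_barcodes)
        truth = sc_fixture.truth
        planted = (truth.status != "single").mean()
        se = np.sqrt(planted * (1 - planted) / len(truth))
        assert abs(rate - planted) < 4 * se
        # every resolved multi-integration cell maps back to one clone barcode
        multi = table[table.status == plasticity.STATUS_MULTI]
        resolved_cells = truth.set_index("cell_id").loc[multi.cell_id]
        assert (resolved_cells.status == "multi_integration").all()


class TestKnnGraph:
    def test_four_nodes_k3_complete(self, rng):
        a = rng.uniform(0.1, 0.9, size=(4, 4))
        sim = (a + a.T) / 2
        np.fill_diagonal(sim, 1.0)
        g = plasticity.build_knn_graph(sim, k=3)
        assert g.number_of_edges() == 6

    def test_chain_similarity_recovers_chain(self, sc_fixture):
        g = plasticity.build_knn_graph(sc_fixture.similarity, k=3)
        mcs = list(sc_fixture.similarity.index)
        for a, b in zip(mcs[:-1], mcs[1:]):
            assert g.has_edge(a, b)

    def test_deterministic_under_ties(self):
        sim = np.full((5, 5), 0.5)
        np.fill_diagonal(sim, 1.0)
        g1 = plasticity.build_knn_graph(sim, k=2)
        g2 = plasticity.build_knn_graph(sim, k=2)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_too_few_nodes_error(self):
        with pytest.raises(ValueError):
            plasticity.build_knn_graph(np.ones((1, 1)))


def membership_from(rows):
    return pd.DataFrame(rows, columns=["metacell", "clone", "passage", "cells"])


class TestRootsAndDistances:
    def test_three_primary_cells_make_a_root(self):
        m = membership_from([("m1", "cl", "P", 3), ("m2", "cl", "P", 2),
                             ("m3", "cl", "S1", 50)])
        assert plasticity.find_roots(m, "cl") == {"m1"}

    def test_no_roots_is_empty_set(self):
        m = membership_from([("m1", "cl", "P", 1)])
        assert plasticity.find_roots(m, "cl") == set()

    def test_chain_distances(self):
        g = nx.path_graph(["A", "B", "C"])
        assert plasticity.assign_distances(g, {"A"}) == {"A": 0, "B": 1, "C": 2}

    def test_all_roots_all_zero(self):
        g = nx.path_graph(["A", "B", "C"])
        d = plasticity.assign_distances(g, {"A", "B", "C"})
        assert set(d.values()) == {0}

    def test_empty_roots_error(self):
        with pytest.raises(ValueError):
            plasticity.assign_distances(nx.path_graph(3), set())

    def test_matches_brute_force_shortest_paths(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 25))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            roots = set(rng.choice(n, size=max(1, n // 5), replace=False).tolist())
            got = plasticity.assign_distances(g, roots)
            # oracle: min over roots of all-pairs BFS lengths
            expect = {}
            for r in roots:
                for node, d in nx.single_source_shortest_path_length(g, r).items():
                    expect[node] = min(expect.get(node, np.inf), d)
            assert got == expect

    def test_unreachable_metacells_absent(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        d = plasticity.assign_distances(g, {"A"})
        assert "C" not in d


class TestGeneModules:
    def test_planted_anticorrelated_blocks(self, rng):
        x = np.linspace(0, 1, 30)
        up = np.outer(x, np.ones(5)) + rng.normal(0, 0.01, (30, 5))
        down = np.outer(1 - x, np.ones(5)) + rng.normal(0, 0.01, (30, 5))
        expr = pd.DataFrame(
            np.hstack([up, down]),
            columns=[f"u{i}" for i in range(5)] + [f"d{i}" for i in range(5)],
        )
        mods = plasticity.cluster_gene_modules(expr, n_modules=2, seed=0)
        sets = [set(g) for g in mods.modules.values()]
        assert {f"u{i}" for i in range(5)} in sets
        assert {f"d{i}" for i in range(5)} in sets

    def test_singleton_modules_when_k_equals_genes(self, rng):
        expr = pd.DataFrame(rng.uniform(0.1, 1, size=(10, 4)),
                            columns=list("abcd"))
        mods = plasticity.cluster_gene_modules(expr, n_modules=4, seed=0)
        assert sorted(len(g) for g in mods.modules.values()) == [1, 1, 1, 1]

    def test_deterministic_under_seed(self, sc_fixture):
        m1 = plasticity.cluster_gene_modules(sc_fixture.expression, 5, seed=3)
        m2 = plasticity.cluster_gene_modules(sc_fixture.expression, 5, seed=3)
        assert m1.modules == m2.modules

    def test_k_below_two_error(self, sc_fixture):
        with pytest.raises(ValueError):
            plasticity.cluster_gene_modules(sc_fixture.expression, 1)

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ValueError):
            plasticity.GeneModuleSet({0: ["a", "b"], 1: ["b"]})


class TestEnrichmentByDistance:
    def test_uniform_expression_zero_enrichment(self):
        expr = pd.DataFrame(np.ones((6, 4)), index=[f"m{i}" for i in range(6)],
                            columns=list("abcd"))
        mods = plasticity.GeneModuleSet({0: ["a", "b"], 1: ["c", "d"]})
        dist = {f"m{i}": i // 2 for i in range(6)}
        out = plasticity.module_enrichment_by_distance(expr, mods, dist)
        assert np.allclose(out.log2_enrichment, 0.0)

    def test_planted_gradient_strictly_increasing(self):
        idx = [f"m{i}" for i in range(8)]
        grad = np.linspace(1, 5, 8)
        expr = pd.DataFrame({"g1": grad, "g2": grad * 2, "flat": np.ones(8)}, index=idx)
        mods = plasticity.GeneModuleSet({0: ["g1", "g2"], 1: ["flat"]})
        dist = {m: i for i, m in enumerate(idx)}
        out = plasticity.module_enrichment_by_distance(expr, mods, dist)
        up = out[out.module == 0].sort_values("distance").log2_enrichment
        assert np.all(np.diff(up) > 0)

    def test_emt_crossing_pattern_on_fixture(self, sc_fixture):
        """Epithelial module falls and mesenchymal rises with distance from
        chain-start roots, reproducing the crossing pattern."""
        g = plasticity.build_knn_graph(sc_fixture.similarity, k=3)
        mcs = list(sc_fixture.similarity.index)
        dist = plasticity.assign_distances(g, {mcs[0]})
        sigs = sc_fixture.signatures
        mods = plasticity.GeneModuleSet({0: sigs.epithelial, 1: sigs.mesenchymal})
        out = plasticity.module_enrichment_by_distance(
            sc_fixture.expression, mods, dist
        )
        epi = out[out.module == 0].sort_values("distance").log2_enrichment.to_numpy()
        mes = out[out.module == 1].sort_values("distance").log2_enrichment.to_numpy()
        assert epi[0] > epi[-1] and mes[0] < mes[-1]
        # correlation with distance has opposite signs
        d = np.arange(len(epi))
        assert np.corrcoef(d, epi)[0, 1] < -0.7 < 0.7 < np.corrcoef(d, mes)[0, 1]


class TestSignatures:
    SIGS = plasticity.SignatureSet(basal=["b1", "b2"], lp=["l1", "l2"], ml=["m1"])

    def test_ternary_proportions(self):
        umis = pd.Series({"b1": 30, "l1": 30, "m1": 40})
        assert plasticity.signature_ternary(umis, self.SIGS) == pytest.approx((0.3, 0.3, 0.4))

    def test_all_ml(self):
        umis = pd.Series({"m1": 12})
        assert plasticity.signature_ternary(umis, self.SIGS) == (0.0, 0.0, 1.0)

    def test_scaling_invariance(self):
        umis = pd.Series({"b1": 3, "l2": 5, "m1": 2, "other": 100})
        a = plasticity.signature_ternary(umis, self.SIGS)
        b = plasticity.signature_ternary(umis * 7, self.SIGS)
        assert a == pytest.approx(b)
        assert sum(a) == pytest.approx(1.0)

    def test_zero_signature_umis_undefined(self):
        with pytest.raises(ValueError):
            plasticity.signature_ternary(pd.Series({"other": 5}), self.SIGS)

    def test_shared_genes_removed_from_signatures(self):
        sigs = plasticity.SignatureSet(
            basal=["shared", "b"], lp=["shared", "l"], ml=["m"]
        )
        assert "shared" not in sigs.basal and "shared" not in sigs.lp


class TestBimodalThreshold:
    def test_symmetric_mixture_split_near_midpoint(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 3000), rng.normal(0.3, 0.05, 3000)])
        assert plasticity.bimodal_threshold(x) == pytest.approx(0.15, abs=0.02)

    def test_single_gaussian_error(self, rng):
        with pytest.raises(ValueError):
            plasticity.bimodal_threshold(rng.normal(0, 1, 1000))

    def test_translation_equivariance(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 2000), rng.normal(0.4, 0.05, 2000)])
        t0 = plasticity.bimodal_threshold(x)
        t1 = plasticity.bimodal_threshold(x + 1.5)
        assert t1 - t0 == pytest.approx(1.5, abs=0.01)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            plasticity.bimodal_threshold(np.arange(50))


class TestReplicateCorrelation:
    def test_identical_fractions_r2_one(self):
        f = np.array([0.5, 0.3, 0.1, 0.1])
        assert plasticity.replicate_state_correlation(f, f) == pytest.approx(1.0)

    def test_independent_fractions_near_zero(self, rng):
        r2s = [
            plasticity.replicate_state_correlation(rng.random(200), rng.random(200))
            for _ in range(20)
        ]
        assert abs(np.mean(r2s)) < 0.05

    def test_noisy_copy_near_one(self, rng):
        f = rng.random(50)
        g = f + rng.normal(0, 0.01, 50)
        assert plasticity.replicate_state_correlation(f, g) > 0.95

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            out = plasticity.replicate_state_correlation(
                np.ones(5), np.array([1, 2, 3, 4, 5.0])
            )
        assert np.isnan(out)


class TestBreadthAndEntropy:
    def test_clone_in_every_metacell(self):
        rows = [(f"m{i}", "cl", "P", 2) for i in range(10)]
        out = plasticity.clone_state_breadth(membership_from(rows), "cl")
        assert out["fraction"] == 1.0 and out["n_metacells"] == 10

    def test_single_metacell_zero_entropy(self):
        m = membership_from([("m1", "cl", "P", 9), ("m2", "other", "P", 3)])
        out = plasticity.clone_state_breadth(m, "cl")
        assert out["entropy"] == 0.0 and out["fraction"] == 0.5

    def test_absent_clone_zero_breadth(self):
        m = membership_from([("m1", "other", "P", 3)])
        assert plasticity.clone_state_breadth(m, "ghost")["n_metacells"] == 0

    def test_dominant_clone_has_highest_entropy(self, sc_fixture):
        mem = sc_fixture.membership
        dominant = mem.groupby("clone")["cells"].sum().idxmax()
        clones = mem.clone.unique()
        ent = {c: plasticity.clone_state_breadth(mem, c)["entropy"] for c in clones}
        others = [v for c, v in ent.items() if c != dominant]
        assert ent[dominant] > max(others)


class TestPseudobulkDE:
    def groups(self, rng, n=40, genes=60, shift=None):
        lam = rng.uniform(0.5, 4, genes)
        a = pd.DataFrame(rng.poisson(lam * 2, (n, genes)))
        lam_b = lam if shift is None else lam * shift
        b = pd.DataFrame(rng.poisson(lam_b * 2, (n, genes)))
        a.columns = b.columns = [f"g{i}" for i in range(genes)]
        return a, b

    def test_low_expressed_fraction_filtered(self, rng):
        a, b = self.groups(rng)
        # a gene expressed in 49% of enriched-group cells must be excluded
        a["rare"] = 0
        b["rare"] = 0
        n = len(a)
        idx = rng.choice(n, size=int(np.floor(0.49 * n)), replace=False)
        a.loc[a.index[idx], "rare"] = 30  # enriched in A, present in <50%
        out = plasticity.pseudobulk_de(a, b, umi_floor=0, seed=0)
        assert "rare" not in out.index

    def test_low_mean_umi_filtered(self, rng):
        a, b = self.groups(rng)
        a["faint"] = rng.binomial(1, 0.6, len(a))  # ~60% of cells, tiny counts
        b["faint"] = 0
        out = plasticity.pseudobulk_de(a, b, umi_floor=0, min_mean_umi=0.7, seed=0)
        assert "faint" not in out.index

    def test_true_signal_detected(self, rng):
        a, b = self.groups(rng, n=60, shift=1.0)
        b["up"] = rng.poisson(8.0, len(b))
        a["up"] = rng.poisson(2.0, len(a))
        out = plasticity.pseudobulk_de(a, b, umi_floor=0, seed=1)
        assert out.loc["up", "q"] < 0.05
        assert out.loc["up", "enriched_in"] == "B"

    def test_permuted_labels_control_fdr(self, rng):
        hits = []
        for rep in range(20):
            a, b = self.groups(rng, n=30, genes=100)
            out = plasticity.pseudobulk_de(a, b, umi_floor=0, seed=rep)
            hits.append((out.q < 0.05).mean())
        assert np.mean(hits) <= 0.05

    def test_downsampling_equalises_cell_totals(self, rng):
        a, _ = self.groups(rng)
        down = plasticity.downsample_cells(a, 50, seed=0)
        assert (down.sum(axis=1) == 50).all()
        assert (down <= a).all().all()

    def test_empty_group_error(self, rng):
        a, b = self.groups(rng)
        with pytest.raises(ValueError):
            plasticity.pseudobulk_de(a.iloc[:1], b)
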