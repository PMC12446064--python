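import itertools

import numpy as np
import pandas as pd
import pytest

from gepcat.consensus import (
    ConsensusSet,
    CorrelationEdge,
    GEPNode,
    build_graph,
    finalize_catalog,
    greedy_merge,
    membership_report,
    normalize_spectra,
)


def _node(vec, dataset, name, genes=None):
    genes = genes or [f"g{i}" for i in range(len(vec))]
    return GEPNode(pd.Series(np.asarray(vec, float), index=genes), dataset, name)


class TestNormalizeSpectra:
    def test_two_step_arithmetic(self):
        spectra = pd.DataFrame([[2.0, 2.0]], index=["P"], columns=["g0", "g1"])
        sd = pd.Series([1.0, 2.0], index=["g0", "g1"])
        nodes = normalize_spectra(spectra, sd, "ds")
        np.testing.assert_allclose(nodes[0].vector.to_numpy(), [5e5, 2.5e5])

    def test_zero_sd_gene_dropped(self):
        spectra = pd.DataFrame([[1.0, 1.0]], index=["P"], columns=["g0", "g1"])
        sd = pd.Series([1.0, 0.0], index=["g0", "g1"])
        nodes = normalize_spectra(spectra, sd, "ds")
        assert list(nodes[0].vector.index) == ["g0"]

    def test_input_scale_invariance(self):
        sd = pd.Series([1.0, 3.0], index=["g0", "g1"])
        a = normalize_spectra(
            pd.DataFrame([[1.0, 4.0]], index=["P"], columns=["g0", "g1"]), sd, "ds"
        )[0].vector
        b = normalize_spectra(
            pd.DataFrame([[10.0, 40.0]], index=["P"], columns=["g0", "g1"]), sd, "ds"
        )[0].vector
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_all_zero_vector_errors(self):
        spectra = pd.DataFrame([[0.0, 0.0]], index=["P"], columns=["g0", "g1"])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_spectra(spectra, pd.Series([1.0, 1.0], index=["g0", "g1"]), "ds")


class TestBuildGraph:
    def test_identical_cross_dataset_pair_connected(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 40)
        edges = build_graph([_node(v, "d1", "a"), _node(v, "d2", "b")])
        assert len(edges) == 1 and edges[0].r == pytest.approx(1.0)

    def test_same_dataset_pair_never_connected(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, 40)
        edges = build_graph([_node(v, "d1", "a"), _node(v, "d1", "b")])
        assert edges == []

    def test_low_correlation_pair_excluded(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0, 1, 100)  # independent -> r ~ 0
        edges = build_graph([_node(a, "d1", "a"), _node(b, "d2", "b")])
        assert edges == []

    def test_too_few_shared_genes_no_edge(self):
        a = _node([1, 2, 3], "d1", "a", genes=["g0", "g1", "g2"])
        b = _node([1, 2, 3], "d2", "b", genes=["g0", "g1", "g2"])
        assert build_graph([a, b], min_shared_genes=20) == []


def brute_force_edges(nodes, r_min=0.5, top_n=7):
    """Literal restatement of the three edge criteria."""
    n = len(nodes)
    R = np.full((n, n), -np.inf)
    for i, j in itertools.combinations(range(n), 2):
        shared = nodes[i].vector.index.intersection(nodes[j].vector.index)
        a = nodes[i].vector.loc[shared]
        b = nodes[j].vector.loc[shared]
        R[i, j] = R[j, i] = np.corrcoef(a, b)[0, 1]
    edges = set()
    for i, j in itertools.combinations(range(n), 2):
        if nodes[i].dataset_id == nodes[j].dataset_id:
            continue
        if not R[i, j] > r_min:
            continue
        top_i = sorted(range(n), key=lambda q: (-R[i, q], q))
        top_i = [q for q in top_i if q != i][:top_n]
        top_j = sorted(range(n), key=lambda q: (-R[j, q], q))
        top_j = [q for q in top_j if q != j][:top_n]
        if j in top_i and i in top_j:
            edges.add((i, j))
    return edges


def brute_force_merge(n_nodes, edges, connectivity_min=2 / 3, rs=None):
    """Direct restatement of the greedy merge over sorted edges."""
    sets = [{i} for i in range(n_nodes)]
    adj = set(edges)
    order = sorted(edges, key=lambda e: (-rs[e], e))
    for (i, j) in order:
        si = next(s for s in sets if i in s)
        sj = next(s for s in sets if j in s)
        if si is sj:
            continue
        union = si | sj
        pairs = list(itertools.combinations(sorted(union), 2))
        frac = sum(p in adj for p in pairs) / len(pairs)
        if frac >= connectivity_min:
            sets.remove(si)
            sets.remove(sj)
            sets.append(union)
    return {frozenset(s) for s in sets}


class TestGraphOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_ds = rng.integers(2, 4)
        nodes = []
        base = rng.uniform(0, 1, size=(4, 60))
        for d in range(n_ds):
            for m in range(4):
                proto = base[rng.integers(0, 4)]
                noise = rng.uniform(0, 1, 60) * rng.uniform(0.1, 1.5)
                nodes.append(_node(proto + noise, f"d{d}", f"p{m}"))
        edges = build_graph(nodes, min_shared_genes=2)
        got = {(e.i, e.j) for e in edges}
        assert got == brute_force_edges(nodes)
        # merge oracle
        rs = {(e.i, e.j): e.r for e in edges}
        sets = greedy_merge(nodes, edges)
        assert {frozenset(s.members) for s in sets} == brute_force_merge(
            len(nodes), got, rs=rs
        )


class TestGreedyMerge:
    def _chain_nodes(self):
        return [_node([1, 0], "d1", "A"), _node([0, 1], "d2", "B"),
                _node([1, 1], "d3", "C")]

    def test_no_edges_all_singletons(self):
        nodes = self._chain_nodes()
        sets = greedy_merge(nodes, [])
        assert all(s.is_singleton for s in sets) and len(sets) == 3

    def test_chain_merges_at_exact_two_thirds(self):
        # A-B (r .9), B-C (r .8), no A-C: {A,B}+C has 2/3 connected pairs
        nodes = self._chain_nodes()
        edges = [CorrelationEdge(0, 1, 0.9), CorrelationEdge(1, 2, 0.8)]
        sets = greedy_merge(nodes, edges)
        assert len(sets) == 1 and sorted(sets[0].members) == [0, 1, 2]

    def test_star_stops_below_two_thirds(self):
        # star A-B, A-C, A-D: {A,B,C} reaches 2/3, adding D gives 3/6
        nodes = [_node([1, 0], "d1", "A"), _node([0, 1], "d2", "B"),
                 _node([1, 1], "d3", "C"), _node([1, 2], "d4", "D")]
        edges = [CorrelationEdge(0, 1, 0.9), CorrelationEdge(0, 2, 0.8),
                 CorrelationEdge(0, 3, 0.7)]
        sets = greedy_merge(nodes, edges)
        by_size = sorted(sets, key=lambda s: -len(s.members))
        assert sorted(by_size[0].members) == [0, 1, 2]
        assert by_size[1].members == [3]

    def test_partition_and_multi_dataset_support(self):
        rng = np.random.default_rng(9)
        nodes = [_node(rng.uniform(0, 1, 30), f"d{i % 3}", f"p{i}") for i in range(9)]
        edges = build_graph(nodes, min_shared_genes=2)
        sets = greedy_merge(nodes, edges)
        all_members = sorted(m for s in sets for m in s.members)
        assert all_members == list(range(9))
        for s in sets:
            if not s.is_singleton:
                assert len(s.supported_datasets) >= 2


class TestFinalizeCatalog:
    def _setup(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        nodes = [
            _node(rng.uniform(0.1, 1, 10), "d1", "a", genes),
            _node(rng.uniform(0.1, 1, 10), "d2", "b", genes),
            _node(rng.uniform(0.1, 1, 10), "d1", "c", genes),
            _node(rng.uniform(0.1, 1, 10), "d2", "d", genes),
            _node(rng.uniform(0.1, 1, 10), "d1", "e", genes),
        ]
        sets = [
            ConsensusSet([0, 1], {"d1", "d2"}),
            ConsensusSet([2, 3], {"d1", "d2"}),
            ConsensusSet([4], {"d1"}),
        ]
        od = {"d1": genes[:8], "d2": genes[4:]}
        full = {"d1": genes, "d2": genes[:9]}
        return nodes, sets, od, full, genes

    def test_singletons_dropped_by_default(self):
        nodes, sets, od, full, genes = self._setup()
        cat = finalize_catalog(sets, nodes, od, full)
        assert len(cat.program_names) == 2

    def test_mean_of_identical_members_is_member(self):
        nodes, sets, od, full, genes = self._setup()
        nodes[1] = GEPNode(nodes[0].vector.copy(), "d2", "b")
        cat = finalize_catalog(sets[:1], nodes, od, full)
        expected = nodes[0].vector.reindex(cat.gene_ids)
        np.testing.assert_allclose(cat.spectra.iloc[0].to_numpy(), expected.to_numpy())

    def test_universe_intersection_rule(self):
        nodes, sets, od, full, genes = self._setup()
        cat = finalize_catalog(sets, nodes, od, full)
        # g9 is overdispersed in d2 but absent from d2's... rather: g9 is in
        # d1's full list but not d2's full list -> excluded from the universe
        assert "g9" not in cat.gene_ids
        # union of od lists = g0..g9; intersect full lists = g0..g8
        assert set(cat.gene_ids) == {f"g{i}" for i in range(9)}

    def test_retained_singleton_kept_and_unknown_errors(self):
        nodes, sets, od, full, genes = self._setup()
        cat = finalize_catalog(sets, nodes, od, full, retain_singletons=["d1/e"])
        assert len(cat.program_names) == 3
        with pytest.raises(ValueError, match="not found"):
            finalize_catalog(sets, nodes, od, full, retain_singletons=["d9/zz"])

    def test_deterministic_rebuild(self):
        nodes, sets, od, full, genes = self._setup()
        a = finalize_catalog(sets, nodes, od, full)
        b = finalize_catalog(sets, nodes, od, full)
        pd.testing.assert_frame_equal(a.spectra, b.spectra)

    def test_membership_report_shape(self):
        nodes, sets, od, full, genes = self._setup()
        rep = membership_report(sets, nodes, [CorrelationEdge(0, 1, 0.9)])
        assert len(rep) == 3 and rep.loc[0, "mean_r"] == pytest.approx(0.9)
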