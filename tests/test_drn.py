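import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmap import drn
from pmap.errors import ConfigError, DataError
from pmap.drn import (DrnResult, assemble_drn, build_graph, discover_n1,
                      discover_n2, mine_drn, pf_scores)


def brute_force_n1(graph, pdegs, min_links=2):
    """Exhaustive predicate evaluation, independent of the implementation."""
    return {g for g in graph.nodes
            if g not in pdegs
            and len([nb for nb in graph.neighbors(g) if nb in pdegs]) >= min_links}


def brute_force_n2(graph, pdegs, n1, min_links=2, excluded=frozenset({"UBC"})):
    out = set()
    for g in graph.nodes:
        if g in pdegs or g in excluded:
            continue
        nbrs = set(graph.neighbors(g))
        if nbrs & n1 and len(nbrs & pdegs) >= min_links:
            out.add(g)
    return out


def random_graph(rng, n_nodes=50, p=0.12, n_pdegs=8):
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
    nodes = sorted(g.nodes)
    pdegs = set(rng.choice(nodes, size=min(n_pdegs, len(nodes)), replace=False))
    return g, pdegs


class TestDiscoverN1:
    def test_star_graph(self):
        g = build_graph([("h", "A"), ("h", "B"), ("h", "C")])
        n1, registry = discover_n1(g, {"A", "B", "C"})
        assert n1 == {"h"}
        assert registry == [("A", "h"), ("B", "h"), ("C", "h")]

    def test_single_pdeg_neighbor_not_n1(self):
        g = build_graph([("x", "A"), ("x", "y")])
        n1, registry = discover_n1(g, {"A"})
        assert n1 == set()
        assert registry == []

    def test_pdegs_excluded_from_n1(self):
        g = build_graph([("A", "B"), ("A", "C"), ("B", "C")])
        n1, _ = discover_n1(g, {"A", "B", "C"})
        assert n1 == set()

    def test_min_links_config_error(self):
        g = build_graph([("a", "b")])
        with pytest.raises(ConfigError):
            discover_n1(g, {"a"}, min_links=0)

    def test_empty_graph_errors(self):
        with pytest.raises(DataError):
            discover_n1(nx.Graph(), {"a"})

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            g, pdegs = random_graph(rng)
            n1, registry = discover_n1(g, pdegs)
            assert n1 == brute_force_n1(g, pdegs)
            # frequency conservation: sum of N1 frequencies equals M
            freq = {}
            for _, gene in registry:
                freq[gene] = freq.get(gene, 0) + 1
            assert sum(freq.values()) == len(registry)
            assert all(v >= 2 for v in freq.values())


class TestDiscoverN2:
    def test_path_definition(self):
        g = build_graph([("A", "x"), ("x", "g"), ("g", "A"), ("g", "B"),
                         ("x", "B")])
        pdegs = {"A", "B"}
        n1, registry = discover_n1(g, pdegs)
        assert "x" in n1
        n2, freq = discover_n2(g, pdegs, n1, registry=registry)
        assert n2 == {"g"} or "g" in n2

    def test_ubc_excluded(self, caplog):
        g = build_graph([("A", "x"), ("B", "x"), ("UBC", "x"),
                         ("UBC", "A"), ("UBC", "B")])
        pdegs = {"A", "B"}
        n1, registry = discover_n1(g, pdegs)
        with caplog.at_level("INFO"):
            n2, _ = discover_n2(g, pdegs, n1, registry=registry)
        assert "UBC" not in n2
        assert "UBC" in caplog.text

    def test_ubc_may_still_be_n1(self):
        g = build_graph([("UBC", "A"), ("UBC", "B")])
        n1, _ = discover_n1(g, {"A", "B"})
        assert "UBC" in n1

    def test_n2_role_frequency_ties_to_registry_rows(self):
        # g adjacent to pdeg A and n1 x: row (A, x) counts; row (B, x) does not
        g = build_graph([("A", "x"), ("B", "x"), ("g", "x"), ("g", "A"),
                         ("g", "C"), ("C", "x")])
        pdegs = {"A", "B", "C"}
        n1, registry = discover_n1(g, pdegs)
        n2, freq = discover_n2(g, pdegs, n1, registry=registry)
        assert "g" in n2
        # registry rows for x: (A,x),(B,x),(C,x); g adjacent to A and C only
        assert freq["g"] == 2

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            g, pdegs = random_graph(rng)
            n1, registry = discover_n1(g, pdegs)
            n2, _ = discover_n2(g, pdegs, n1, registry=registry)
            assert n2 == brute_force_n2(g, pdegs, n1)


class TestAssembleDrn:
    def test_star_edges(self):
        g = build_graph([("h", "A"), ("h", "B"), ("h", "C")])
        result = mine_drn(g, {"A", "B", "C"}, "c-sensitive")
        assert len(result.edges) == 3
        summary = drn.degree_summary(result)
        assert int(summary.set_index("gene").loc["h", "degree"]) == 3

    def test_empty_pdegs_empty_drn(self):
        g = build_graph([("a", "b"), ("b", "c")])
        result = mine_drn(g, set(), "c-sensitive")
        assert result.n1 == set() and result.n2 == set()
        assert result.edges == []

    def test_planted_pairs_contained(self, small_scenario):
        truth = small_scenario["truth"]
        graph = build_graph(small_scenario["edges"])
        for cls_name, planted_n1 in truth.planted_n1.items():
            result = mine_drn(graph, truth.planted_pdegs[cls_name], cls_name)
            for g in planted_n1:
                assert g in result.n1
                pairs = {(p, n) for p, n in result.pair_registry if n == g}
                assert len(pairs) >= \
                    small_scenario["config"].planted_n1_min_pdeg_links
            edge_set = {(a, b) for a, b, _ in result.edges}
            for p, n in result.pair_registry:
                key = (p, n) if p < n else (n, p)
                assert key in edge_set


def _result(name, freq_n1, freq_n2=None):
    return DrnResult(phenotype_class=name, pdegs_in_graph=set(), n1=set(freq_n1),
                     n2=set(freq_n2 or {}), pair_registry=[],
                     freq_n1=dict(freq_n1), freq_n2=dict(freq_n2 or {}))


class TestPfScores:
    def test_symmetric_frequencies_zero(self):
        s = _result("c-sensitive", {"x": 5})
        r = _result("c-resistant", {"x": 5})
        (rec,) = pf_scores(s, r)
        assert rec.pf_n1 == 0 and rec.pf_sum == 0

    def test_swap_negates(self, rng):
        for _ in range(10):
            genes = [f"g{i}" for i in range(8)]
            f1 = {g: int(rng.integers(0, 9)) for g in genes if rng.random() < .8}
            f2 = {g: int(rng.integers(0, 9)) for g in genes if rng.random() < .8}
            s = _result("c-sensitive", f1)
            r = _result("c-resistant", f2)
            fwd = {x.gene: (x.pf_n1, x.pf_n2, x.pf_sum) for x in pf_scores(s, r)}
            rev = {x.gene: (x.pf_n1, x.pf_n2, x.pf_sum) for x in pf_scores(r, s)}
            assert set(fwd) == set(rev)
            for g in fwd:
                assert fwd[g] == tuple(-v for v in rev[g])

    def test_mismatched_class_errors(self):
        with pytest.raises(DataError):
            pf_scores(_result("a-sensitive", {}), _result("b-resistant", {}))

    def test_sorted_by_pf_sum_then_symbol(self):
        s = _result("c-sensitive", {"b": 3, "a": 3, "z": 9})
        r = _result("c-resistant", {"q": 4})
        recs = pf_scores(s, r)
        assert [x.gene for x in recs] == ["z", "a", "b", "q"]
        assert [x.rank for x in recs] == [1, 2, 3, 4]

    def test_pf_sum_is_component_sum(self, rng):
        g, pdegs = random_graph(rng, n_nodes=40)
        g2, pdegs2 = random_graph(rng, n_nodes=40)
        s = mine_drn(g, pdegs, "c-sensitive")
        r = mine_drn(g2, pdegs2, "c-resistant")
        for rec in pf_scores(s, r):
            assert rec.pf_sum == rec.pf_n1 + rec.pf_n2


class TestMonotonicity:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_new_pdeg_edge_never_decreases_frequency(self, seed):
        rng = np.random.default_rng(seed)
        g, pdegs = random_graph(rng, n_nodes=30, n_pdegs=6)
        n1, registry = discover_n1(g, pdegs)
        if not n1:
            return
        gene = sorted(n1)[0]
        before = sum(1 for _, x in registry if x == gene)
        new_pdeg = "brand_new_pdeg"
        g.add_edge(gene, new_pdeg)
        n1_after, registry_after = discover_n1(g, pdegs | {new_pdeg})
        after = sum(1 for _, x in registry_after if x == gene)
        assert gene in n1_after
        assert after >= before
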