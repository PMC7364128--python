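"""Biclique enumeration, HiSim construction, bootstrap and ranking."""
from itertools import combinations

import numpy as np
import pytest

from qtlconverge.convergence import (
    bootstrap_edge_support,
    bootstrap_hisim,
    build_bipartite,
    build_hisim,
    enumerate_maximal_bicliques,
    rank_candidates,
)
from qtlconverge.errors import CorpusError
from qtlconverge.genesets import GeneSetCorpus
from qtlconverge.simulate import GeneSetCorpusSpec, generate_geneset_corpus

from conftest import make_corpus


def brute_force_bicliques(corpus: GeneSetCorpus, min_sets=2, min_genes=1):
    """Oracle: check every set-side subset for closure and intersection."""
    ids = corpus.set_ids
    members = {s.set_id: set(s.genes) for s in corpus}
    out = set()
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            genes = set.intersection(*(members[s] for s in combo))
            if not genes:
                continue
            closure = {s for s in ids if genes <= members[s]}
            if set(combo) != closure:
                continue  # another set could be added: not maximal
            if len(combo) >= min_sets and len(genes) >= min_genes:
                out.add((frozenset(combo), frozenset(genes)))
    return out


class TestBipartite:
    def test_disjoint_sets_vertex_and_edge_counts(self):
        corpus = make_corpus({"S1": ["a", "b", "c"], "S2": ["d", "e", "f"]})
        g = build_bipartite(corpus)
        assert g.number_of_nodes() == 8
        assert g.number_of_edges() == 6

    def test_restriction_keeps_only_listed_gene_vertices(self):
        spec = GeneSetCorpusSpec(n_genes=1000, planted=(("geneX", 7),), seed=3)
        corpus = generate_geneset_corpus(spec)
        g = build_bipartite(corpus, restrict_to_genes=["geneX"])
        assert g.degree(("gene", "geneX")) == 7
        assert sum(1 for _, d in g.nodes(data=True) if d["kind"] == "gene") == 1

    def test_empty_restriction_leaves_isolated_set_vertices(self, worked_corpus):
        g = build_bipartite(worked_corpus, restrict_to_genes=[])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 0


class TestEnumeration:
    def test_worked_three_set_example(self, worked_corpus):
        found = {(b.sets, b.genes) for b in enumerate_maximal_bicliques(worked_corpus)}
        assert found == {
            (frozenset({"S1", "S2"}), frozenset({"b", "c"})),
            (frozenset({"S1", "S2", "S3"}), frozenset({"c"})),
        }

    def test_complete_membership_gives_single_biclique(self):
        corpus = make_corpus({f"S{i}": ["a", "b"] for i in range(4)})
        found = enumerate_maximal_bicliques(corpus)
        assert len(found) == 1
        assert found[0].sets == frozenset(corpus.set_ids)
        assert found[0].genes == frozenset({"a", "b"})

    def test_disjoint_sets_have_no_shared_bicliques(self):
        corpus = make_corpus({"S1": ["a"], "S2": ["b"], "S3": ["c"]})
        assert enumerate_maximal_bicliques(corpus) == []

    def test_graph_and_corpus_inputs_agree(self, worked_corpus):
        via_graph = enumerate_maximal_bicliques(build_bipartite(worked_corpus))
        via_corpus = enumerate_maximal_bicliques(worked_corpus)
        assert via_graph == via_corpus

    def test_matches_brute_force_oracle_on_random_corpora(self):
        rng = np.random.default_rng(2024)
        for trial in range(200):
            n_sets = int(rng.integers(2, 11))
            n_genes = int(rng.integers(2, 16))
            genes = [f"g{i}" for i in range(n_genes)]
            sets = {}
            for j in range(n_sets):
                size = int(rng.integers(1, n_genes + 1))
                sets[f"S{j}"] = list(rng.choice(genes, size=size, replace=False))
            corpus = make_corpus(sets)
            found = {(b.sets, b.genes) for b in enumerate_maximal_bicliques(corpus)}
            assert found == brute_force_bicliques(corpus), f"trial {trial}"


class TestHiSim:
    def test_worked_example_structure(self, worked_corpus):
        g = build_hisim(worked_corpus)
        assert set(g.graph.nodes) == {"B:S1|S2", "B:S1|S2|S3", "T:S1", "T:S2", "T:S3"}
        assert set(g.graph.edges) == {
            ("B:S1|S2|S3", "B:S1|S2"),
            ("B:S1|S2", "T:S1"),
            ("B:S1|S2", "T:S2"),
            ("B:S1|S2|S3", "T:S3"),
        }

    def test_single_set_corpus_has_one_terminal_no_edges(self):
        g = build_hisim(make_corpus({"S1": ["a", "b"]}))
        assert g.terminals() == ["T:S1"]
        assert g.internal_nodes() == []
        assert g.graph.number_of_edges() == 0

    def test_duplicated_sets_share_one_internal_node(self):
        g = build_hisim(make_corpus({"S1": ["a", "b"], "S2": ["a", "b"]}))
        assert g.internal_nodes() == ["B:S1|S2"]
        assert set(g.graph.edges) == {("B:S1|S2", "T:S1"), ("B:S1|S2", "T:S2")}

    def test_unknown_set_id_rejected(self, worked_corpus):
        bad = enumerate_maximal_bicliques(make_corpus({"X1": ["a"], "X2": ["a"]}))
        with pytest.raises(CorpusError):
            build_hisim(worked_corpus, bad)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_structural_invariants_on_random_corpora(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(25)]
        sets = {
            f"S{j}": list(rng.choice(genes, size=int(rng.integers(2, 12)), replace=False))
            for j in range(12)
        }
        corpus = make_corpus(sets)
        g = build_hisim(corpus)
        assert nx.is_directed_acyclic_graph(g.graph)
        sides = {n: g.set_side(n) for n in g.graph.nodes}
        for u, v in g.graph.edges:
            assert sides[v] < sides[u]  # parent strict superset
            assert g.gene_side(u) <= g.gene_side(v)
            # transitive reduction: no node strictly between parent and child
            for w in g.graph.nodes:
                if w in (u, v):
                    continue
                assert not (sides[v] < sides[w] < sides[u])


class TestBootstrap:
    def test_deterministic_given_seed(self, worked_corpus):
        a = bootstrap_hisim(worked_corpus, iterations=50, seed=4)
        b = bootstrap_hisim(worked_corpus, iterations=50, seed=4)
        assert a == b

    def test_supports_in_unit_interval_and_retained_above_half(self, worked_corpus):
        g = bootstrap_hisim(worked_corpus, iterations=100, retention=0.5, seed=5)
        for _, _, d in g.edges():
            assert 0.0 <= d["support"] <= 1.0
            assert d["support"] > 0.5

    def test_two_identical_sets_support_matches_binomial_enumeration(self):
        # drawing 2 of 2 with replacement: both distinct sets present with
        # probability 1 - 2*(1/2)^2 = 0.5, exactly when the shared internal
        # node and its two terminal edges can be rebuilt
        corpus = make_corpus({"S1": ["a", "b"], "S2": ["a", "b"]})
        support, draws = bootstrap_edge_support(corpus, fraction=1.0, iterations=200, seed=6)
        both = sum(1 for d in draws if len(set(d)) == 2) / len(draws)
        key = (frozenset({"S1", "S2"}), frozenset({"S1"}))
        assert abs(both - 0.5) < 0.07
        assert support[key] == pytest.approx(both, abs=1e-12)

    def test_full_draw_iterations_reproduce_unbootstrapped_edges(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        corpus = make_corpus(
            {f"S{j}": list(rng.choice(genes, size=6, replace=False)) for j in range(5)}
        )
        full = build_hisim(corpus)
        full_keys = {full.edge_key(u, v) for u, v, _ in full.edges()}
        support, draws = bootstrap_edge_support(corpus, fraction=1.0, iterations=100, seed=10)
        all_drawn = [i for i, d in enumerate(draws) if len(set(d)) == len(corpus)]
        assert all_drawn  # with 5 sets some iterations draw everything
        # every full-graph edge must appear at least as often as the
        # all-drawn iterations occur
        rate = len(all_drawn) / len(draws)
        for key in full_keys:
            assert support.get(key, 0.0) >= rate - 1e-12

    def test_raising_retention_never_adds_edges(self, worked_corpus):
        low = bootstrap_hisim(worked_corpus, iterations=100, retention=0.3, seed=11)
        high = bootstrap_hisim(worked_corpus, iterations=100, retention=0.7, seed=11)
        assert set(high.graph.edges) <= set(low.graph.edges)

    def test_single_set_corpus_rejected(self):
        with pytest.raises(CorpusError):
            bootstrap_hisim(make_corpus({"S1": ["a"]}), iterations=10, seed=1)


class TestRanking:
    def test_planted_candidate_ranks_first_with_its_membership_degree(self):
        spec = GeneSetCorpusSpec(
            n_genes=2000, planted=(("geneX", 7),), max_background_membership=4, seed=12
        )
        corpus = generate_geneset_corpus(spec)
        candidates = ["geneX"] + corpus.universe[:30]
        ranking = rank_candidates(corpus, candidates)
        assert ranking.top().gene_id == "geneX"
        assert ranking.top().degree == 7

    def test_absent_candidate_gets_degree_zero_and_last_rank(self, worked_corpus):
        ranking = rank_candidates(worked_corpus, ["c", "ghost"])
        assert ranking.records[-1].gene_id == "ghost"
        assert ranking.records[-1].degree == 0

    def test_deepest_biclique_breaks_degree_ties(self):
        # geneA and geneB both sit in 3 sets, but pruning removed geneB's
        # three-set intersection node, leaving only a pairwise one: the
        # gene still reachable at depth 3 ranks first
        import networkx as nx

        from qtlconverge.convergence import HiSimGraph

        corpus = make_corpus(
            {
                "S1": ["geneA", "x1"],
                "S2": ["geneA", "x2"],
                "S3": ["geneA", "x3"],
                "S4": ["geneB", "y1"],
                "S5": ["geneB", "y2"],
                "S6": ["geneB", "y3"],
            }
        )
        g = nx.DiGraph()
        g.add_node("B:S1|S2|S3", kind="biclique", set_ids=("S1", "S2", "S3"), gene_ids=("geneA",))
        g.add_node("B:S4|S5", kind="biclique", set_ids=("S4", "S5"), gene_ids=("geneB",))
        for t, parent in [("S1", "B:S1|S2|S3"), ("S2", "B:S1|S2|S3"), ("S3", "B:S1|S2|S3"),
                          ("S4", "B:S4|S5"), ("S5", "B:S4|S5")]:
            g.add_node(f"T:{t}", kind="terminal", set_ids=(t,), gene_ids=tuple(corpus[t].genes))
            g.add_edge(parent, f"T:{t}", support=1.0)
        pruned = HiSimGraph(g)
        ranking = rank_candidates(corpus, ["geneB", "geneA"], pruned)
        assert [r.gene_id for r in ranking] == ["geneA", "geneB"]
        assert ranking.records[0].degree == ranking.records[1].degree == 3
        assert ranking.records[0].deepest_biclique_sets == 3
        assert ranking.records[1].deepest_biclique_sets == 2

    def test_empty_candidates_rejected(self, worked_corpus):
        with pytest.raises(CorpusError):
            rank_candidates(worked_corpus, [])

    def test_planted_recovery_over_many_corpora(self):
        hits = 0
        for seed in range(50):
            spec = GeneSetCorpusSpec(
                n_genes=2000,
                planted=(("geneX", 7),),
                max_background_membership=4,
                seed=3000 + seed,
            )
            corpus = generate_geneset_corpus(spec)
            candidates = ["geneX"] + corpus.universe[:50]
            if rank_candidates(corpus, candidates).top().gene_id == "geneX":
                hits += 1
        assert hits >= 48
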