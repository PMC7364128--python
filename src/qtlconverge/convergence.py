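"""Convergent prioritization of candidate genes over a gene-set corpus.

The corpus is viewed as a bipartite membership graph (genes on one side,
gene sets on the other).  Every maximal biclique of this graph is a
maximal group of gene sets together with the full intersection of their
gene lists; arranging bicliques by set-side containment yields the
hierarchical-similarity (HiSim) graph, in which each terminal node is an
input gene set, each internal node a biclique, and parent nodes carry
strictly larger set sides (more sets, fewer shared genes) than their
children.  Edges are pruned by bootstrap resampling of the corpus, and
positional candidates are ranked by their degree of connectivity: the
number of corpus sets that contain them, with the deepest biclique
(largest retained set side containing the gene) breaking ties.

Enumeration is a depth-first search over the set side with gene-side
intersection pruning and canonical-closure (duplicate-elimination)
checks; set and gene memberships are held as integer bitmasks, so each
extension and closure is a handful of word-wide AND operations.
"""
from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import CorpusError
from .genesets import GeneSet, GeneSetCorpus

__all__ = [
    "Biclique",
    "HiSimGraph",
    "CandidateRanking",
    "build_bipartite",
    "enumerate_maximal_bicliques",
    "build_hisim",
    "bootstrap_hisim",
    "bootstrap_edge_support",
    "rank_candidates",
]


@dataclass(frozen=True)
class Biclique:
    """A maximal gene-gene-set biclique: every listed gene is a member of
    every listed set, and neither side can be extended."""

    sets: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise CorpusError("biclique gene side must be non-empty")
        if not self.sets:
            raise CorpusError("biclique set side must be non-empty")

    def sorted_sets(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))

    def sorted_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))


@dataclass(frozen=True)
class RankedCandidate:
    gene_id: str
    degree: int
    supporting_sets: tuple[str, ...]
    deepest_biclique_sets: int


class CandidateRanking:
    """Candidates ordered by degree of connectivity (descending)."""

    def __init__(self, records: Sequence[RankedCandidate]):
        self.records = list(records)

    def top(self) -> RankedCandidate:
        if not self.records:
            raise CorpusError("empty ranking")
        return self.records[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": [r.gene_id for r in self.records],
                "degree": [r.degree for r in self.records],
                "supporting_sets": ["|".join(r.supporting_sets) for r in self.records],
                "deepest_biclique_sets": [r.deepest_biclique_sets for r in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# bipartite graph

SET_KIND = "set"
GENE_KIND = "gene"


def build_bipartite(corpus: GeneSetCorpus, restrict_to_genes: Iterable[str] | None = None):
    """Bipartite membership graph: one vertex per set, one per gene.

    Nodes are ``("set", id)`` / ``("gene", id)`` tuples so that gene and
    set namespaces cannot collide.  When ``restrict_to_genes`` is given,
    only those gene vertices (and their membership edges) are created;
    sets emptied by the restriction remain as isolated set vertices.
    """
    if len(corpus) == 0:
        raise CorpusError("corpus must be non-empty")
    allowed = None if restrict_to_genes is None else set(restrict_to_genes)
    g = nx.Graph()
    for s in corpus:
        g.add_node((SET_KIND, s.set_id), kind=SET_KIND, bipartite=0)
    genes: dict[str, None] = {}
    for s in corpus:
        for gene in s.genes:
            if allowed is not None and gene not in allowed:
                continue
            genes.setdefault(gene, None)
    for gene in genes:
        g.add_node((GENE_KIND, gene), kind=GENE_KIND, bipartite=1)
    for s in corpus:
        for gene in s.genes:
            if allowed is not None and gene not in allowed:
                continue
            g.add_edge((SET_KIND, s.set_id), (GENE_KIND, gene))
    return g


def _graph_to_membership(graph) -> tuple[list[str], list[str], list[set[str]]]:
    set_ids = sorted(n[1] for n, d in graph.nodes(data=True) if d.get("kind") == SET_KIND)
    gene_ids = sorted(n[1] for n, d in graph.nodes(data=True) if d.get("kind") == GENE_KIND)
    members = []
    for sid in set_ids:
        members.append({v[1] for v in graph.neighbors((SET_KIND, sid))})
    return set_ids, gene_ids, members


class _CorpusIndex:
    """Bitmask index of a corpus: genes over set bits, sets over gene bits."""

    def __init__(self, set_ids: Sequence[str], gene_lists: Sequence[Iterable[str]]):
        self.set_ids = list(set_ids)
        genes: dict[str, None] = {}
        for lst in gene_lists:
            for g in lst:
                genes.setdefault(g, None)
        self.gene_ids = sorted(genes)
        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self.n_sets = len(self.set_ids)
        self.n_genes = len(self.gene_ids)
        self.set_members = []  # per set: int bitmask over genes
        self.gene_sets = [0] * self.n_genes  # per gene: int bitmask over sets
        for s, lst in enumerate(gene_lists):
            mask = 0
            for g in lst:
                i = gene_pos[g]
                mask |= 1 << i
                self.gene_sets[i] |= 1 << s
            self.set_members.append(mask)

    @classmethod
    def from_corpus(cls, corpus: GeneSetCorpus, restrict: set[str] | None = None):
        lists = []
        for s in corpus:
            genes = s.genes if restrict is None else [g for g in s.genes if g in restrict]
            lists.append(genes)
        return cls(corpus.set_ids, lists)

    def set_mask_ids(self, mask: int) -> frozenset[str]:
        return frozenset(self.set_ids[i] for i in _bits(mask))

    def gene_mask_ids(self, mask: int) -> frozenset[str]:
        return frozenset(self.gene_ids[i] for i in _bits(mask))


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _enumerate_masks(index: _CorpusIndex, min_sets: int, min_genes: int):
    """All maximal bicliques as (set mask, gene mask) pairs.

    Depth-first enumeration of closed set sides: each recursion extends
    the current biclique with one additional set, intersects the gene
    side, and closes the set side (adds every set containing the reduced
    gene side).  A closure that pulls in a set below the extension point
    has already been visited and is pruned (canonical-parent check).
    """
    results: list[tuple[int, int]] = []
    if index.n_genes == 0 or index.n_sets == 0:
        return results
    all_genes = (1 << index.n_genes) - 1
    gene_sets = index.gene_sets
    set_members = index.set_members
    all_sets_mask = (1 << index.n_sets) - 1

    def closure(gmask: int) -> int:
        cl = all_sets_mask
        for i in _bits(gmask):
            cl &= gene_sets[i]
        return cl

    def candidates(tmask: int, gmask: int, at_root: bool) -> int:
        if at_root:
            return all_sets_mask & ~tmask
        cand = 0
        for i in _bits(gmask):
            cand |= gene_sets[i]
        return cand & ~tmask

    def dfs(tmask: int, gmask: int, start: int, at_root: bool):
        if tmask.bit_count() >= min_sets and gmask.bit_count() >= min_genes:
            results.append((tmask, gmask))
        cand = candidates(tmask, gmask, at_root)
        cand &= ~((1 << start) - 1)
        for s in _bits(cand):
            g2 = gmask & set_members[s]
            if g2 == 0 or g2.bit_count() < min_genes:
                continue
            t2 = closure(g2)
            if t2 & ~tmask & ((1 << s) - 1):
                continue  # non-canonical: a smaller-index set joins the closure
            dfs(t2, g2, s + 1, False)

    root = closure(all_genes)
    dfs(root, all_genes, 0, True)
    return results


def enumerate_maximal_bicliques(
    graph_or_corpus,
    min_sets: int = 2,
    min_genes: int = 1,
) -> list[Biclique]:
    """Enumerate every maximal biclique of the membership graph.

    Accepts the bipartite graph from :func:`build_bipartite` or a
    :class:`GeneSetCorpus` directly.  Results are exactly the maximal
    bicliques whose sides meet the size floors, each reported once,
    canonically sorted by set side.
    """
    if isinstance(graph_or_corpus, GeneSetCorpus):
        index = _CorpusIndex.from_corpus(graph_or_corpus)
    else:
        set_ids, _, members = _graph_to_membership(graph_or_corpus)
        index = _CorpusIndex(set_ids, members)
    out = [
        Biclique(sets=index.set_mask_ids(t), genes=index.gene_mask_ids(g))
        for t, g in _enumerate_masks(index, min_sets, min_genes)
    ]
    out.sort(key=lambda b: (b.sorted_sets(), b.sorted_genes()))
    return out


# ---------------------------------------------------------------------------
# HiSim graph

TERMINAL = "terminal"
INTERNAL = "biclique"


def _terminal_id(set_id: str) -> str:
    return f"T:{set_id}"


def _internal_id(sets: Iterable[str]) -> str:
    return "B:" + "|".join(sorted(sets))


class HiSimGraph:
    """Hierarchical-similarity graph over gene sets and their bicliques.

    Wraps a :class:`networkx.DiGraph`.  Node attributes: ``kind``
    (terminal or biclique), ``set_ids`` and ``gene_ids`` (sorted tuples),
    ``contains_candidate`` / ``candidate_ids`` after annotation.  Edge
    attribute ``support`` is the bootstrap support in [0, 1] (1.0 before
    bootstrapping).  Edges run from parents (larger set side) to children.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- accessors ---------------------------------------------------------
    def terminals(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == TERMINAL)

    def internal_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == INTERNAL)

    def set_side(self, node: str) -> frozenset[str]:
        return frozenset(self.graph.nodes[node]["set_ids"])

    def gene_side(self, node: str) -> frozenset[str]:
        return frozenset(self.graph.nodes[node]["gene_ids"])

    def edges(self):
        return self.graph.edges(data=True)

    def edge_key(self, parent: str, child: str) -> tuple[frozenset[str], frozenset[str]]:
        return (self.set_side(parent), self.set_side(child))

    def annotate_candidates(self, candidates: Iterable[str]) -> None:
        cand = set(candidates)
        for node in self.graph.nodes:
            hit = sorted(cand & set(self.graph.nodes[node]["gene_ids"]))
            self.graph.nodes[node]["contains_candidate"] = bool(hit)
            self.graph.nodes[node]["candidate_ids"] = tuple(hit)

    def _canonical(self):
        nodes = {
            n: (
                d["kind"],
                tuple(d["set_ids"]),
                tuple(d["gene_ids"]),
                bool(d.get("contains_candidate", False)),
                tuple(d.get("candidate_ids", ())),
            )
            for n, d in self.graph.nodes(data=True)
        }
        edges = {(u, v): float(d.get("support", 1.0)) for u, v, d in self.graph.edges(data=True)}
        return nodes, edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, HiSimGraph):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __repr__(self) -> str:
        g = self.graph
        return f"HiSimGraph({g.number_of_nodes()} nodes, {g.number_of_edges()} edges)"


def _hisim_structure(index: _CorpusIndex, biclique_masks: list[tuple[int, int]]):
    """Immediate-cover (Hasse) edges among bicliques and terminals.

    Returns ``(internal_nodes, edges)`` where edges are (parent_tmask,
    child_tmask_or_terminal_index) pairs expressed over set masks.
    Parents are found through an inverted index keyed by one member set,
    so the cost is proportional to local overlap rather than the square
    of the node count.
    """
    internal = sorted(biclique_masks, key=lambda tg: (tg[0].bit_count(), tg[0]))
    by_set: dict[int, list[int]] = {}
    for idx, (tmask, _) in enumerate(internal):
        for s in _bits(tmask):
            by_set.setdefault(s, []).append(idx)

    def minimal_strict_supersets(tmask: int) -> list[int]:
        pivot = None
        for s in _bits(tmask):
            lst = by_set.get(s, [])
            if pivot is None or len(lst) < len(pivot):
                pivot = lst
        if pivot is None:
            return []
        sups = [
            i
            for i in pivot
            if internal[i][0] != tmask and internal[i][0] & tmask == tmask
        ]
        sups.sort(key=lambda i: internal[i][0].bit_count())
        minimal: list[int] = []
        for i in sups:
            ti = internal[i][0]
            if any(ti & internal[k][0] == internal[k][0] for k in minimal):
                continue  # a kept superset lies strictly between
            minimal.append(i)
        return minimal

    edges: list[tuple[int, int | None, int]] = []
    # internal -> internal covers
    for idx, (tmask, _) in enumerate(internal):
        for parent in minimal_strict_supersets(tmask):
            edges.append((parent, None, idx))
    # terminals hang below the minimal internal nodes containing them
    for s in range(index.n_sets):
        for parent in minimal_strict_supersets(1 << s):
            edges.append((parent, s, -1))
    return internal, edges


def build_hisim(corpus: GeneSetCorpus, bicliques: Sequence[Biclique] | None = None) -> HiSimGraph:
    """Assemble the HiSim graph from a corpus and its maximal bicliques.

    Terminals are created for every input set; internal nodes for every
    biclique (set side >= 2).  A parent-child edge is drawn exactly when
    the child's set side is strictly contained in the parent's with no
    other node's set side strictly between (immediate-cover reduction).
    When ``bicliques`` is omitted they are enumerated from the corpus.
    """
    if bicliques is None:
        bicliques = enumerate_maximal_bicliques(corpus)
    known = set(corpus.set_ids)
    for b in bicliques:
        unknown = b.sets - known
        if unknown:
            raise CorpusError(f"biclique references unknown set ids {sorted(unknown)}")

    index = _CorpusIndex.from_corpus(corpus)
    pos = {sid: i for i, sid in enumerate(index.set_ids)}
    gene_pos = {g: i for i, g in enumerate(index.gene_ids)}
    masks = []
    for b in bicliques:
        tmask = 0
        for sid in b.sets:
            tmask |= 1 << pos[sid]
        gmask = 0
        for g in b.genes:
            if g in gene_pos:
                gmask |= 1 << gene_pos[g]
        masks.append((tmask, gmask))

    internal, edges = _hisim_structure(index, masks)
    g = nx.DiGraph()
    for s in corpus:
        g.add_node(
            _terminal_id(s.set_id),
            kind=TERMINAL,
            set_ids=(s.set_id,),
            gene_ids=tuple(sorted(s.genes)),
        )
    node_ids = []
    for tmask, gmask in internal:
        sids = tuple(sorted(index.set_mask_ids(tmask)))
        nid = _internal_id(sids)
        node_ids.append(nid)
        g.add_node(
            nid,
            kind=INTERNAL,
            set_ids=sids,
            gene_ids=tuple(sorted(index.gene_mask_ids(gmask))),
        )
    for parent, terminal_set, child in edges:
        u = node_ids[parent]
        v = _terminal_id(index.set_ids[terminal_set]) if terminal_set is not None else node_ids[child]
        g.add_edge(u, v, support=1.0)
    return HiSimGraph(g)


# ---------------------------------------------------------------------------
# bootstrap pruning


def _resample_set_ids(corpus: GeneSetCorpus, fraction: float, rng, mode: str) -> list[str]:
    k = len(corpus)
    ids = corpus.set_ids
    if mode == "round":
        draw = int(round(fraction * k))
        if draw < 1:
            raise CorpusError("resample fraction yields fewer than one set")
        picks = rng.integers(0, k, size=draw)
    elif mode == "keep_fraction":
        picks = rng.integers(0, k, size=k)[: max(int(round(fraction * k)), 1)]
    else:
        raise CorpusError(f"unknown resample mode {mode!r}")
    chosen = sorted(set(int(i) for i in picks))
    return [ids[i] for i in chosen]


def _edge_keys_for_corpus(corpus: GeneSetCorpus) -> set[tuple[frozenset[str], frozenset[str]]]:
    """Parent-child relations of the HiSim graph of ``corpus``, keyed by
    the frozen pair of set-side id collections."""
    index = _CorpusIndex.from_corpus(corpus)
    masks = _enumerate_masks(index, min_sets=2, min_genes=1)
    internal, edges = _hisim_structure(index, masks)
    keys = set()
    for parent, terminal_set, child in edges:
        psets = index.set_mask_ids(internal[parent][0])
        csets = (
            frozenset({index.set_ids[terminal_set]})
            if terminal_set is not None
            else index.set_mask_ids(internal[child][0])
        )
        keys.add((psets, csets))
    return keys


def bootstrap_edge_support(
    corpus: GeneSetCorpus,
    fraction: float = 0.75,
    iterations: int = 1000,
    seed: int = 0,
    resample_mode: str = "round",
):
    """Per-edge bootstrap support of the HiSim parent-child relations.

    Each iteration draws ``round(fraction * K)`` sets with replacement,
    deduplicates, rebuilds the HiSim graph of the resampled corpus, and
    records which parent-child relations appear (keyed by the pair of
    set-side id collections, so structurally identical relations are
    counted together even when resampled gene sides differ).  Returns
    ``(support, draws)``: a dict mapping edge keys to occurrence
    fractions over all iterations, and the per-iteration drawn set ids.
    """
    if not 0 < fraction <= 1:
        raise CorpusError("fraction must lie in (0, 1]")
    if len(corpus) < 2:
        raise CorpusError("bootstrap needs a corpus with at least 2 sets")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[frozenset[str], frozenset[str]], int] = {}
    draws: list[tuple[str, ...]] = []
    for _ in range(iterations):
        chosen = _resample_set_ids(corpus, fraction, rng, resample_mode)
        draws.append(tuple(chosen))
        if len(chosen) < 2:
            continue
        sub = corpus.subset(chosen)
        for key in _edge_keys_for_corpus(sub):
            counts[key] = counts.get(key, 0) + 1
    support = {key: c / iterations for key, c in counts.items()}
    return support, draws


def bootstrap_hisim(
    corpus: GeneSetCorpus,
    fraction: float = 0.75,
    iterations: int = 1000,
    retention: float = 0.5,
    seed: int = 0,
    resample_mode: str = "round",
) -> HiSimGraph:
    """HiSim graph with bootstrap-pruned edges.

    The full-corpus graph is built, each edge is annotated with its
    bootstrap support (fraction of resampled reconstructions in which
    the same parent-child relation reappears, counted over all
    iterations), and edges with support <= ``retention`` are removed.
    Internal nodes left without any retained edge are dropped (they are
    no longer part of the retained hierarchy); terminals are always
    kept, since they represent the input sets themselves.
    """
    if not 0 <= retention < 1:
        raise CorpusError("retention must lie in [0, 1)")
    support, _ = bootstrap_edge_support(
        corpus, fraction=fraction, iterations=iterations, seed=seed, resample_mode=resample_mode
    )
    full = build_hisim(corpus)
    g = full.graph
    for u, v in list(g.edges):
        key = full.edge_key(u, v)
        s = support.get(key, 0.0)
        if s > retention:
            g.edges[u, v]["support"] = s
        else:
            g.remove_edge(u, v)
    for node in list(g.nodes):
        if g.nodes[node]["kind"] == INTERNAL and g.degree(node) == 0:
            g.remove_node(node)
    return full


# ---------------------------------------------------------------------------
# candidate ranking


def rank_candidates(
    corpus: GeneSetCorpus,
    candidates: Iterable[str],
    graph: HiSimGraph | None = None,
) -> CandidateRanking:
    """Rank positional candidates by degree of connectivity.

    Degree is the number of distinct corpus sets containing the gene;
    ties break on the deepest biclique (largest set side over internal
    nodes of ``graph`` whose gene side contains the gene; 0 if none or
    no graph given), then on gene id.  Candidates absent from the corpus
    get degree 0 and sink to the bottom.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise CorpusError("candidates must be non-empty")
    membership: dict[str, list[str]] = {c: [] for c in candidates}
    for s in corpus:
        genes = set(s.genes)
        for c in candidates:
            if c in genes:
                membership[c].append(s.set_id)

    deepest = {c: 0 for c in candidates}
    if graph is not None:
        for node in graph.internal_nodes():
            side = len(graph.set_side(node))
            genes = graph.gene_side(node)
            for c in candidates:
                if c in genes and side > deepest[c]:
                    deepest[c] = side

    records = [
        RankedCandidate(
            gene_id=c,
            degree=len(membership[c]),
            supporting_sets=tuple(sorted(membership[c])),
            deepest_biclique_sets=deepest[c],
        )
        for c in candidates
    ]
    records.sort(key=lambda r: (-r.degree, -r.deepest_biclique_sets, r.gene_id))
    return CandidateRanking(records)
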