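"""Embedded-quartet decomposition and plurality supertree assembly.

Every 4-taxon subset of the union taxon set is scored across gene trees:
each tree containing all four taxa votes for the induced pairing (or
abstains when unresolved).  The plurality topology per subset, weighted by
its margin over the runner-up, constrains the supertree.  The supertree
itself maximises the summed margin of satisfied plurality quartets —
exactly, by enumerating all unrooted topologies, for up to 8 taxa; a
quartet-joining agglomeration polished by NNI hill climbing covers larger
taxon sets and must agree with the exact search on small fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from rnol.tree import (
    PhyloTree,
    QuartetTopology,
    write_newick,
    _quartet_from_bipartitions,
)
from rnol.reconstruct import enumerate_unrooted_topologies, ML_MAX_TAXA

__all__ = [
    "QuartetTally",
    "embedded_quartet_tally",
    "plurality_quartet_map",
    "supertree_search",
    "quartet_topology_code",
]

UNRESOLVED = 3
TOPOLOGY_CODES = ("12|34", "13|24", "14|23", "U")


def quartet_topology_code(qt: QuartetTopology) -> int:
    """Code of a quartet topology relative to its sorted taxa.

    For sorted taxa (t1, t2, t3, t4): 0 = t1t2|t3t4, 1 = t1t3|t2t4,
    2 = t1t4|t2t3, 3 = unresolved.
    """
    if not qt.is_resolved:
        return UNRESOLVED
    t1, t2, t3, t4 = sorted(qt.taxa)
    for code, pair in enumerate(((t1, t2), (t1, t3), (t1, t4))):
        if frozenset(pair) in qt.pairs:
            return code
    raise AssertionError("unreachable")


@dataclass
class QuartetTally:
    """Per-4-subset topology weights aggregated across gene trees.

    ``counts[subset]`` is a length-4 float vector: weights of the three
    resolved pairings (codes 0..2 relative to the sorted subset) plus the
    unresolved count.
    """

    counts: Dict[Tuple[str, str, str, str], np.ndarray] = field(default_factory=dict)

    def add(self, subset: Tuple[str, ...], code: int, weight: float = 1.0) -> None:
        subset = tuple(sorted(subset))
        if subset not in self.counts:
            self.counts[subset] = np.zeros(4)
        if weight < 0:
            raise ValueError("quartet weight must be >= 0")
        self.counts[subset][code] += weight

    def total(self, subset: Tuple[str, ...]) -> float:
        return float(self.counts[tuple(sorted(subset))].sum())

    @property
    def taxa(self) -> frozenset:
        out = set()
        for subset in self.counts:
            out.update(subset)
        return frozenset(out)

    def to_tsv(self) -> str:
        lines = ["taxon1\ttaxon2\ttaxon3\ttaxon4\ttopology\tweight"]
        for subset in sorted(self.counts):
            for code, w in enumerate(self.counts[subset]):
                if w:
                    lines.append("\t".join(subset) + "\t%s\t%.10g"
                                 % (TOPOLOGY_CODES[code], w))
        return "\n".join(lines) + "\n"


def embedded_quartet_tally(gene_trees: Sequence[PhyloTree]) -> QuartetTally:
    """Tally the embedded quartets of every gene tree.

    Trees may have different, overlapping taxon sets; each tree votes on
    every 4-subset it fully contains.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    tally = QuartetTally()
    union = sorted(set().union(*(t.taxa for t in gene_trees)))
    for subset in itertools.combinations(union, 4):
        sset = frozenset(subset)
        for tree in gene_trees:
            if not sset <= tree.taxa:
                continue
            qt = _quartet_from_bipartitions(tree.bipartitions(), sset)
            tally.add(subset, quartet_topology_code(qt))
    return tally


def plurality_quartet_map(tally: QuartetTally) -> Dict[tuple, Tuple[int, float]]:
    """Winner and margin per subset; exact ties are dropped (undecided)."""
    if not tally.counts:
        raise ValueError("empty tally")
    pmap = {}
    for subset, w in tally.counts.items():
        resolved = w[:3]
        order = np.argsort(resolved)[::-1]
        top, runner = resolved[order[0]], resolved[order[1]]
        if top == 0 or top == runner:
            continue  # unresolved everywhere, or tied: no constraint
        pmap[subset] = (int(order[0]), float(top - runner))
    return pmap


# ---------------------------------------------------------------------------
# supertree search
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _topology_library(taxa: Tuple[str, ...]):
    """All unrooted topologies on ``taxa`` with their quartet code tables,
    sorted by canonical newick (the tie-break order)."""
    lib = []
    for tree in enumerate_unrooted_topologies(list(taxa)):
        codes = {}
        bps = tree.bipartitions()
        for subset in itertools.combinations(sorted(taxa), 4):
            qt = _quartet_from_bipartitions(bps, frozenset(subset))
            codes[subset] = quartet_topology_code(qt)
        lib.append((write_newick(tree), tree, codes))
    lib.sort(key=lambda item: item[0])
    return tuple(lib)


def _score_codes(codes: Dict[tuple, int], pmap: Dict[tuple, Tuple[int, float]]) -> float:
    return sum(margin for subset, (code, margin) in pmap.items()
               if codes.get(subset) == code)


def score_tree(tree: PhyloTree, pmap: Dict[tuple, Tuple[int, float]]) -> float:
    """Summed margin of plurality quartets satisfied by ``tree``."""
    bps = tree.bipartitions()
    total = 0.0
    for subset, (code, margin) in pmap.items():
        qt = _quartet_from_bipartitions(bps, frozenset(subset))
        if quartet_topology_code(qt) == code:
            total += margin
    return total


def supertree_search(pmap: Dict[tuple, Tuple[int, float]],
                     mode: str = "exhaustive",
                     min_margin: float = 0.0,
                     taxa: Optional[Iterable[str]] = None) -> PhyloTree:
    """Margin-weighted plurality supertree.

    ``mode='exhaustive'`` enumerates every unrooted topology (<= 8 taxa) and
    returns the maximum-score tree, ties broken by canonical newick order.
    ``mode='greedy'`` runs quartet-joining agglomeration followed by NNI
    hill climbing under the same score.  ``min_margin`` discards weakly
    decided subsets before the search.  ``taxa`` fixes the supertree leaf
    set explicitly (taxa whose every subset is undecided would otherwise
    drop out of the map and the tree).
    """
    if not pmap and taxa is None:
        raise ValueError("empty plurality map")
    if min_margin > 0:
        pmap = {s: v for s, v in pmap.items() if v[1] >= min_margin}
        if not pmap and taxa is None:
            raise ValueError("no quartets above the margin threshold")
    if taxa is None:
        taxa = tuple(sorted(set().union(*map(frozenset, pmap))))
    else:
        taxa = tuple(sorted(taxa))
    if mode == "exhaustive":
        if len(taxa) > ML_MAX_TAXA:
            raise ValueError("exhaustive search limited to %d taxa; use greedy"
                             % ML_MAX_TAXA)
        best = None
        for newick, tree, codes in _topology_library(taxa):
            s = _score_codes(codes, pmap)
            if best is None or s > best[0]:
                best = (s, tree)
        return best[1]
    if mode == "greedy":
        start = _quartet_joining(pmap, taxa)
        return _nni_hill_climb(start, pmap)
    raise ValueError("unknown mode %r" % mode)


def _quartet_joining(pmap, taxa) -> PhyloTree:
    """Agglomerate the pair of clusters with the highest net cherry support."""
    clusters = [(t,) for t in taxa]  # each cluster: tuple of member taxa
    subtrees = {c: c[0] for c in clusters}  # nested-tuple representation

    def cherry_score(X, Y):
        others = [c for c in clusters if c is not X and c is not Y]
        s = 0.0
        for U, V in itertools.combinations(others, 2):
            for x, y, c, d in itertools.product(X, Y, U, V):
                subset = tuple(sorted((x, y, c, d)))
                got = pmap.get(subset)
                if got is None:
                    continue
                code, margin = got
                ordered = sorted((x, y, c, d))
                pair_code = None
                for k, pair in enumerate(((ordered[0], ordered[1]),
                                          (ordered[0], ordered[2]),
                                          (ordered[0], ordered[3]))):
                    if frozenset(pair) == frozenset((x, y)) or \
                       frozenset(pair) == frozenset((c, d)):
                        pair_code = k
                        break
                if pair_code == code:
                    s += margin
                else:
                    s -= margin
        return s

    while len(clusters) > 3:
        best = None
        for X, Y in itertools.combinations(clusters, 2):
            s = cherry_score(X, Y)
            key = (-s, min(X), min(Y))
            if best is None or key < best[0]:
                best = (key, X, Y)
        _, X, Y = best
        merged = tuple(sorted(X + Y))
        sub = (subtrees[X], subtrees[Y])
        clusters = [c for c in clusters if c is not X and c is not Y] + [merged]
        subtrees.pop(X), subtrees.pop(Y)
        subtrees[merged] = sub
    nested = tuple(subtrees[c] for c in clusters)
    return PhyloTree.from_nested(nested, rooted=False)


def _nni_neighbors(tree: PhyloTree):
    g = tree.graph
    internal_edges = [(u, v) for u, v in g.edges
                      if g.degree(u) > 1 and g.degree(v) > 1]
    for u, v in internal_edges:
        a, b = [x for x in g.neighbors(u) if x != v][:2]
        cs = [x for x in g.neighbors(v) if x != u]
        for c in cs:
            for swap in ((b, c),):
                h = g.copy()
                h.remove_edge(u, swap[0])
                h.remove_edge(v, swap[1])
                h.add_edge(u, swap[1])
                h.add_edge(v, swap[0])
                if nx.is_tree(h):
                    yield PhyloTree(h, tree.root, rooted=False)


def _nni_hill_climb(tree: PhyloTree, pmap) -> PhyloTree:
    cur = tree
    cur_key = (-score_tree(cur, pmap), write_newick(cur))
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(cur):
            key = (-score_tree(nb, pmap), write_newick(nb))
            if key < cur_key:
                cur, cur_key = nb, key
                improved = True
                break
    return cur
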