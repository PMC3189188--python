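"""Rooted scaffold construction and reticulated-network assembly.

The scaffold is a rooted tree inferred from concatenated (possibly mixed
protein/nucleotide) partitions by distance methods, rooted on an outgroup.
Gene-family trees are then superimposed: where a gene tree disagrees with
the scaffold, the maximum agreement subset pins down the displaced taxa and
each maximal displaced clade becomes a candidate reticulation, a directed
edge from the clade's gene-tree neighbourhood (the putative donor lineage)
to its scaffold position.  Candidates recurring across enough families are
kept; deleting all reticulation edges always returns the bare scaffold.

Scaffold edges carry stable post-order ids so attachments are reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from rnol.reconstruct import (
    DistanceMatrix,
    exhaustive_ml_tree,
    k2p_distance_matrix,
    neighbor_joining,
    protein_distance_matrix,
)
from rnol.simulate import Alignment
from rnol.tree import (
    Bipartition,
    PhyloTree,
    are_compatible,
    maximum_agreement_subset,
    restrict_to_taxa,
    robinson_foulds,
    write_newick,
)

__all__ = [
    "Reticulation",
    "ReticulatedNetwork",
    "build_scaffold",
    "root_on_outgroup",
    "detect_reticulations",
    "assemble_network",
    "write_network",
    "read_network_tsv",
    "scaffold_edges",
]

logger = logging.getLogger("rnol.network")

DEFAULT_MIN_FAMILY_SUPPORT = 5


@dataclass(frozen=True)
class Reticulation:
    """A directed transfer edge between two scaffold edges."""

    source_edge: int
    target_edge: int
    moved: frozenset
    evidence: tuple = ()  # (family_id, max_support) pairs

    def merge_key(self):
        return (self.source_edge, self.target_edge, self.moved)


@dataclass
class ReticulatedNetwork:
    scaffold: PhyloTree
    reticulations: List[Reticulation] = field(default_factory=list)

    def __post_init__(self):
        if not self.scaffold.rooted:
            raise ValueError("scaffold must be rooted")
        leaves = self.scaffold.taxa
        edge_ids = set(scaffold_edges(self.scaffold))
        for r in self.reticulations:
            if not r.moved or not r.moved <= leaves:
                raise ValueError("moved taxa %s not within the scaffold"
                                 % sorted(r.moved))
            if r.source_edge not in edge_ids or r.target_edge not in edge_ids:
                raise ValueError("reticulation references unknown scaffold edge")

    def __eq__(self, other):
        if not isinstance(other, ReticulatedNetwork):
            return NotImplemented
        mine = sorted((r.source_edge, r.target_edge, tuple(sorted(r.moved)),
                       tuple(r.evidence)) for r in self.reticulations)
        theirs = sorted((r.source_edge, r.target_edge, tuple(sorted(r.moved)),
                         tuple(r.evidence)) for r in other.reticulations)
        return write_newick(self.scaffold) == write_newick(other.scaffold) \
            and mine == theirs


def scaffold_edges(scaffold: PhyloTree) -> Dict[int, tuple]:
    """Stable edge ids: post-order index -> (child, parent) node pair."""
    return {k: edge for k, edge in enumerate(scaffold._edges_postorder())}


def _edge_leafset(scaffold: PhyloTree, edge: tuple) -> frozenset:
    child, parent = edge
    return scaffold._leafset_below(child, parent)


def _edge_above_clade(scaffold: PhyloTree, leaves: frozenset) -> int:
    """Id of the smallest scaffold edge whose below-leafset covers ``leaves``.

    A leaf set straddling the root has no covering edge; the root-child
    edge with the largest overlap stands in (smaller id on ties)."""
    best = None
    fallback = None
    for eid, edge in scaffold_edges(scaffold).items():
        below = _edge_leafset(scaffold, edge)
        if leaves <= below:
            if best is None or len(below) < best[1]:
                best = (eid, len(below))
        if edge[1] == scaffold.root:
            overlap = len(leaves & below)
            if fallback is None or overlap > fallback[1]:
                fallback = (eid, overlap)
    if best is not None:
        return best[0]
    if fallback is not None:
        return fallback[0]
    raise ValueError("no scaffold edge covers %s" % sorted(leaves))


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def _partition_distance(aln: Alignment) -> DistanceMatrix:
    if aln.alphabet.upper() in ("ACGT", "ACGU"):
        return k2p_distance_matrix(aln)
    return protein_distance_matrix(aln)


def combined_distance_matrix(partitions: Sequence[Alignment]) -> DistanceMatrix:
    """Partition-length-weighted average of per-partition corrected
    distances (pairs missing from a partition renormalise its weight)."""
    if not partitions:
        raise ValueError("no partitions")
    taxa = tuple(sorted(partitions[0].taxa))
    for aln in partitions:
        if tuple(sorted(aln.taxa)) != taxa:
            raise ValueError("partitions do not share a taxon set")
    n = len(taxa)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    pnum = np.zeros((n, n))
    for aln in partitions:
        order = [aln.taxa.index(t) for t in taxa]
        sub = Alignment(taxa, aln.data[order], aln.alphabet)
        # pairs with no comparable sites in this partition get zero weight
        w = float(sub.n_sites)
        valid = sub.data != Alignment.GAP
        have = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            have[i, j] = have[j, i] = bool((valid[i] & valid[j]).any())
        if not have.any():
            continue
        masked = sub
        if not have.all():
            masked = sub  # distances computed pairwise below
        dm = _masked_distance(sub, have)
        num += np.where(have, dm.d, 0.0) * w
        pnum += np.where(have, dm.p, 0.0) * w
        den += np.where(have, w, 0.0)
    if np.any(den[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError("no partition covers the pair (%s, %s)"
                         % (taxa[i], taxa[j]))
    np.fill_diagonal(den, 1.0)
    return DistanceMatrix(taxa, pnum / den, num / den)


def _masked_distance(aln: Alignment, have: np.ndarray) -> DistanceMatrix:
    """Distance matrix tolerant of pairs with no shared sites (left at 0,
    to be zero-weighted by the caller)."""
    n = len(aln.taxa)
    if have.all():
        return _partition_distance(aln)
    p = np.zeros((n, n))
    d = np.zeros((n, n))
    full = _partition_distance_or_none(aln, have)
    return full


def _partition_distance_or_none(aln, have):
    n = len(aln.taxa)
    p = np.zeros((n, n))
    d = np.zeros((n, n))
    nucleotide = aln.alphabet.upper() in ("ACGT", "ACGU")
    for i, j in itertools.combinations(range(n), 2):
        if not have[i, j]:
            continue
        pair = Alignment((aln.taxa[i], aln.taxa[j]),
                         aln.data[[i, j]], aln.alphabet)
        dm = k2p_distance_matrix(pair) if nucleotide \
            else protein_distance_matrix(pair)
        p[i, j] = p[j, i] = dm.p[0, 1]
        d[i, j] = d[j, i] = dm.d[0, 1]
    return DistanceMatrix(aln.taxa, p, d)


def root_on_outgroup(tree: PhyloTree, outgroup: Iterable) -> PhyloTree:
    """Root an unrooted tree on the edge separating ``outgroup``.

    The outgroup must be one leaf or a set separable by a single edge; the
    root splits that edge's length in half.
    """
    outgroup = frozenset(outgroup)
    if not outgroup or not outgroup <= tree.taxa:
        raise ValueError("outgroup must be a non-empty subset of the taxa")
    g = tree.graph.copy()
    target = None
    if len(outgroup) == 1:
        leaf = tree.taxon_node(next(iter(outgroup)))
        target = (leaf, next(iter(g.neighbors(leaf))))
    else:
        for child, parent in tree._edges_postorder():
            below = tree._leafset_below(child, parent)
            if below == outgroup or (tree.taxa - below) == outgroup:
                target = (child, parent)
                break
        if target is None:
            raise ValueError("outgroup %s is not separable by any edge"
                             % sorted(outgroup))
    u, v = target
    attrs = dict(g.edges[u, v])
    g.remove_edge(u, v)
    root = max(g.nodes) + 1 if all(isinstance(n, int) for n in g.nodes) else "root"
    g.add_node(root)
    half = attrs.get("length")
    half = half / 2.0 if half is not None else None
    for end in (u, v):
        eattrs = dict(attrs)
        if half is not None:
            eattrs["length"] = half
        g.add_edge(root, end, **eattrs)
    return PhyloTree(g, root, rooted=True)


def build_scaffold(partitions: Sequence[Alignment], root_outgroup: Iterable,
                   method: str = "NJ", model=None) -> PhyloTree:
    """Concatenate partitions under combined distances, reconstruct, and
    root on the outgroup edge."""
    dm = combined_distance_matrix(partitions)
    if method == "NJ":
        tree = neighbor_joining(dm)
    elif method == "ML":
        from rnol.models import jtt_model
        from rnol.reconstruct import concatenate_supermatrix
        from rnol.simulate import GenomeSet
        gs = GenomeSet(tuple(sorted(partitions[0].taxa)), list(partitions))
        sm = concatenate_supermatrix(gs)
        tree = exhaustive_ml_tree(sm.alignment, model or jtt_model())
    else:
        raise ValueError("unknown method %r" % method)
    return root_on_outgroup(tree, root_outgroup)


# ---------------------------------------------------------------------------
# reticulation detection
# ---------------------------------------------------------------------------

def detect_reticulations(scaffold: PhyloTree, gene_tree: PhyloTree,
                         s: float = 0.0) -> List[Reticulation]:
    """Candidate reticulations explaining one gene tree's disagreement.

    The scaffold is restricted to the gene tree's taxa; if the topologies
    agree the list is empty.  Otherwise the complement of the maximum
    agreement subset marks the displaced taxa; each maximal displaced clade
    of the restricted scaffold yields a candidate whose target is its
    scaffold attachment edge and whose source is the scaffold edge of its
    nearest-neighbour group in the gene tree.  When the gene tree carries
    support values, candidates backed only by bipartitions below ``s`` are
    discarded; unsupported gene trees are taken at face value.
    """
    shared = gene_tree.taxa & scaffold.taxa
    if gene_tree.taxa - scaffold.taxa:
        raise ValueError("gene tree taxa missing from scaffold: %s"
                         % sorted(gene_tree.taxa - scaffold.taxa))
    if len(shared) < 4:
        logger.info("skipping gene tree with %d shared taxa (< 4)", len(shared))
        return []
    restricted = restrict_to_taxa(scaffold, shared)
    scaffold_bps = {bp.key() for bp in restricted.bipartitions()}
    gene_bps = gene_tree.bipartitions()
    if {bp.key() for bp in gene_bps} == scaffold_bps:
        return []
    conflicting = [bp for bp in gene_bps
                   if bp.key() not in scaffold_bps
                   and any(not are_compatible(bp, sb)
                           for sb in restricted.bipartitions())]
    if gene_tree.has_supports():
        strong = [bp for bp in conflicting
                  if bp.support is not None and bp.support >= s]
        if conflicting and not strong:
            return []
    agree = maximum_agreement_subset(restricted, gene_tree)
    displaced = shared - agree
    if not displaced:
        return []
    candidates = []
    for clade in _maximal_displaced_clades(restricted, displaced):
        target = _edge_above_clade(scaffold, clade)
        neighbour = _gene_tree_neighbourhood(gene_tree, clade, displaced)
        if not neighbour:
            continue
        source = _edge_above_clade(scaffold, neighbour)
        candidates.append(Reticulation(source, target, frozenset(clade)))
    return candidates


def _maximal_displaced_clades(restricted: PhyloTree,
                              displaced: frozenset) -> List[frozenset]:
    """Maximal scaffold clades made up entirely of displaced taxa."""
    clades = [frozenset([t]) for t in displaced]
    for child, parent in restricted._edges_postorder():
        below = restricted._leafset_below(child, parent)
        if below and below <= displaced:
            clades.append(below)
    maximal = []
    for c in sorted(clades, key=len, reverse=True):
        if not any(c < m for m in maximal):
            if not any(c <= m for m in maximal):
                maximal.append(c)
    return sorted(maximal, key=lambda c: (len(c), sorted(c)))


def _gene_tree_neighbourhood(gene_tree: PhyloTree, clade: frozenset,
                             displaced: frozenset) -> frozenset:
    """The displaced clade's sister group in the gene tree (non-displaced
    members preferred): the smallest gene-tree split side properly
    containing the clade, minus the clade itself."""
    best = None
    for child, parent in gene_tree._edges_postorder():
        below = gene_tree._leafset_below(child, parent)
        for side in (below, gene_tree.taxa - below):
            if clade < side:
                rest = side - clade
                if best is None or len(rest) < len(best):
                    best = rest
    if best is None:
        return frozenset()
    non_displaced = best - displaced
    return frozenset(non_displaced or best)


def assemble_network(scaffold: PhyloTree,
                     candidates_by_family: Dict[int, Sequence[Reticulation]],
                     min_family_support: int = DEFAULT_MIN_FAMILY_SUPPORT,
                     ) -> ReticulatedNetwork:
    """Merge per-family candidates and keep the recurrent ones.

    Candidates identical in (source, target, moved taxa) merge, with the
    supporting family ids concatenated as evidence; merged reticulations
    backed by fewer than ``min_family_support`` families are dropped.
    """
    merged: Dict[tuple, list] = {}
    for fam_id in sorted(candidates_by_family):
        for cand in candidates_by_family[fam_id]:
            merged.setdefault(cand.merge_key(), []).append((fam_id, cand))
    kept = []
    for key in sorted(merged, key=lambda k: (k[0], k[1], sorted(k[2]))):
        entries = merged[key]
        if len(entries) < min_family_support:
            logger.info("dropping reticulation %s: %d < %d supporting families",
                        key, len(entries), min_family_support)
            continue
        evidence = tuple((fam_id, max((s for _, s in cand.evidence), default=None))
                        for fam_id, cand in entries)
        source, target, moved = key
        kept.append(Reticulation(source, target, moved, evidence))
    return ReticulatedNetwork(scaffold, kept)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _node_names(scaffold: PhyloTree) -> Dict[object, str]:
    names = {}
    for k, (child, parent) in scaffold_edges(scaffold).items():
        if child not in names:
            d = scaffold.graph.nodes[child]
            names[child] = d["taxon"] if "taxon" in d else "n%d" % k
    names[scaffold.root] = "root"
    return names


def write_network(net: ReticulatedNetwork) -> Tuple[str, str]:
    """Serialise as (extended newick, edge-list TSV).

    The extended newick labels each reticulation's target attachment
    ``#Hk`` and adds a ``#Hk`` leaf under the source attachment (the
    standard duplicated-node convention).  The TSV lists every tree edge
    and reticulation with enough detail to rebuild an identical network.
    """
    edges = scaffold_edges(net.scaffold)
    g = net.scaffold.graph.copy()
    # insert labelled attachment nodes per reticulation
    inserted = {}

    def split_edge(eid, label):
        child, parent = edges[eid]
        key = (eid,)
        if key in inserted:
            return inserted[key]
        attrs = dict(g.edges[child, parent])
        g.remove_edge(child, parent)
        mid = ("mid", eid)
        g.add_node(mid)
        half = attrs.get("length")
        half = half / 2.0 if half is not None else None
        a1 = dict(attrs)
        a2 = dict(attrs)
        if half is not None:
            a1["length"] = a2["length"] = half
        a1.pop("support", None)
        g.add_edge(parent, mid, **a1)
        g.add_edge(mid, child, **a2)
        inserted[key] = mid
        return mid

    for k, r in enumerate(net.reticulations, start=1):
        tmid = split_edge(r.target_edge, "#H%d" % k)
        g.nodes[tmid]["hlabel"] = "#H%d" % k
        smid = split_edge(r.source_edge, None)
        hleaf = ("hleaf", k)
        g.add_node(hleaf, taxon="#H%d" % k)
        g.add_edge(smid, hleaf, length=0.0)

    def render(node, parent):
        d = g.nodes[node]
        if "taxon" in d and g.degree(node) <= 1:
            return d["taxon"]
        parts = []
        for nb in g.neighbors(node):
            if nb == parent:
                continue
            sub = render(nb, node)
            eattrs = g.edges[node, nb]
            if eattrs.get("length") is not None:
                sub += ":%.6f" % eattrs["length"]
            parts.append(sub)
        parts.sort()
        label = d.get("hlabel", "")
        return "(%s)%s" % (",".join(parts), label)

    enewick = render(net.scaffold.root, None) + ";"

    names = _node_names(net.scaffold)
    lines = ["edge_id\tparent\tchild\tkind\tlength\tmoved_taxa\tevidence"]
    for eid in sorted(edges):
        child, parent = edges[eid]
        length = net.scaffold.graph.edges[child, parent].get("length")
        lines.append("%d\t%s\t%s\ttree\t%s\t\t" % (
            eid, names[parent], names[child],
            "" if length is None else "%.6f" % length))
    for k, r in enumerate(net.reticulations):
        ev = ";".join("%s:%s" % (fid, "" if sup is None else "%g" % sup)
                      for fid, sup in r.evidence)
        lines.append("R%d\t%d\t%d\treticulation\t\t%s\t%s" % (
            k, r.source_edge, r.target_edge, ",".join(sorted(r.moved)), ev))
    return enewick, "\n".join(lines) + "\n"


def read_network_tsv(tsv: str) -> ReticulatedNetwork:
    """Rebuild a network from the edge-list TSV written by write_network."""
    tree_edges = []
    retics = []
    lengths = {}
    for line in tsv.splitlines():
        if line.startswith("edge_id") or not line.strip():
            continue
        fields = line.split("\t")
        fields += [""] * (7 - len(fields))
        eid, parent, child, kind, length, moved, ev = fields
        if kind == "tree":
            tree_edges.append((parent, child,
                               float(length) if length else None))
        else:
            evidence = []
            if ev:
                for item in ev.split(";"):
                    fid, _, sup = item.partition(":")
                    evidence.append((int(fid), float(sup) if sup else None))
            retics.append(Reticulation(int(parent), int(child),
                                       frozenset(moved.split(",")),
                                       tuple(evidence)))
    g = nx.Graph()
    children = set()
    for parent, child, length in tree_edges:
        attrs = {"length": length} if length is not None else {}
        g.add_edge(parent, child, **attrs)
        children.add(child)
    import re

    # internal nodes are written as "root" / "n<k>"; degree-1 others are taxa
    for node in g.nodes:
        internal = node == "root" or re.fullmatch(r"n\d+", node)
        if g.degree(node) == 1 and not internal:
            g.nodes[node]["taxon"] = node
    scaffold = PhyloTree(g, "root", rooted=True)
    return ReticulatedNetwork(scaffold, retics)
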