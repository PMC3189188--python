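"""Phylogenetic tree primitives.

Trees are stored as undirected :class:`networkx.Graph` topologies with leaf
nodes carrying taxon labels and edges carrying optional branch lengths and
support values.  Unrooted trees keep an arbitrary internal "virtual root"
used only for traversal; every topological comparison goes through
bipartition sets, never node identity.  Newick parsing is delegated to
dendropy; writing produces a canonical form (children ordered by smallest
descendant label, unrooted trees anchored at the neighbour of the globally
smallest leaf) so that equal topologies yield equal strings.

Support values may arrive on either the [0,1] or the [0,100] scale; they are
normalised to [0,1] on input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import networkx as nx

__all__ = [
    "PhyloTree",
    "Bipartition",
    "QuartetTopology",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "are_compatible",
    "induced_quartet_topology",
    "restrict_to_taxa",
    "robinson_foulds",
    "maximum_agreement_subset",
]

MAST_EXACT_LIMIT = 16  # exact MAST search cap (documented contract)


class NewickParseError(ValueError):
    pass


class TreeValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Bipartition:
    """An unordered split {side_a | side_b} of a taxon set.

    ``side_a`` is the side containing the lexicographically smallest taxon,
    so equality and hashing are order-independent.  ``support`` is carried
    along but excluded from equality.
    """

    side_a: frozenset
    side_b: frozenset
    support: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if a & b:
            raise TreeValidationError("bipartition sides overlap: %r" % sorted(a & b))
        if not a or not b:
            raise TreeValidationError("bipartition sides must be non-empty")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restricted(self, taxa: Iterable) -> Optional["Bipartition"]:
        """Restrict to a taxon subset; None if a side empties out."""
        taxa = frozenset(taxa)
        a, b = self.side_a & taxa, self.side_b & taxa
        if not a or not b:
            return None
        return Bipartition(a, b, self.support)

    def key(self):
        return frozenset((self.side_a, self.side_b))

    def __repr__(self):
        return "Bipartition(%s | %s)" % (
            ",".join(sorted(self.side_a)),
            ",".join(sorted(self.side_b)),
        )


@dataclass(frozen=True)
class QuartetTopology:
    """One of the 3 resolved pairings of 4 taxa, or the unresolved state.

    A resolved topology ``AB|CD`` is stored as a frozenset of two frozen
    2-sets; ``pairs is None`` encodes the unresolved (star) state.
    """

    taxa: frozenset
    pairs: Optional[frozenset] = None

    @classmethod
    def resolved(cls, pair1: Iterable, pair2: Iterable) -> "QuartetTopology":
        p1, p2 = frozenset(pair1), frozenset(pair2)
        if len(p1) != 2 or len(p2) != 2 or p1 & p2:
            raise TreeValidationError("quartet pairs must be disjoint 2-sets")
        return cls(p1 | p2, frozenset((p1, p2)))

    @classmethod
    def unresolved(cls, taxa: Iterable) -> "QuartetTopology":
        taxa = frozenset(taxa)
        if len(taxa) != 4:
            raise TreeValidationError("quartet needs exactly 4 taxa")
        return cls(taxa, None)

    @property
    def is_resolved(self) -> bool:
        return self.pairs is not None


class PhyloTree:
    """A rooted or unrooted phylogenetic tree.

    Parameters
    ----------
    graph : networkx.Graph
        Tree topology.  Leaf nodes must carry a ``taxon`` attribute; edges
        may carry ``length`` (>= 0) and ``support`` (in [0, 1]).
    root : hashable
        Node used as traversal anchor.  For rooted trees the root is
        meaningful (degree >= 2, conventionally 2); for unrooted trees it is
        a virtual anchor only.
    rooted : bool
    """

    def __init__(self, graph: nx.Graph, root, rooted: bool):
        self.graph = graph
        self.root = root
        self.rooted = rooted
        self._validate()
        self._bipartitions = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nested(cls, nested, rooted: bool = False) -> "PhyloTree":
        """Build a tree from nested tuples/strings.

        Leaves are strings or ``(label, length)`` pairs; internal nodes are
        tuples of children, optionally ``(child, ..., {"length": l,
        "support": s})`` with a trailing dict of edge attributes.
        """
        g = nx.Graph()
        counter = itertools.count()

        def build(spec):
            attrs = {}
            if isinstance(spec, tuple) and spec and isinstance(spec[-1], dict):
                attrs = spec[-1]
                spec = spec[:-1]
                if len(spec) == 1:
                    spec = spec[0]
            if isinstance(spec, str):
                node = next(counter)
                g.add_node(node, taxon=spec)
                return node, attrs
            node = next(counter)
            g.add_node(node)
            for child in spec:
                cnode, cattrs = build(child)
                g.add_edge(node, cnode, **cattrs)
            return node, attrs

        root, _ = build(nested)
        return cls(g, root, rooted)

    def _validate(self):
        g = self.graph
        if g.number_of_nodes() == 0:
            raise TreeValidationError("empty tree")
        if not nx.is_tree(g):
            raise TreeValidationError("graph is not a tree")
        labels = [d["taxon"] for _, d in g.nodes(data=True) if "taxon" in d]
        if len(set(labels)) != len(labels):
            dups = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError("duplicate leaf labels: %s" % dups)
        if any(not lab for lab in labels):
            raise TreeValidationError("empty taxon label")
        for u, v, d in g.edges(data=True):
            length = d.get("length")
            if length is not None and length < 0:
                raise TreeValidationError(
                    "negative branch length %r on edge (%r, %r)" % (length, u, v)
                )
        for n, d in g.nodes(data=True):
            if g.degree(n) == 1 and "taxon" not in d and g.number_of_nodes() > 1:
                raise TreeValidationError("unlabeled leaf node %r" % n)

    # -- basic accessors ------------------------------------------------------

    @property
    def taxa(self) -> frozenset:
        return frozenset(
            d["taxon"] for _, d in self.graph.nodes(data=True) if "taxon" in d
        )

    def leaf_nodes(self):
        return [n for n, d in self.graph.nodes(data=True) if "taxon" in d]

    def taxon_node(self, taxon):
        for n, d in self.graph.nodes(data=True):
            if d.get("taxon") == taxon:
                return n
        raise KeyError("taxon %r not in tree" % taxon)

    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.graph.copy(), self.root, self.rooted)

    def has_branch_lengths(self) -> bool:
        return all(
            d.get("length") is not None for _, _, d in self.graph.edges(data=True)
        )

    def has_supports(self) -> bool:
        return any(
            d.get("support") is not None for _, _, d in self.graph.edges(data=True)
        )

    # -- bipartitions ---------------------------------------------------------

    def bipartitions(self) -> frozenset:
        """Nontrivial bipartitions, one per internal edge (cached)."""
        if self._bipartitions is None:
            self._bipartitions = frozenset(self._compute_bipartitions())
        return self._bipartitions

    def _compute_bipartitions(self):
        g = self.graph
        all_taxa = self.taxa
        seen = {}
        # leaf sets below each edge via one rooted traversal
        for child, parent in self._edges_postorder():
            below = self._leafset_below(child, parent)
            if len(below) < 2 or len(all_taxa - below) < 2:
                continue
            bp = Bipartition(below, all_taxa - below, g.edges[child, parent].get("support"))
            k = bp.key()
            if k in seen:  # two root-adjacent edges of a rooted tree coincide
                if seen[k].support is None and bp.support is not None:
                    seen[k] = bp
            else:
                seen[k] = bp
        return seen.values()

    def _edges_postorder(self):
        """(child, parent) pairs in postorder from the traversal root.

        Children are visited in order of their smallest descendant taxon
        label, so the sequence (and any edge ids derived from it) is stable
        across graph rebuilds.
        """
        g = self.graph
        minlab = {}

        def label_pass(node, parent):
            d = g.nodes[node]
            labs = [d["taxon"]] if "taxon" in d else []
            for nb in g.neighbors(node):
                if nb != parent:
                    labs.append(label_pass(nb, node))
            minlab[(node, parent)] = min(labs)
            return minlab[(node, parent)]

        label_pass(self.root, None)
        order = []

        def walk(node, parent):
            children = sorted(
                (nb for nb in g.neighbors(node) if nb != parent),
                key=lambda nb: minlab[(nb, node)],
            )
            for nb in children:
                walk(nb, node)
                order.append((nb, node))

        walk(self.root, None)
        return order

    def _leafset_below(self, node, parent) -> frozenset:
        leaves = set()
        stack = [(node, parent)]
        while stack:
            n, p = stack.pop()
            d = self.graph.nodes[n]
            if "taxon" in d:
                leaves.add(d["taxon"])
            for nb in self.graph.neighbors(n):
                if nb != p:
                    stack.append((nb, n))
        return frozenset(leaves)

    # -- convenience ----------------------------------------------------------

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self):
        kind = "rooted" if self.rooted else "unrooted"
        return "<PhyloTree %s, %d leaves>" % (kind, self.n_leaves())

    def __eq__(self, other):
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __hash__(self):
        return hash(write_newick(self))


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Internal node labels that parse as numbers are read as support values on
    the edge above the node; values above 1 put the whole tree on the
    percentage scale and all supports are divided by 100.  A bifurcating
    basal node marks the tree rooted, a basal polytomy unrooted.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        if "uplicate" in str(exc):
            raise TreeValidationError("duplicate leaf label: %s" % exc) from None
        raise NewickParseError("malformed newick: %s" % exc) from None

    g = nx.Graph()
    counter = itertools.count()
    raw_supports = []

    def convert(dnode):
        node = next(counter)
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickParseError("leaf without label")
            g.add_node(node, taxon=dnode.taxon.label)
        else:
            g.add_node(node)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            attrs = {}
            if dchild.edge.length is not None:
                attrs["length"] = float(dchild.edge.length)
            if not dchild.is_leaf() and dchild.label is not None:
                try:
                    sup = float(dchild.label)
                except ValueError:
                    sup = None
                if sup is not None:
                    attrs["support"] = sup
                    raw_supports.append(sup)
            g.add_edge(node, child, **attrs)
        return node

    root = convert(dtree.seed_node)
    if any(s > 1.0 for s in raw_supports):
        for _, _, d in g.edges(data=True):
            if d.get("support") is not None:
                d["support"] = d["support"] / 100.0
    for _, _, d in g.edges(data=True):
        s = d.get("support")
        if s is not None and not (0.0 <= s <= 1.0):
            raise TreeValidationError("support %r outside [0, 1] after scaling" % s)

    n_leaves = sum(1 for _, d in g.nodes(data=True) if "taxon" in d)
    rooted = g.degree(root) == 2 and n_leaves >= 2
    tree = PhyloTree(g, root, rooted)
    return tree


def _format_length(x: float) -> str:
    return "%.6f" % x


def _format_support(s: float) -> str:
    return ("%.6f" % s).rstrip("0").rstrip(".")


def write_newick(tree: PhyloTree) -> str:
    """Canonical newick: children sorted by smallest descendant label.

    Unrooted trees are anchored at the internal node adjacent to the
    lexicographically smallest leaf so that equal unrooted topologies always
    serialise identically.  Branch lengths are printed with 6 decimals and
    supports (normalised, in [0, 1]) as internal-node labels.
    """
    g = tree.graph
    if g.number_of_nodes() == 1:
        (node,) = g.nodes
        return "%s;" % g.nodes[node]["taxon"]
    if g.number_of_nodes() == 2:
        (a, b) = sorted(g.nodes, key=lambda n: g.nodes[n]["taxon"])
        length = g.edges[a, b].get("length")
        suffix = ":" + _format_length(length) if length is not None else ""
        return "(%s,%s%s);" % (g.nodes[a]["taxon"], g.nodes[b]["taxon"], suffix)

    if tree.rooted:
        anchor = tree.root
    else:
        smallest = min(tree.taxa)
        leaf = tree.taxon_node(smallest)
        if g.degree(leaf) == 0:
            return "%s;" % smallest
        anchor = next(iter(g.neighbors(leaf)))
        if g.degree(anchor) == 1:  # two-leaf tree: anchor at the other leaf
            anchor = leaf

    def render(node, parent):
        d = g.nodes[node]
        if "taxon" in d:
            return d["taxon"], d["taxon"]
        parts = []
        for nb in g.neighbors(node):
            if nb == parent:
                continue
            sub, smallest = render(nb, node)
            eattrs = g.edges[node, nb]
            label = ""
            if "taxon" not in g.nodes[nb] and eattrs.get("support") is not None:
                label = _format_support(eattrs["support"])
            piece = sub + label
            if eattrs.get("length") is not None:
                piece += ":" + _format_length(eattrs["length"])
            parts.append((smallest, piece))
        parts.sort(key=lambda t: t[0])
        return "(%s)" % ",".join(p for _, p in parts), parts[0][0]

    body, _ = render(anchor, None)
    return body + ";"


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> frozenset:
    """The nontrivial bipartitions of ``tree`` (empty for < 4 taxa)."""
    return tree.bipartitions()


def bipartitions_tsv(tree: PhyloTree) -> str:
    """Bipartition dump as TSV (side_a, side_b, support)."""
    lines = ["side_a\tside_b\tsupport"]
    for bp in sorted(tree.bipartitions(),
                     key=lambda b: (sorted(b.side_a), sorted(b.side_b))):
        lines.append("%s\t%s\t%s" % (
            ",".join(sorted(bp.side_a)), ",".join(sorted(bp.side_b)),
            "" if bp.support is None else "%g" % bp.support))
    return "\n".join(lines) + "\n"


def are_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Standard split compatibility after restriction to shared taxa.

    Two splits can coexist in one tree iff at least one of the four pairwise
    side intersections is empty.  Splits sharing fewer than 4 taxa, or
    rendered trivial by the restriction, are compatible by convention.
    """
    shared = b1.taxa & b2.taxa
    if len(shared) < 4:
        return True
    r1, r2 = b1.restricted(shared), b2.restricted(shared)
    if r1 is None or r2 is None or not r1.nontrivial or not r2.nontrivial:
        return True
    return (
        not (r1.side_a & r2.side_a)
        or not (r1.side_a & r2.side_b)
        or not (r1.side_b & r2.side_a)
        or not (r1.side_b & r2.side_b)
    )


def induced_quartet_topology(tree: PhyloTree, quartet: Iterable) -> QuartetTopology:
    """Topology induced by restricting ``tree`` to 4 of its leaves."""
    q = frozenset(quartet)
    if len(q) != 4:
        raise ValueError("need exactly 4 distinct taxa")
    missing = q - tree.taxa
    if missing:
        raise KeyError("taxa not in tree: %s" % sorted(missing))
    return _quartet_from_bipartitions(tree.bipartitions(), q)


def _quartet_from_bipartitions(bps, q: frozenset) -> QuartetTopology:
    for bp in bps:
        a, b = bp.side_a & q, bp.side_b & q
        if len(a) == 2 and len(b) == 2:
            return QuartetTopology.resolved(a, b)
    return QuartetTopology.unresolved(q)


def restrict_to_taxa(tree: PhyloTree, keep: Iterable) -> PhyloTree:
    """Induced subtree on ``keep``: prune, then suppress degree-2 nodes
    summing their branch lengths."""
    keep = frozenset(keep)
    extra = keep - tree.taxa
    if extra:
        raise KeyError("taxa not in tree: %s" % sorted(extra))
    if not keep:
        raise ValueError("keep must be non-empty")
    g = tree.graph.copy()
    drop = [
        n for n, d in g.nodes(data=True) if "taxon" in d and d["taxon"] not in keep
    ]
    g.remove_nodes_from(drop)
    # iteratively prune newly-bare internal leaves
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) <= 1 and "taxon" not in g.nodes[n] and g.number_of_nodes() > 1:
                g.remove_node(n)
                changed = True
    root = tree.root if tree.root in g else next(iter(g.nodes))
    # suppress degree-2 nodes (keep a rooted tree's root)
    for n in list(g.nodes):
        if "taxon" in g.nodes[n]:
            continue
        if tree.rooted and n == root:
            continue
        if g.degree(n) == 2:
            (u, v) = list(g.neighbors(n))
            du, dv = g.edges[n, u], g.edges[n, v]
            length = None
            if du.get("length") is not None and dv.get("length") is not None:
                length = du["length"] + dv["length"]
            sups = [x for x in (du.get("support"), dv.get("support")) if x is not None]
            attrs = {}
            if length is not None:
                attrs["length"] = length
            if sups:
                attrs["support"] = min(sups)
            g.remove_node(n)
            g.add_edge(u, v, **attrs)
    if root not in g:
        root = next(iter(g.nodes))
    # a rooted root left with a single child is redundant
    if tree.rooted and root in g and "taxon" not in g.nodes[root] and g.degree(root) == 1:
        child = next(iter(g.neighbors(root)))
        g.remove_node(root)
        root = child
    return PhyloTree(g, root, tree.rooted)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (RF) distance over nontrivial bipartitions."""
    if t1.taxa != t2.taxa:
        raise ValueError(
            "taxon sets differ; restrict first (only in t1: %s; only in t2: %s)"
            % (sorted(t1.taxa - t2.taxa), sorted(t2.taxa - t1.taxa))
        )
    s1 = {bp.key() for bp in t1.bipartitions()}
    s2 = {bp.key() for bp in t2.bipartitions()}
    return len(s1 ^ s2)


def _same_restricted_topology(bps1, bps2, subset: frozenset) -> bool:
    def restricted_keys(bps):
        keys = set()
        for bp in bps:
            r = bp.restricted(subset)
            if r is not None and r.nontrivial:
                keys.add(r.key())
        return keys

    return restricted_keys(bps1) == restricted_keys(bps2)


def maximum_agreement_subset(t1: PhyloTree, t2: PhyloTree) -> frozenset:
    """A maximum-cardinality taxon subset on which both trees agree.

    Exact (descending-size enumeration) up to ``MAST_EXACT_LIMIT`` shared
    taxa, greedy leaf-removal beyond.  Ties break toward the
    lexicographically smallest sorted label list.
    """
    shared = t1.taxa & t2.taxa
    if len(shared) < 4:
        return shared
    bps1 = [bp for bp in t1.bipartitions()]
    bps2 = [bp for bp in t2.bipartitions()]
    if len(shared) <= MAST_EXACT_LIMIT:
        ordered = sorted(shared)
        for size in range(len(shared), 3, -1):
            for combo in itertools.combinations(ordered, size):
                sub = frozenset(combo)
                if _same_restricted_topology(bps1, bps2, sub):
                    return sub
        # no agreeing subset of size >= 4: any 3 taxa agree vacuously
        return frozenset(ordered[:3])
    # greedy: drop the leaf whose removal most reduces restricted RF
    current = set(shared)
    while not _same_restricted_topology(bps1, bps2, frozenset(current)):
        best = None
        for leaf in sorted(current):
            cand = frozenset(current - {leaf})
            rf = _restricted_rf(bps1, bps2, cand)
            if best is None or rf < best[0]:
                best = (rf, leaf)
        current.discard(best[1])
    return frozenset(current)


def _restricted_rf(bps1, bps2, subset: frozenset) -> int:
    def keys(bps):
        out = set()
        for bp in bps:
            r = bp.restricted(subset)
            if r is not None and r.nontrivial:
                out.add(r.key())
        return out

    return len(keys(bps1) ^ keys(bps2))
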