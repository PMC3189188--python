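"""Tree reconstruction: corrected distances, neighbor-joining, supermatrix
concatenation, per-family gene trees, and small-scale maximum likelihood.

Distances follow the classic protein workflow: observed difference
proportion p with pairwise deletion of gaps, then the Kimura correction
d = -ln(1 - p - 0.2 p^2), which approximates PAM-style multiple-hit
correction and saturates at p = 0.85 (an error here; simulated data stays
far below it).  Neighbor-joining is the standard Saitou-Nei agglomeration
with deterministic tie-breaking so reruns are byte-identical.  Likelihood
uses Felsenstein pruning with optional discrete-gamma and invariant-site
mixtures, and an exhaustive topology search for up to 8 taxa.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

from rnol.models import SubstitutionModel, jtt_model
from rnol.simulate import Alignment, GenomeSet
from rnol.tree import PhyloTree, write_newick

__all__ = [
    "DistanceMatrix",
    "Supermatrix",
    "kimura_protein_distance",
    "protein_distance_matrix",
    "k2p_distance_matrix",
    "neighbor_joining",
    "concatenate_supermatrix",
    "gene_tree_set",
    "bootstrap_support",
    "felsenstein_loglik",
    "exhaustive_ml_tree",
    "enumerate_unrooted_topologies",
]

KIMURA_SATURATION = 0.85
ML_MAX_TAXA = 8


class SaturationError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Observed (p) and corrected (d) pairwise distances."""

    taxa: tuple
    p: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        n = len(self.taxa)
        for m in (self.p, self.d):
            if m.shape != (n, n):
                raise ValueError("matrix shape mismatch")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError("distance matrix not symmetric")
            if np.abs(np.diag(m)).max() > 1e-12:
                raise ValueError("nonzero diagonal")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join("%.10g" % x for x in self.d[i]))
        return "\n".join(lines) + "\n"


def kimura_protein_distance(p):
    """Kimura's empirical correction d = -ln(1 - p - 0.2 p^2)."""
    p = np.asarray(p, dtype=float)
    if np.any(p > KIMURA_SATURATION):
        raise SaturationError("p-distance %.3f beyond saturation cutoff %.2f"
                              % (float(p.max()), KIMURA_SATURATION))
    return -np.log(1.0 - p - 0.2 * p * p)


def _pairwise_p(aln: Alignment) -> np.ndarray:
    n = len(aln.taxa)
    data = aln.data
    valid = data != Alignment.GAP
    p = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        sites = int(ok.sum())
        if sites == 0:
            raise ValueError("no comparable sites between %s and %s"
                             % (aln.taxa[i], aln.taxa[j]))
        diff = int((data[i, ok] != data[j, ok]).sum())
        p[i, j] = p[j, i] = diff / sites
    return p


def protein_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Kimura-corrected protein distances with pairwise gap deletion."""
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 sequences")
    p = _pairwise_p(aln)
    sat = p > KIMURA_SATURATION
    if sat.any():
        i, j = np.argwhere(sat)[0]
        raise SaturationError(
            "pair (%s, %s) beyond saturation: p=%.3f"
            % (aln.taxa[i], aln.taxa[j], p[i, j]))
    d = kimura_protein_distance(p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.taxa, p, d)


def k2p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Kimura two-parameter nucleotide distances (transitions vs
    transversions corrected separately)."""
    if aln.alphabet.upper() not in ("ACGT", "ACGU"):
        raise ValueError("K2P distances require a nucleotide alignment")
    n = len(aln.taxa)
    data = aln.data
    valid = data != Alignment.GAP
    purine = (data == 0) | (data == 2)  # A, G in ACGT order
    p = np.zeros((n, n))
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ok = valid[i] & valid[j]
        sites = int(ok.sum())
        if sites == 0:
            raise ValueError("no comparable sites between %s and %s"
                             % (aln.taxa[i], aln.taxa[j]))
        diff = data[i, ok] != data[j, ok]
        transition = diff & (purine[i, ok] == purine[j, ok])
        P = float(transition.sum()) / sites
        Q = float((diff & ~transition).sum()) / sites
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError("pair (%s, %s) saturated under K2P"
                                  % (aln.taxa[i], aln.taxa[j]))
        p[i, j] = p[j, i] = P + Q
        d[i, j] = d[j, i] = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return DistanceMatrix(aln.taxa, p, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on the corrected distances.

    Ties in the Q criterion break toward the smallest (row, column) index
    pair under the input taxon ordering; negative branch-length estimates
    are clamped to 0 with the deficit shifted to the sister branch, so the
    output is deterministic and non-negative.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.astype(float).copy()
    g = nx.Graph()
    # active node ids: 0..n-1 are leaves
    for i, t in enumerate(dm.taxa):
        g.add_node(i, taxon=t)
    active = list(range(n))
    next_id = n
    cur = D

    while len(active) > 3:
        m = len(active)
        r = cur.sum(axis=1)
        Qm = (m - 2) * cur - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        # deterministic argmin: first (i, j) in row-major order
        flat = np.argmin(Qm)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = cur[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        g.add_node(u)
        g.add_edge(u, active[i], length=li)
        g.add_edge(u, active[j], length=lj)
        keep = [x for x in range(m) if x not in (i, j)]
        newrow = 0.5 * (cur[i, keep] + cur[j, keep] - dij)
        newrow = np.maximum(newrow, 0.0)
        sub = cur[np.ix_(keep, keep)]
        nxt = np.zeros((len(keep) + 1, len(keep) + 1))
        nxt[:-1, :-1] = sub
        nxt[-1, :-1] = newrow
        nxt[:-1, -1] = newrow
        active = [active[x] for x in keep] + [u]
        cur = nxt

    # final three-way join
    a, b, c = active
    dab, dac, dbc = cur[0, 1], cur[0, 2], cur[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    center = next_id
    g.add_node(center)
    g.add_edge(center, a, length=la)
    g.add_edge(center, b, length=lb)
    g.add_edge(center, c, length=lc)
    return PhyloTree(g, center, rooted=False)


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated alignment plus the family -> column-range partition map
    (0-based, half-open)."""

    alignment: Alignment
    partitions: List[Tuple[int, int, int]]  # (family_id, start, end)

    def partition_tsv(self) -> str:
        lines = ["family_id\tstart\tend"]
        for fid, s, e in self.partitions:
            lines.append("%d\t%d\t%d" % (fid, s, e))
        return "\n".join(lines) + "\n"


def concatenate_supermatrix(gs: GenomeSet) -> Supermatrix:
    """Join every family's sequence per taxon, in family order."""
    if not gs.families:
        raise ValueError("empty genome set")
    taxa = tuple(sorted(gs.taxa))
    blocks = []
    partitions = []
    col = 0
    for fid, fam in enumerate(gs.families):
        missing = set(taxa) - set(fam.taxa)
        if missing:
            raise ValueError("family %d missing taxa %s" % (fid, sorted(missing)))
        order = [fam.taxa.index(t) for t in taxa]
        blocks.append(fam.data[order])
        partitions.append((fid, col, col + fam.n_sites))
        col += fam.n_sites
    data = np.concatenate(blocks, axis=1)
    return Supermatrix(Alignment(taxa, data, gs.families[0].alphabet), partitions)


def gene_tree_set(gs: GenomeSet, method: str = "NJ",
                  model: Optional[SubstitutionModel] = None) -> List[PhyloTree]:
    """One tree per family, in family order."""
    trees = []
    for fid, fam in enumerate(gs.families):
        try:
            if method == "NJ":
                trees.append(neighbor_joining(protein_distance_matrix(fam)))
            elif method == "ML":
                trees.append(exhaustive_ml_tree(fam, model or jtt_model()))
            else:
                raise ValueError("unknown method %r" % method)
        except ValueError as exc:
            raise ValueError("family %d: %s" % (fid, exc)) from exc
    return trees


def bootstrap_support(aln: Alignment, n_boot: int,
                      rng: np.random.Generator) -> PhyloTree:
    """NJ tree with bipartition supports from column-resampling bootstrap."""
    base = neighbor_joining(protein_distance_matrix(aln))
    counts = {bp.key(): 0 for bp in base.bipartitions()}
    L = aln.n_sites
    for _ in range(n_boot):
        cols = rng.integers(L, size=L)
        rep = Alignment(aln.taxa, aln.data[:, cols], aln.alphabet)
        for bp in neighbor_joining(protein_distance_matrix(rep)).bipartitions():
            k = bp.key()
            if k in counts:
                counts[k] += 1
    annotated = base.copy()
    g = annotated.graph
    for child, parent in annotated._edges_postorder():
        below = annotated._leafset_below(child, parent)
        rest = annotated.taxa - below
        if len(below) >= 2 and len(rest) >= 2:
            key = frozenset((below, rest))
            if key in counts:
                g.edges[child, parent]["support"] = counts[key] / n_boot
    annotated._bipartitions = None
    return annotated


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def felsenstein_loglik(tree: PhyloTree, aln: Alignment,
                       model: SubstitutionModel) -> float:
    """Log-likelihood of the alignment on the tree by the pruning algorithm.

    Handles the model's discrete-gamma categories and invariant-site class;
    gap cells contribute a flat partial (missing data).
    """
    if aln.n_sites == 0:
        raise ValueError("zero-length alignment")
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError("alignment and tree taxa differ")
    g = tree.graph
    for u, v, d in g.edges(data=True):
        if d.get("length") is None:
            raise ValueError("missing branch length")

    n_states = model.n_states
    L = aln.n_sites
    rates = model.rates
    site_lik = np.zeros(L)
    for rate in rates:
        partial = _prune(tree, aln, model, rate)
        site_lik += partial @ model.freqs
    site_lik /= len(rates)

    if model.pinv > 0:
        const = np.zeros(L)
        valid = aln.data != Alignment.GAP
        for s in range(n_states):
            ok = ((aln.data == s) | ~valid).all(axis=0)
            const += np.where(ok, model.freqs[s], 0.0)
        site_lik = (1.0 - model.pinv) * site_lik + model.pinv * const

    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.log(site_lik).sum())


def _prune(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
           rate: float) -> np.ndarray:
    g = tree.graph
    n_states = model.n_states
    L = aln.n_sites
    partials = {}
    for node, parent in tree._edges_postorder() + [(tree.root, None)]:
        d = g.nodes[node]
        if "taxon" in d:
            codes = aln.row(d["taxon"])
            part = np.zeros((L, n_states))
            valid = codes != Alignment.GAP
            part[~valid] = 1.0
            part[np.arange(L)[valid], codes[valid]] = 1.0
        else:
            part = np.ones((L, n_states))
            for nb in g.neighbors(node):
                if nb == parent:
                    continue
                t = g.edges[node, nb]["length"]
                P = model.transition_matrix(t, rate)
                part *= partials[nb] @ P.T
        partials[node] = part
    return partials[tree.root]


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> List[PhyloTree]:
    """All resolved unrooted topologies on ``taxa`` by stepwise addition.

    (2n-5)!! trees; callers cap n at 8 (10395 topologies)."""
    taxa = sorted(taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > ML_MAX_TAXA:
        raise ValueError("exhaustive enumeration limited to %d taxa; use NJ"
                         % ML_MAX_TAXA)
    base = [(0, 3), (1, 3), (2, 3)]  # star on first three leaves, center id 3
    trees = [(base, 4)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_id in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                mid, leaf_id = next_id, next_id + 1
                new_edges = edges[:k] + edges[k + 1:] + [
                    (u, mid), (mid, v), (mid, leaf_id)]
                nxt.append((new_edges, next_id + 2))
        trees = nxt

    # node id of taxon k: k for the seed leaves, 2k - 1 for later additions
    leaf_id = {k: (k if k < 3 else 2 * k - 1) for k in range(n)}
    out = []
    for edges, _ in trees:
        g = nx.Graph()
        g.add_edges_from(edges)
        for k, nid in leaf_id.items():
            g.nodes[nid]["taxon"] = taxa[k]
        root = next(nd for nd in g.nodes if g.degree(nd) > 1)
        out.append(PhyloTree(g, root, rooted=False))
    return out


def _optimize_branch_lengths(tree: PhyloTree, aln: Alignment,
                             model: SubstitutionModel, max_sweeps: int = 50,
                             rel_tol: float = 1e-6) -> float:
    g = tree.graph
    for u, v, d in g.edges(data=True):
        if d.get("length") is None:
            d["length"] = 0.1
    prev = felsenstein_loglik(tree, aln, model)
    for _ in range(max_sweeps):
        for u, v in sorted(g.edges):
            edge = g.edges[u, v]

            def nll(x, edge=edge):
                edge["length"] = x
                return -felsenstein_loglik(tree, aln, model)

            res = minimize_scalar(nll, bounds=(1e-9, 20.0), method="bounded",
                                  options={"xatol": 1e-8})
            edge["length"] = float(res.x)
        cur = felsenstein_loglik(tree, aln, model)
        if abs(cur - prev) <= rel_tol * (abs(prev) + 1e-12):
            prev = cur
            break
        prev = cur
    return prev


def exhaustive_ml_tree(aln: Alignment, model: SubstitutionModel) -> PhyloTree:
    """Best-likelihood topology over all resolved unrooted trees (<= 8 taxa).

    Branch lengths per topology are optimised by cyclic single-branch Brent
    search; ties break toward the canonical newick order.
    """
    taxa = sorted(aln.taxa)
    if len(taxa) > ML_MAX_TAXA:
        raise ValueError("exhaustive ML limited to %d taxa; use neighbor_joining"
                         % ML_MAX_TAXA)
    best = None
    for top in enumerate_unrooted_topologies(taxa):
        ll = _optimize_branch_lengths(top, aln, model)
        key = (-ll, write_newick(top))
        if best is None or key < best[0]:
            best = (key, top)
    return best[1]
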