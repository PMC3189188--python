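"""Congruence screen over gene trees: highly supported, mutually
incompatible bipartitions, classified by taxonomic rank.

For every pair of gene trees the supported bipartitions are restricted to
the shared taxon set; each incompatible pair of restricted splits is a
conflict record.  The taxa whose side-membership differs between the two
splits (the minimal reassignment set) determine the conflict's rank: if the
disagreement crosses domains it is inter-domain, if every displaced taxon
shares an order with its conflicting-context neighbours it is intra-order,
otherwise inter-order.  Partitions implicated in conflicts at or above a
configurable rank have the offending taxa gap-masked before concatenation,
keeping the supermatrix taxon set constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from rnol.simulate import Alignment
from rnol.tree import Bipartition, PhyloTree, are_compatible

__all__ = [
    "TaxonomyTable",
    "ConflictRecord",
    "ConflictReport",
    "supported_bipartitions",
    "screen_conflicts",
    "classify_conflict_rank",
    "filter_partitions",
]

RANKS = ("intra-order", "inter-order", "inter-domain")
DEFAULT_SUPPORT_THRESHOLD = 0.9
MIN_SHARED_TAXA = 4  # quartet-information minimum


class TaxonomyTable:
    """Per-taxon genus / order / domain assignments (TSV-backed)."""

    def __init__(self, table: Dict[str, Tuple[str, str, str]]):
        for taxon, ranks in table.items():
            if len(ranks) != 3 or not all(ranks):
                raise ValueError("taxon %r needs non-empty genus/order/domain"
                                 % taxon)
        self._table = {t: tuple(r) for t, r in table.items()}

    @classmethod
    def from_tsv(cls, path_or_buf) -> "TaxonomyTable":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str,
                         names=["taxon", "genus", "order", "domain"], header=0)
        return cls({row.taxon: (row.genus, row.order, row.domain)
                    for row in df.itertuples()})

    def to_tsv(self) -> str:
        lines = ["taxon\tgenus\torder\tdomain"]
        for t in sorted(self._table):
            lines.append("%s\t%s\t%s\t%s" % ((t,) + self._table[t]))
        return "\n".join(lines) + "\n"

    def __contains__(self, taxon):
        return taxon in self._table

    def genus(self, taxon: str) -> str:
        return self._lookup(taxon)[0]

    def order(self, taxon: str) -> str:
        return self._lookup(taxon)[1]

    def domain(self, taxon: str) -> str:
        return self._lookup(taxon)[2]

    def _lookup(self, taxon):
        try:
            return self._table[taxon]
        except KeyError:
            raise KeyError("taxon %r missing from taxonomy table" % taxon) from None


@dataclass
class ConflictRecord:
    tree_id_1: int
    bipartition_1: Bipartition
    support_1: float
    tree_id_2: int
    bipartition_2: Bipartition
    support_2: float
    shared_taxa: int
    rank: str
    displaced: frozenset = frozenset()


@dataclass
class ConflictReport:
    threshold: float
    records: List[ConflictRecord] = field(default_factory=list)
    pair_counts: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        for rec in self.records:
            if rec.rank not in RANKS:
                raise ValueError("unknown rank %r" % rec.rank)

    def count_by_rank(self) -> Dict[str, int]:
        out = {r: 0 for r in RANKS}
        for rec in self.records:
            out[rec.rank] += 1
        return out

    def to_tsv(self) -> str:
        lines = ["# support_threshold=%g" % self.threshold,
                 "tree_id_1\tbipartition_1\tsupport_1\ttree_id_2\t"
                 "bipartition_2\tsupport_2\tshared_taxa\trank\tdisplaced"]
        for r in self.records:
            lines.append("\t".join([
                str(r.tree_id_1), _bp_str(r.bipartition_1), "%g" % r.support_1,
                str(r.tree_id_2), _bp_str(r.bipartition_2), "%g" % r.support_2,
                str(r.shared_taxa), r.rank, ",".join(sorted(r.displaced))]))
        return "\n".join(lines) + "\n"


def _bp_str(bp: Bipartition) -> str:
    return "%s|%s" % (",".join(sorted(bp.side_a)), ",".join(sorted(bp.side_b)))


def supported_bipartitions(tree: PhyloTree, s: float) -> Set[Bipartition]:
    """Nontrivial bipartitions with support >= s."""
    if not (0.0 <= s <= 1.0):
        raise ValueError("support threshold must be in [0, 1]")
    if not tree.has_supports():
        raise ValueError("tree carries no support values; run a bootstrap "
                         "(e.g. reconstruct.bootstrap_support) first")
    return {bp for bp in tree.bipartitions()
            if bp.support is not None and bp.support >= s}


def _displaced_taxa(b1: Bipartition, b2: Bipartition,
                    taxonomy: Optional[TaxonomyTable] = None) -> frozenset:
    """Minimal set of taxa whose reassignment reconciles the two splits.

    The two possible side alignments give two candidate sets; the smaller
    wins, with ties broken toward the taxonomically tighter set (fewer
    distinct orders, then domains, then lexicographic order).
    """
    m1 = b1.side_a ^ b2.side_a  # aligning A1 with A2
    m2 = b1.side_a ^ b2.side_b  # aligning A1 with B2

    use_tax = taxonomy is not None and all(t in taxonomy for t in m1 | m2)

    def key(m):
        extra = ()
        if use_tax:
            extra = (len({taxonomy.order(t) for t in m}),
                     len({taxonomy.domain(t) for t in m}))
        return (len(m),) + extra + (tuple(sorted(m)),)

    return frozenset(min((m1, m2), key=key))


def classify_conflict_rank(b1: Bipartition, b2: Bipartition,
                           taxonomy: TaxonomyTable) -> Tuple[str, frozenset]:
    """Rank label for a pair of incompatible splits on a shared taxon set.

    The displaced taxa are the minimal reassignment set.  A displacement
    confined to one order (several members of the same order trading
    places) is intra-order.  Otherwise each displaced taxon is compared
    with its conflicting-context neighbours -- the non-displaced taxa it is
    grouped with under either split: a domain mismatch with all neighbours
    of one claim makes the conflict inter-domain; a taxon whose order is
    represented among the neighbours of both claims stays intra-order;
    anything else is inter-order.
    """
    moved = _displaced_taxa(b1, b2, taxonomy)
    for t in moved:
        taxonomy._lookup(t)  # raise early on missing taxa
    if len(moved) >= 2:
        orders = {taxonomy.order(t) for t in moved}
        domains = {taxonomy.domain(t) for t in moved}
        if len(orders) == 1 and len(domains) == 1:
            return "intra-order", moved
    severity = 0  # 0 intra-order, 1 inter-order, 2 inter-domain
    for t in sorted(moved):
        contexts = []
        for bp in (b1, b2):
            side = bp.side_a if t in bp.side_a else bp.side_b
            context = side - moved - {t}
            if not context:
                context = side - {t}
            contexts.append(context)
        for context in contexts:
            if context and taxonomy.domain(t) not in \
                    {taxonomy.domain(x) for x in context}:
                return "inter-domain", moved
        in_both = all(
            not context or
            taxonomy.order(t) in {taxonomy.order(x) for x in context}
            for context in contexts)
        if not in_both:
            severity = max(severity, 1)
    return RANKS[severity], moved


def screen_conflicts(gene_trees: Sequence[PhyloTree], s: float,
                     taxonomy: TaxonomyTable) -> ConflictReport:
    """All-pairs conflict screen at support threshold ``s``.

    Both trees' supported bipartitions are restricted to the pair's shared
    taxon set; every incompatible pair of restrictions with >= 4 shared
    taxa becomes a rank-classified record.
    """
    if len(gene_trees) < 2:
        raise ValueError("need at least two trees to screen")
    report = ConflictReport(threshold=s)
    supported = [sorted(supported_bipartitions(t, s),
                        key=lambda bp: _bp_str(bp))
                 for t in gene_trees]
    for i, j in itertools.combinations(range(len(gene_trees)), 2):
        shared = gene_trees[i].taxa & gene_trees[j].taxa
        n_pair = 0
        if len(shared) >= MIN_SHARED_TAXA:
            for bi in supported[i]:
                ri = bi.restricted(shared)
                if ri is None or not ri.nontrivial:
                    continue
                for bj in supported[j]:
                    rj = bj.restricted(shared)
                    if rj is None or not rj.nontrivial:
                        continue
                    if ri.key() == rj.key() or are_compatible(ri, rj):
                        continue
                    rank, moved = classify_conflict_rank(ri, rj, taxonomy)
                    report.records.append(ConflictRecord(
                        i, ri, bi.support, j, rj, bj.support,
                        len(shared), rank, moved))
                    n_pair += 1
        report.pair_counts[(i, j)] = n_pair
    return report


RANK_SEVERITY = {r: k for k, r in enumerate(RANKS)}


def filter_partitions(partitions: Sequence[Alignment], report: ConflictReport,
                      exclusion_rank: str = "inter-order"
                      ) -> Tuple[List[Alignment], List[Tuple[int, str, str]]]:
    """Gap-mask conflicted sequences before concatenation.

    For every conflict at or above ``exclusion_rank``, the displaced taxa's
    rows in both implicated partitions are replaced by all-gap rows (column
    count preserved).  Returns the filtered partitions and an exclusion log
    of (partition_id, taxon, reason) tuples.
    """
    if exclusion_rank not in RANKS:
        raise ValueError("unknown rank %r" % exclusion_rank)
    cut = RANK_SEVERITY[exclusion_rank]
    to_mask: Dict[int, Set[str]] = {}
    log: List[Tuple[int, str, str]] = []
    for rec in report.records:
        if RANK_SEVERITY[rec.rank] < cut:
            continue
        for pid in (rec.tree_id_1, rec.tree_id_2):
            if pid >= len(partitions):
                raise ValueError("conflict references partition %d beyond input"
                                 % pid)
            for taxon in sorted(rec.displaced):
                if taxon not in to_mask.setdefault(pid, set()):
                    to_mask[pid].add(taxon)
                    log.append((pid, taxon, rec.rank))
    out = []
    for pid, aln in enumerate(partitions):
        mask = to_mask.get(pid)
        if not mask:
            out.append(aln)
            continue
        data = aln.data.copy()
        for taxon in mask:
            if taxon in aln.taxa:
                data[aln.taxa.index(taxon)] = Alignment.GAP
        out.append(Alignment(aln.taxa, data, aln.alphabet))
    return out, sorted(log)
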