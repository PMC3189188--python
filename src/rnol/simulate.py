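"""Genome-evolution simulation with a directed highway of gene sharing.

The default experiment evolves G single-copy gene families of length L
along a fixed 7-taxon species tree under the JTT model, then imposes a
highway of horizontal transfer: in a fraction h of the families the
recipient genome F's sequence is overwritten by the donor genome Bp's
sequence (ortholog replacement at the tips).  The donor Bp (sister to B) is
subsequently dropped, so the transfers surface as conflicting signal that
pulls F toward B in reconstruction.

The species-tree topology is ((A,(B,Bp)),C,(D,(E,F))) with the internal
branch adjacent to the (E,F) cherry set to ``b`` substitutions/site and all
other branches set to a common default of 0.1.  ``Bp`` denotes the donor
lineage B-prime.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from rnol.models import SubstitutionModel, jtt_model
from rnol.tree import PhyloTree, parse_newick, restrict_to_taxa

__all__ = [
    "Alignment",
    "GenomeSet",
    "ExperimentConfig",
    "default_species_tree",
    "true_ingroup_tree",
    "evolve_alignment",
    "simulate_genome_set",
    "apply_highway",
    "drop_taxon",
    "write_genome_set",
    "read_genome_set",
]

DEFAULT_TAXA = ("A", "B", "Bp", "C", "D", "E", "F")
DEFAULT_DONOR = "Bp"
DEFAULT_RECIPIENT = "F"


@dataclass
class Alignment:
    """A positional multiple alignment, one row per taxon.

    ``data`` holds residue codes in the order of ``alphabet`` (uint8,
    n_taxa x n_sites); the gap/ambiguity code 255 marks masked cells.
    """

    taxa: tuple
    data: np.ndarray
    alphabet: str

    GAP = 255

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("row count does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        codes = self.row(taxon)
        return "".join("-" if c == self.GAP else self.alphabet[c] for c in codes)

    @classmethod
    def from_sequences(cls, seqs: dict, alphabet: str) -> "Alignment":
        taxa = tuple(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("unequal sequence lengths: %s" % sorted(lengths))
        lut = np.full(128, 255, dtype=np.uint8)
        for i, ch in enumerate(alphabet):
            lut[ord(ch)] = i
        data = np.empty((len(taxa), lengths.pop()), dtype=np.uint8)
        for i, t in enumerate(taxa):
            raw = np.frombuffer(seqs[t].upper().encode("ascii"), dtype=np.uint8)
            codes = lut[raw]
            unknown = (codes == 255) & (raw != ord("-")) & (raw != ord("?")) \
                & (raw != ord("X"))
            if unknown.any():
                bad = sorted({chr(c) for c in raw[unknown]})
                raise ValueError("unknown residues %s in %s" % (bad, t))
            data[i] = codes
        return cls(taxa, data, alphabet)

    def drop_taxon(self, taxon: str) -> "Alignment":
        i = self.taxa.index(taxon)
        keep = [j for j in range(len(self.taxa)) if j != i]
        return Alignment(tuple(t for t in self.taxa if t != taxon),
                         self.data[keep].copy(), self.alphabet)

    def to_fasta(self) -> str:
        buf = io.StringIO()
        records = [SeqRecord(Seq(self.sequence(t)), id=t, description="")
                   for t in self.taxa]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()

    @classmethod
    def from_fasta(cls, handle, alphabet: str) -> "Alignment":
        if isinstance(handle, str) and "\n" in handle:
            handle = io.StringIO(handle)
        seqs = {}
        for rec in SeqIO.parse(handle, "fasta"):
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError("no sequences in FASTA input")
        return cls.from_sequences(seqs, alphabet)


@dataclass
class GenomeSet:
    """An ordered collection of gene-family alignments over one taxon set.

    ``transferred[k]`` is the set of taxa in family ``k`` whose sequence was
    overwritten by a horizontal transfer (empty when vertical).
    """

    taxa: tuple
    families: List[Alignment]
    transferred: List[Set[str]] = field(default_factory=list)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if not self.transferred:
            self.transferred = [set() for _ in self.families]
        if len(self.transferred) != len(self.families):
            raise ValueError("provenance list length mismatch")
        for k, fam in enumerate(self.families):
            if set(fam.taxa) != set(self.taxa):
                raise ValueError("family %d does not cover the taxon set" % k)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def transfer_count(self) -> int:
        return sum(1 for t in self.transferred if t)


@dataclass
class ExperimentConfig:
    """Parameters of the highway simulation experiment."""

    internal_branch: float = 0.05       # substitutions/site on the (E,F) edge
    other_branch: float = 0.1           # every other branch
    gene_count: int = 100
    gene_length: int = 300
    hgt_fraction: float = 0.0
    replicates: int = 100
    seed: int = 0
    donor: str = DEFAULT_DONOR
    recipient: str = DEFAULT_RECIPIENT
    methods: tuple = ("supermatrix-NJ", "quartet-supertree")

    def __post_init__(self):
        if not (0.0 <= self.hgt_fraction <= 1.0):
            raise ValueError("hgt_fraction must be in [0, 1]")
        if self.internal_branch <= 0 or self.other_branch <= 0:
            raise ValueError("branch lengths must be positive")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")

    def species_tree(self) -> PhyloTree:
        return default_species_tree(self.internal_branch, self.other_branch)


def default_species_tree(b: float, other: float = 0.1) -> PhyloTree:
    """The 7-taxon highway species tree ((A,(B,Bp)),C,(D,(E,F))).

    ``b`` is the length of the internal branch separating the (E,F) cherry
    from the rest; every other branch gets length ``other``.
    """
    if b <= 0:
        raise ValueError("internal branch length must be positive")
    if other <= 0:
        raise ValueError("branch length must be positive")
    newick = (
        "((A:{o},(B:{o},Bp:{o}):{o}):{o},C:{o},(D:{o},(E:{o},F:{o}):{b}):{o});"
        .format(o=repr(other), b=repr(b))
    )
    return parse_newick(newick)


def true_ingroup_tree(b: float, other: float = 0.1) -> PhyloTree:
    """The correct 6-taxon tree used for recovery scoring (donor dropped)."""
    return restrict_to_taxa(default_species_tree(b, other), set("ABCDEF"))


def evolve_alignment(tree: PhyloTree, length: int, model: SubstitutionModel,
                     rng: np.random.Generator) -> Alignment:
    """Simulate one gene family along ``tree`` under ``model``.

    The root sequence is drawn from the stationary frequencies; each site
    then evolves independently down every branch with transition matrix
    exp(Q t).  Sites may carry discrete-gamma rate categories and an
    invariant-site class if the model defines them.  No indels.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    g = tree.graph
    for u, v, d in g.edges(data=True):
        if d.get("length") is None:
            raise ValueError("missing branch length on edge (%r, %r)" % (u, v))

    k = len(model.rates)
    site_cat = rng.integers(k, size=length) if k > 1 else np.zeros(length, dtype=int)
    invariant = (rng.random(length) < model.pinv) if model.pinv > 0 else None

    n = model.n_states
    root_seq = rng.choice(n, size=length, p=model.freqs).astype(np.uint8)
    states = {tree.root: root_seq}
    out = {}

    stack = [(tree.root, None)]
    while stack:
        node, parent = stack.pop()
        if parent is not None:
            t = g.edges[node, parent]["length"]
            pstate = states[parent]
            child = pstate.copy()
            if t > 0:
                for c in range(k):
                    mask = site_cat == c
                    if invariant is not None:
                        mask = mask & ~invariant
                    if not mask.any():
                        continue
                    P = model.transition_matrix(t, model.rates[c])
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(int(mask.sum()))
                    child[mask] = (u[:, None] > cum[pstate[mask]]).sum(axis=1) \
                        .astype(np.uint8)
            states[node] = child
        d = g.nodes[node]
        if "taxon" in d:
            out[d["taxon"]] = states[node]
        for nb in g.neighbors(node):
            if nb != parent:
                stack.append((nb, node))

    taxa = tuple(sorted(out))
    data = np.vstack([out[t] for t in taxa])
    return Alignment(taxa, data, model.alphabet)


def simulate_genome_set(config: ExperimentConfig, rng: np.random.Generator,
                        model: Optional[SubstitutionModel] = None) -> GenomeSet:
    """G independent families evolved on the config's species tree."""
    model = model or jtt_model()
    tree = config.species_tree()
    families = [evolve_alignment(tree, config.gene_length, model, rng)
                for _ in range(config.gene_count)]
    taxa = families[0].taxa if families else tuple(sorted(tree.taxa))
    return GenomeSet(taxa, families)


def apply_highway(gs: GenomeSet, donor: str, recipient: str, h: float,
                  rng: np.random.Generator) -> GenomeSet:
    """Ortholog replacement along the highway.

    round(G*h) families are chosen uniformly without replacement; in each
    the recipient's row is overwritten by the donor's row and flagged
    ``transferred``.  The donor row is untouched.
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError("transfer fraction must be in [0, 1]")
    for t in (donor, recipient):
        if t not in gs.taxa:
            raise KeyError("taxon %r not in genome set" % t)
    n_transfer = int(round(gs.n_families * h))
    chosen = set(rng.choice(gs.n_families, size=n_transfer, replace=False).tolist()) \
        if n_transfer else set()
    families = []
    transferred = []
    for k, fam in enumerate(gs.families):
        flags = set(gs.transferred[k])
        if k in chosen:
            data = fam.data.copy()
            data[fam.taxa.index(recipient)] = data[fam.taxa.index(donor)]
            fam = Alignment(fam.taxa, data, fam.alphabet)
            flags.add(recipient)
        families.append(fam)
        transferred.append(flags)
    return GenomeSet(gs.taxa, families, transferred)


def drop_taxon(gs: GenomeSet, taxon: str) -> GenomeSet:
    """Remove one taxon's row from every family (e.g. the donor Bp)."""
    if taxon not in gs.taxa:
        raise KeyError("taxon %r not in genome set" % taxon)
    families = [fam.drop_taxon(taxon) for fam in gs.families]
    transferred = [set(t) - {taxon} for t in gs.transferred]
    return GenomeSet(tuple(t for t in gs.taxa if t != taxon), families, transferred)


# ---------------------------------------------------------------------------
# on-disk layout: fam_0001.fasta ... + manifest.tsv
# ---------------------------------------------------------------------------

def write_genome_set(gs: GenomeSet, outdir: str, seed: Optional[int] = None) -> None:
    os.makedirs(outdir, exist_ok=True)
    lines = ["family_id\ttransferred_taxa"]
    for k, fam in enumerate(gs.families):
        name = "fam_%04d.fasta" % (k + 1)
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write(fam.to_fasta())
        lines.append("%s\t%s" % (name, ",".join(sorted(gs.transferred[k]))))
    header = "# rnol genome set"
    if seed is not None:
        header += "; master_seed=%d" % seed
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write(header + "\n" + "\n".join(lines) + "\n")


def read_genome_set(indir: str, alphabet: str) -> GenomeSet:
    manifest = os.path.join(indir, "manifest.tsv")
    families, transferred = [], []
    with open(manifest) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family_id"):
                continue
            name, _, flagged = line.partition("\t")
            with open(os.path.join(indir, name)) as f:
                families.append(Alignment.from_fasta(f, alphabet))
            transferred.append(set(x for x in flagged.split(",") if x))
    if not families:
        raise ValueError("no families listed in %s" % manifest)
    return GenomeSet(families[0].taxa, families, transferred)
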