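# Methods

## The model system

The toolkit studies a single *directed highway of gene sharing* on a fixed
species tree. Seven genomes evolve along the unrooted tree

```
((A, (B, Bp)), C, (D, (E, F)))
```

with the donor lineage Bp sister to B and the recipient F in the `(E,F)`
cherry. The focal parameter is the length *b* of the internal branch
separating `(E,F)` from the rest: 0.05 substitutions/site (well-supported
edge) or 0.01 (weak edge). The exact lengths of the remaining branches are
a free choice of the design; they default to 0.1 substitutions/site, a
moderate divergence at which 300-residue protein alignments retain strong
but not saturated signal. The default is recorded in every output header
and is configurable (`ExperimentConfig.other_branch`).

Each replicate simulates *G* = 100 gene families of *L* = 300 amino acids.
Horizontal transfer is modelled as *ortholog replacement at the tips*:
in round(G·h) families, chosen uniformly without replacement, the
recipient's extant sequence is overwritten by the donor's extant sequence
from the same family. This is deliberately the most coherent (and therefore
hardest) form of conflicting signal — every transferred family carries the
identical alternative history. The donor Bp is excluded from all
reconstruction, so the transfers surface only as a pull of F toward B.

## Sequence evolution

Sites evolve independently under a reversible CTMC. The default model is
JTT: the published integer exchangeabilities and stationary frequencies are
embedded verbatim (`rnol._jtt`), assembled into Q = S·diag(π), and scaled so
one unit of branch length equals one expected substitution per site at
stationarity. Transition matrices P(t) = exp(Qt) come from a cached
eigendecomposition of the π^½-symmetrised generator, so per-branch costs are
one matrix multiply. Discrete-gamma rate variation (mean-rate categories via
the incomplete-gamma discretisation) and an invariant-site class are
implemented and tested but **off by default**: the simulation design keeps
the generating process as simple as possible, and the sweep thresholds are
bracketed rather than pinned, so unmodelled rate variation would only shift
them smoothly. No indels are simulated and alignments are never re-aligned;
alignment columns are positionally true by construction.

## Distances and trees

Protein distances use the observed difference proportion *p* with pairwise
deletion of gaps and Kimura's empirical correction
d = −ln(1 − p − 0.2 p²), which is accurate for p ≲ 0.75. Beyond p = 0.85
the toolkit raises a saturation error instead of consulting lookup tables;
simulated data stay far below the cutoff (max pairwise path ≈ 0.75
substitutions/site ⇒ p ≈ 0.5). Nucleotide partitions use the Kimura
two-parameter correction. Neighbor joining is the standard Saitou–Nei
agglomeration with two determinism rules: Q-criterion ties break toward the
smallest (row, column) pair under the input taxon ordering, and negative
branch-length estimates are clamped to zero with the deficit shifted to the
sister branch. NJ output is cross-checked in the test suite against
scikit-bio's independent implementation.

Maximum likelihood (Felsenstein pruning, optional gamma/invariant mixture)
enumerates all unrooted topologies for ≤ 8 taxa and optimises branch
lengths per topology by cyclic bounded Brent search (relative tolerance
1e-6, ≤ 50 sweeps). It exists for parity and verification at small scale;
the headline sweep is NJ-driven, matching the distance-based default of the
experiment.

## Quartet supertrees

For every 4-taxon subset of the union taxon set, each gene tree containing
all four taxa votes for the induced pairing (unresolved restrictions
abstain). The plurality topology per subset wins with margin = top weight −
runner-up; exact ties leave the subset unconstrained. The supertree
maximises the summed margin of satisfied plurality quartets. With the
6-taxon reconstruction set this is solved exactly by scoring all 105
unrooted topologies; the greedy mode (quartet-joining agglomeration on net
cherry support, then NNI hill climbing under the same score, with a strict
(score, canonical-newick) descent key so it terminates) is for larger taxon
sets and is required by the tests to match the exact search on a battery of
random 6–7-taxon plurality maps. Ties in the exact search break toward the
lexicographically smallest canonical newick, making every run reproducible.
No bootstrap weighting of quartets is applied by default; a minimum-margin
filter is exposed as configuration (default 0).

## The recovery sweep

Per grid point h ∈ {0, 0.05, …, 0.60} and replicate: simulate → transfer →
drop donor → reconstruct by (a) supermatrix NJ and (b) quartet supertree →
compare with the species tree restricted to {A…F}. "Recovered" means
Robinson–Foulds distance 0; "majority" means > 50% of replicates; the
F-sister-to-B diagnostic is the presence of a {B,F} cherry split. The
summary reports, per method: the largest h with majority-correct recovery
(last success), the smallest h at or below the majority cut (first
failure), and the onset of majority F-sister-to-B. Each (grid point,
replicate) pair owns an RNG substream spawned from the master seed, so
results are byte-identical across reruns and safely parallelisable. The
acceptance script runs the full design (100 replicates per grid point, both
b values, ≈ 2 600 replicates in total, a few minutes on one CPU); the test
suite uses 30 replicates per point, which is ample to locate thresholds
that sit on a 5-percentage-point grid.

## Conflict screening

"Highly supported" is not a universal constant; the default threshold is
s = 0.9 on the normalised [0,1] support scale (both percentage and
fractional newick supports are accepted on input) and is recorded in every
report header. For every tree pair, supported bipartitions are restricted
to the shared taxon set (≥ 4 shared taxa required — the quartet-information
minimum) and checked with the standard split-compatibility criterion. The
taxa implicated in a conflict are the minimal set whose reassignment
between sides reconciles the two splits (ties broken toward the
taxonomically tighter set). Rank classification is a declared, deterministic
heuristic, since manual expert judgement cannot be reproduced in code: a
displacement confined to one order is intra-order; a displaced taxon whose
conflicting-context neighbours (either claim) belong to another domain
makes the conflict inter-domain; everything else is inter-order. Exclusion
before concatenation replaces the offending rows with all-gap rows rather
than deleting them, so the supermatrix taxon set stays constant; intra-order
conflicts are preserved by default.

## Scaffold and network

The scaffold is built from concatenated partitions — protein partitions
under Kimura/JTT distances, nucleotide under K2P, combined as the
partition-length-weighted average distance (pairs absent from a partition
renormalise its weight) — then rooted on a user-supplied outgroup edge.
Reticulation detection is deliberately *not* a full
duplication-transfer-loss reconciliation: no cost values are defined for
one, and a reconciliation's output cannot be oracle-checked at this scale.
Instead the maximum agreement subset between the restricted scaffold and a
gene tree (exact for ≤ 16 shared taxa, greedy leaf-removal beyond) marks
the displaced taxa; each maximal displaced scaffold clade becomes a
candidate whose target is its scaffold attachment edge and whose source is
the scaffold edge of its nearest-neighbour group in the gene tree. The
displaced clade is recorded as the recipient — an annotation, not a truth
claim, since donor/recipient polarity is generally unidentifiable from
topology alone. Candidates recurring in ≥ 5 families (configurable) become
reticulation edges; scaffold edges carry post-order ids (deterministic
child ordering by smallest descendant label) so attachments are stable
across runs and serialisation round-trips. Networks serialise as extended
newick (#H-labelled duplicated nodes) plus an edge-list TSV that rebuilds
an identical network.

## What the synthetic experiments do and do not show

The generator produces equal-length, gap-free, single-copy, orthologous
families with a single coherent highway and no rate heterogeneity across
sites or lineages. Real ribosomal datasets add alignment uncertainty,
compositional and rate heterogeneity, intra-genomic copy variation, gene
loss, and many weak transfers in place of one strong highway. Passing tests
therefore demonstrate the *methods* — that the quartet decomposition
resists coherent minority signal far better than concatenation, and that
the screen/network machinery finds exactly the planted conflicts — not that
any particular empirical dataset will behave identically. The published
conflict counts for real ribosomal data require alignments that are not
redistributable; the screen is validated here on synthetic fixtures with
conflicts injected at known taxonomic ranks.

## Numerical and degenerate-input choices

- Support values normalised to [0,1]; both input conventions accepted.
- Canonical newick (children by smallest descendant label, unrooted trees
  anchored at the smallest leaf's neighbour, 6-decimal lengths) makes
  string equality a topology test.
- Bipartitions sharing < 4 taxa, or rendered trivial by restriction, are
  compatible by convention.
- Star restrictions induce the unresolved quartet state, which counts
  toward no topology.
- MAST ties break toward the lexicographically smallest sorted label list.
- All stochastic defaults (grid, replicate counts, seeds) live in one
  place (`ExperimentConfig`, `DEFAULT_H_GRID`) and appear in output
  headers.

## Known limitations

- Exhaustive ML and exhaustive supertree search cap at 8 taxa; the greedy
  supertree and NJ cover larger problems without optimality guarantees.
- The reticulation source heuristic can be ambiguous when a displaced
  clade's gene-tree neighbourhood straddles the scaffold root; the
  root-child edge with the largest overlap stands in.
- K2P distances assume equal base frequencies; no codon or covarion models.
- The conflict-rank heuristic is a reproducible stand-in for expert
  curation, not a reimplementation of it.
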