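import io
import itertools

import numpy as np
import pytest

from rnol.models import jtt_model
from rnol.reconstruct import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    concatenate_supermatrix,
    enumerate_unrooted_topologies,
    exhaustive_ml_tree,
    felsenstein_loglik,
    gene_tree_set,
    k2p_distance_matrix,
    kimura_protein_distance,
    neighbor_joining,
    protein_distance_matrix,
)
from rnol.simulate import (
    Alignment,
    ExperimentConfig,
    evolve_alignment,
    simulate_genome_set,
    true_ingroup_tree,
)
from rnol.tree import parse_newick, robinson_foulds, write_newick

from conftest import random_tree


class TestKimuraDistance:
    @pytest.mark.parametrize("p,expected", [
        (0.0, 0.0),
        (0.1, 0.10758521067993743),   # -ln(0.898)
        (0.5, 0.7985076962177716),    # -ln(0.45)
    ])
    def test_closed_form_values(self, p, expected):
        assert kimura_protein_distance(p) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_and_convex(self):
        p = np.linspace(0.0, 0.84, 200)
        d = kimura_protein_distance(p)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > 0)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            kimura_protein_distance(0.9)

    def test_identical_sequences_zero(self, jtt):
        aln = Alignment.from_sequences(
            {"X": "ACDEF", "Y": "ACDEF"}, jtt.alphabet)
        dm = protein_distance_matrix(aln)
        assert dm.p[0, 1] == 0.0 and dm.d[0, 1] == 0.0

    def test_pairwise_deletion_of_gaps(self, jtt):
        aln = Alignment.from_sequences(
            {"X": "AC-EF", "Y": "ACDEF", "Z": "GCDEF"}, jtt.alphabet)
        dm = protein_distance_matrix(aln)
        ix, iy, iz = (dm.taxa.index(t) for t in "XYZ")
        assert dm.p[ix, iy] == 0.0           # gap column excluded
        assert dm.p[iy, iz] == pytest.approx(0.2)

    def test_corrected_at_least_observed(self, jtt):
        rng = np.random.default_rng(0)
        t = parse_newick("(X:0.4,Y:0.4);")
        aln = evolve_alignment(t, 500, jtt, rng)
        dm = protein_distance_matrix(aln)
        assert np.all(dm.d >= dm.p)


class TestK2PDistance:
    def test_known_proportions(self):
        # 10 sites, 2 transitions (A<->G), 1 transversion (A<->C)
        x = "AAGGCCTTAA"
        y = "GAGAACTTAA"
        from rnol.models import k2p_model
        aln = Alignment.from_sequences({"X": x, "Y": y}, "ACGT")
        dm = k2p_distance_matrix(aln)
        P, Q = 0.2, 0.1
        expected = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        assert dm.d[0, 1] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(("X", "Y", "Z"), d * 0, d))
        lengths = {}
        for leaf in t.leaf_nodes():
            (nb,) = t.graph.neighbors(leaf)
            lengths[t.graph.nodes[leaf]["taxon"]] = \
                t.graph.edges[leaf, nb]["length"]
        assert lengths["X"] == pytest.approx(1.0)
        assert lengths["Y"] == pytest.approx(2.0)
        assert lengths["Z"] == pytest.approx(3.0)

    def test_additive_four_taxon_recovery(self):
        # distances from ((A:1,B:1):1,(C:1,D:1))
        taxa = ("A", "B", "C", "D")
        d = np.array([[0, 2, 3, 3],
                      [2, 0, 3, 3],
                      [3, 3, 0, 2],
                      [3, 3, 2, 0]], float)
        t = neighbor_joining(DistanceMatrix(taxa, d * 0, d))
        assert write_newick(t) == \
            "(A:1.000000,B:1.000000,(C:1.000000,D:1.000000):1.000000);"

    @pytest.mark.parametrize("seed", range(6))
    def test_additive_matrices_recover_generating_tree(self, seed):
        rng = np.random.default_rng(seed)
        true = random_tree(rng, int(rng.integers(5, 9)))
        import networkx as nx
        leaves = true.leaf_nodes()
        n = len(leaves)
        d = np.zeros((n, n))
        taxa = tuple(sorted(true.graph.nodes[l]["taxon"] for l in leaves))
        node_of = {true.graph.nodes[l]["taxon"]: l for l in leaves}
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = nx.shortest_path_length(
                true.graph, node_of[taxa[i]], node_of[taxa[j]],
                weight="length")
        t = neighbor_joining(DistanceMatrix(taxa, d * 0, d))
        assert robinson_foulds(t, true) == 0
        # branch lengths recovered on internal edges too
        for i, j in itertools.combinations(range(n), 2):
            path = nx.shortest_path_length(
                t.graph, t.taxon_node(taxa[i]), t.taxon_node(taxa[j]),
                weight="length")
            assert path == pytest.approx(d[i, j], abs=1e-9)

    def test_equidistant_matrix_deterministic(self):
        taxa = tuple("VWXYZ")
        d = np.ones((5, 5)) - np.eye(5)
        first = neighbor_joining(DistanceMatrix(taxa, d * 0, d.copy()))
        for _ in range(3):
            again = neighbor_joining(DistanceMatrix(taxa, d * 0, d.copy()))
            assert write_newick(again) == write_newick(first)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        rng = np.random.default_rng(17)
        for _ in range(5):
            pts = rng.random((7, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            taxa = tuple("T%d" % i for i in range(7))
            mine = neighbor_joining(DistanceMatrix(taxa, d * 0, d))
            buf = io.StringIO()
            sknj(SkDM(d, ids=list(taxa))).write(buf)
            theirs = parse_newick(buf.getvalue())
            assert robinson_foulds(mine, theirs) == 0

    def test_too_few_taxa(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("X", "Y"), d, d))


class TestSupermatrix:
    def test_concatenated_width(self, jtt):
        cfg = ExperimentConfig(gene_count=4, gene_length=30)
        gs = simulate_genome_set(cfg, np.random.default_rng(0), model=jtt)
        sm = concatenate_supermatrix(gs)
        assert sm.alignment.n_sites == 120
        # partition map covers [0, total) without gaps or overlaps
        spans = sorted((s, e) for _, s, e in sm.partitions)
        assert spans[0][0] == 0 and spans[-1][1] == 120
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

    def test_single_family_identity(self, jtt):
        cfg = ExperimentConfig(gene_count=1, gene_length=200)
        gs = simulate_genome_set(cfg, np.random.default_rng(5), model=jtt)
        sm = concatenate_supermatrix(gs)
        t_sm = neighbor_joining(protein_distance_matrix(sm.alignment))
        t_fam = neighbor_joining(protein_distance_matrix(gs.families[0]))
        assert write_newick(t_sm) == write_newick(t_fam)

    def test_gene_tree_count_and_consistency(self, jtt):
        cfg = ExperimentConfig(gene_count=12, gene_length=1500)
        gs = simulate_genome_set(cfg, np.random.default_rng(3), model=jtt)
        trees = gene_tree_set(gs, method="NJ")
        assert len(trees) == 12
        truth = cfg.species_tree()
        matches = sum(robinson_foulds(t, truth) == 0 for t in trees)
        assert matches > 6  # long genes: majority recover the species tree


class TestLikelihood:
    def test_closed_form_single_site(self, jtt):
        aln = Alignment.from_sequences({"X": "A", "Y": "A"}, jtt.alphabet)
        t = parse_newick("(X:0.5,Y:0.7);")
        iA = jtt.alphabet.index("A")
        expected = np.log(jtt.freqs[iA] * jtt.transition_matrix(1.2)[iA, iA])
        assert felsenstein_loglik(t, aln, jtt) == pytest.approx(expected)

    def test_rerooting_invariance(self, jtt):
        rng = np.random.default_rng(2)
        tree = random_tree(rng, 6)
        aln = evolve_alignment(tree, 40, jtt, rng)
        base = felsenstein_loglik(tree, aln, jtt)
        # anchor the traversal at every internal node in turn
        from rnol.tree import PhyloTree
        for node in tree.graph.nodes:
            if tree.graph.degree(node) > 1:
                alt = PhyloTree(tree.graph, node, rooted=False)
                assert felsenstein_loglik(alt, aln, jtt) == pytest.approx(base)

    def test_perturbing_true_branch_lowers_likelihood(self, jtt):
        rng = np.random.default_rng(6)
        t = parse_newick("((A:0.2,B:0.2):0.3,C:0.2,D:0.2);")
        aln = evolve_alignment(t, 5000, jtt, rng)
        base = felsenstein_loglik(t, aln, jtt)
        child, parent = next(
            (c, p) for c, p in t._edges_postorder()
            if t._leafset_below(c, p) == frozenset("AB"))
        t.graph.edges[child, parent]["length"] = 3.0
        assert felsenstein_loglik(t, aln, jtt) < base

    def test_empty_alignment_rejected(self, jtt):
        aln = Alignment(("X", "Y"), np.empty((2, 0), dtype=np.uint8),
                        jtt.alphabet)
        with pytest.raises(ValueError):
            felsenstein_loglik(parse_newick("(X:1,Y:1);"), aln, jtt)


class TestExhaustiveML:
    def test_topology_counts(self):
        assert len(enumerate_unrooted_topologies("ABCD")) == 3
        assert len(enumerate_unrooted_topologies("ABCDE")) == 15
        assert len(enumerate_unrooted_topologies("ABCDEF")) == 105

    def test_recovers_long_internal_branch(self, jtt):
        t = parse_newick("((A:0.1,B:0.1):0.5,C:0.1,D:0.1);")
        aln = evolve_alignment(t, 300, jtt, np.random.default_rng(1))
        best = exhaustive_ml_tree(aln, jtt)
        assert write_newick(best).startswith("(A")
        assert robinson_foulds(best, parse_newick("((A,B),C,D);")) == 0

    def test_constant_alignment_deterministic_tie(self, jtt):
        aln = Alignment.from_sequences(
            {t: "AAAA" for t in "WXYZ"}, jtt.alphabet)
        first = exhaustive_ml_tree(aln, jtt)
        second = exhaustive_ml_tree(aln, jtt)
        assert write_newick(first) == write_newick(second)

    def test_agrees_with_nj_on_clean_data(self, jtt):
        t = parse_newick("((A:0.15,B:0.15):0.2,(C:0.15,D:0.15):0.1,E:0.3);")
        aln = evolve_alignment(t, 2000, jtt, np.random.default_rng(12))
        ml = exhaustive_ml_tree(aln, jtt)
        nj = neighbor_joining(protein_distance_matrix(aln))
        assert robinson_foulds(ml, nj) == 0

    def test_scale_cap(self, jtt):
        aln = Alignment.from_sequences(
            {"T%d" % i: "AA" for i in range(9)}, jtt.alphabet)
        with pytest.raises(ValueError, match="NJ|neighbor"):
            exhaustive_ml_tree(aln, jtt)


class TestBootstrapSupport:
    def test_clean_data_high_support(self, jtt):
        t = parse_newick("((A:0.1,B:0.1):0.3,C:0.1,D:0.1);")
        aln = evolve_alignment(t, 1000, jtt, np.random.default_rng(0))
        boot = bootstrap_support(aln, 25, np.random.default_rng(1))
        (bp,) = boot.bipartitions()
        assert bp.support is not None and bp.support > 0.9
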