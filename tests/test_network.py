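import itertools

import numpy as np
import pytest

from rnol.network import (
    ReticulatedNetwork,
    Reticulation,
    assemble_network,
    build_scaffold,
    combined_distance_matrix,
    detect_reticulations,
    read_network_tsv,
    root_on_outgroup,
    scaffold_edges,
    write_network,
    _edge_leafset,
)
from rnol.reconstruct import neighbor_joining, protein_distance_matrix
from rnol.simulate import (
    Alignment,
    ExperimentConfig,
    apply_highway,
    drop_taxon,
    evolve_alignment,
    simulate_genome_set,
    true_ingroup_tree,
)
from rnol.tree import (
    parse_newick,
    restrict_to_taxa,
    robinson_foulds,
    write_newick,
)

from conftest import random_tree


@pytest.fixture(scope="module")
def clean_family(jtt):
    cfg = ExperimentConfig(gene_count=1, gene_length=2000)
    gs = drop_taxon(simulate_genome_set(cfg, np.random.default_rng(3),
                                        model=jtt), "Bp")
    return gs.families[0]


@pytest.fixture(scope="module")
def scaffold(clean_family):
    return build_scaffold([clean_family], root_outgroup={"A"})


class TestBuildScaffold:
    def test_single_partition_equals_family_nj(self, clean_family, scaffold):
        nj = neighbor_joining(protein_distance_matrix(clean_family))
        unrooted = restrict_to_taxa(scaffold, scaffold.taxa)
        assert {bp.key() for bp in scaffold.bipartitions()} >= \
            {bp.key() for bp in nj.bipartitions()} or \
            robinson_foulds(
                neighbor_joining(protein_distance_matrix(clean_family)),
                _unroot(scaffold)) == 0

    def test_rooted_on_outgroup_pendant_edge(self, scaffold):
        root_children = list(scaffold.graph.neighbors(scaffold.root))
        assert scaffold.rooted and len(root_children) == 2
        sides = [scaffold._leafset_below(c, scaffold.root)
                 for c in root_children]
        assert frozenset({"A"}) in sides

    def test_equal_mixed_partitions_same_topology(self, jtt, clean_family):
        # protein partition + nucleotide partition on the same tree
        from rnol.models import k2p_model
        k2p = k2p_model()
        tree = true_ingroup_tree(0.05)
        nt = evolve_alignment(tree, 2000, k2p, np.random.default_rng(10))
        sc_mixed = build_scaffold([clean_family, nt], root_outgroup={"A"})
        sc_prot = build_scaffold([clean_family], root_outgroup={"A"})
        assert robinson_foulds(_unroot(sc_mixed), _unroot(sc_prot)) == 0

    def test_unseparable_outgroup_raises(self, clean_family):
        with pytest.raises(ValueError, match="separable"):
            build_scaffold([clean_family], root_outgroup={"A", "F"})

    def test_combined_distance_weights_by_length(self, jtt):
        a1 = Alignment.from_sequences({"W": "ARND", "X": "ARND",
                                       "Y": "ARND", "Z": "ARND"},
                                      jtt.alphabet)
        a2 = Alignment.from_sequences({"W": "AA", "X": "AC",
                                       "Y": "AA", "Z": "AA"}, jtt.alphabet)
        dm = combined_distance_matrix([a1, a2])
        iw, ix = dm.taxa.index("W"), dm.taxa.index("X")
        # W-X: p=0 over 4 sites, p=0.5 over 2 sites -> weighted p = 1/6
        assert dm.p[iw, ix] == pytest.approx(1.0 / 6.0)


def _unroot(tree):
    from rnol.tree import PhyloTree
    g = tree.graph.copy()
    root = tree.root
    if g.degree(root) == 2:
        u, v = g.neighbors(root)
        lu = g.edges[root, u].get("length")
        lv = g.edges[root, v].get("length")
        attrs = {}
        if lu is not None and lv is not None:
            attrs["length"] = lu + lv
        g.remove_node(root)
        g.add_edge(u, v, **attrs)
        root = u if g.degree(u) > 1 else v
    return PhyloTree(g, root, rooted=False)


class TestDetectReticulations:
    def test_agreeing_gene_tree_empty(self, scaffold, clean_family):
        gt = neighbor_joining(protein_distance_matrix(clean_family))
        assert detect_reticulations(scaffold, gt) == []

    def test_f_beside_b_yields_f_candidate(self, scaffold):
        gt = parse_newick("((A,(B,F)),C,(D,E));")
        (cand,) = detect_reticulations(scaffold, gt)
        assert cand.moved == frozenset({"F"})
        edges = scaffold_edges(scaffold)
        assert _edge_leafset(scaffold, edges[cand.target_edge]) == \
            frozenset({"F"})
        assert _edge_leafset(scaffold, edges[cand.source_edge]) == \
            frozenset({"B"})

    def test_two_displaced_leaves_match_prune_oracle(self, scaffold):
        # B regrafted beside F and D beside A: two independent displacements
        gt = parse_newick("(((B,F),E),(A,D),C);")
        cands = detect_reticulations(scaffold, gt)
        moved = {frozenset(c.moved) for c in cands}
        assert moved == {frozenset({"B"}), frozenset({"D"})}
        # oracle: the displaced union must be a minimal prune set
        minimal = []
        for r in (1, 2):
            if minimal:
                break
            for combo in itertools.combinations(sorted(scaffold.taxa), r):
                keep = scaffold.taxa - set(combo)
                r1 = restrict_to_taxa(scaffold, keep)
                r2 = restrict_to_taxa(gt, keep)
                if {b.key() for b in r1.bipartitions()} == \
                   {b.key() for b in r2.bipartitions()}:
                    minimal.append(frozenset(combo))
        assert frozenset().union(*moved) in minimal

    def test_small_shared_set_skipped(self, scaffold):
        gt = parse_newick("(A,B,C);")
        assert detect_reticulations(scaffold, gt) == []

    def test_weakly_supported_conflict_discarded(self, scaffold):
        gt = parse_newick("((A,(B,F)0.3)0.4:1,C,(D,E)0.2:1);")
        assert detect_reticulations(scaffold, gt, s=0.9) == []

    def test_unknown_taxon_rejected(self, scaffold):
        gt = parse_newick("((A,(B,ZZ)),C,(D,E));")
        with pytest.raises(ValueError, match="missing"):
            detect_reticulations(scaffold, gt)


class TestAssembleNetwork:
    def test_no_candidates_scaffold_alone(self, scaffold):
        net = assemble_network(scaffold, {})
        assert net.reticulations == []

    def test_recurrent_candidate_kept_with_evidence(self, scaffold):
        gt = parse_newick("((A,(B,F)),C,(D,E));")
        cands = detect_reticulations(scaffold, gt)
        net = assemble_network(scaffold, {i: cands for i in range(48)},
                               min_family_support=5)
        (r,) = net.reticulations
        assert len(r.evidence) == 48
        assert r.moved == frozenset({"F"})

    def test_below_min_support_dropped(self, scaffold):
        gt = parse_newick("((A,(B,F)),C,(D,E));")
        cands = detect_reticulations(scaffold, gt)
        net = assemble_network(scaffold, {i: cands for i in range(3)},
                               min_family_support=5)
        assert net.reticulations == []

    def test_network_minus_reticulations_is_scaffold(self, scaffold):
        gt = parse_newick("((A,(B,F)),C,(D,E));")
        cands = detect_reticulations(scaffold, gt)
        net = assemble_network(scaffold, {i: cands for i in range(10)},
                               min_family_support=2)
        assert write_newick(net.scaffold) == write_newick(scaffold)


class TestHighwayRecovery:
    def test_highway_surfaces_as_f_reticulation(self, jtt):
        """A simulated highway at h=0.45 should assemble into a network
        with a reticulation moving F, sourced on the B lineage, in most
        replicates."""
        hits = 0
        n_rep = 3
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            cfg = ExperimentConfig(gene_count=60, gene_length=300)
            gs = simulate_genome_set(cfg, rng, model=jtt)
            gs = apply_highway(gs, "Bp", "F", 0.45, rng)
            gs = drop_taxon(gs, "Bp")
            sc = root_on_outgroup(true_ingroup_tree(0.05), {"A"})
            from rnol.reconstruct import gene_tree_set
            trees = gene_tree_set(gs, method="NJ")
            cands = {i: detect_reticulations(sc, t)
                     for i, t in enumerate(trees)}
            net = assemble_network(sc, cands, min_family_support=5)
            edges = scaffold_edges(sc)
            for r in net.reticulations:
                if r.moved == frozenset({"F"}) and \
                        _edge_leafset(sc, edges[r.source_edge]) <= \
                        frozenset({"B"}):
                    hits += 1
                    break
        assert hits >= 2

    def test_clean_genomes_yield_no_reticulations(self, jtt):
        empty = 0
        n_rep = 4
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            cfg = ExperimentConfig(gene_count=20, gene_length=1500)
            gs = drop_taxon(simulate_genome_set(cfg, rng, model=jtt), "Bp")
            sc = root_on_outgroup(true_ingroup_tree(0.05), {"A"})
            from rnol.reconstruct import gene_tree_set
            trees = gene_tree_set(gs, method="NJ")
            cands = {i: detect_reticulations(sc, t, s=0.95)
                     for i, t in enumerate(trees)}
            net = assemble_network(sc, cands, min_family_support=5)
            if not net.reticulations:
                empty += 1
        assert empty >= 3


class TestSerialisation:
    def _network(self, scaffold, n_fams=10):
        gt = parse_newick("((A,(B,F)),C,(D,E));")
        cands = detect_reticulations(scaffold, gt)
        return assemble_network(scaffold, {i: cands for i in range(n_fams)},
                                min_family_support=2)

    def test_scaffold_only_round_trip(self, scaffold):
        net = ReticulatedNetwork(scaffold, [])
        enewick, tsv = write_network(net)
        assert "#H" not in enewick
        assert read_network_tsv(tsv) == net

    def test_single_reticulation_labels(self, scaffold):
        net = self._network(scaffold)
        enewick, tsv = write_network(net)
        assert enewick.count("#H1") == 2  # target label + source leaf
        assert sum(1 for line in tsv.splitlines()
                   if "\treticulation\t" in line) == 1

    def test_round_trip_random_fixtures(self, scaffold):
        rng = np.random.default_rng(0)
        edges = list(scaffold_edges(scaffold))
        for _ in range(10):
            k = rng.integers(0, 3)
            retics = []
            used = set()
            for _ in range(k):
                src, tgt = rng.choice(edges, size=2, replace=False)
                tgt = int(tgt)
                leaves = _edge_leafset(scaffold,
                                       scaffold_edges(scaffold)[tgt])
                if not leaves or tgt in used:
                    continue
                used.add(tgt)
                retics.append(Reticulation(int(src), tgt, leaves,
                                           ((1, 0.9), (2, None))))
            net = ReticulatedNetwork(scaffold, retics)
            _, tsv = write_network(net)
            assert read_network_tsv(tsv) == net
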