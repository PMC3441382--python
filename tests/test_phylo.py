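"""Distances, neighbor joining, bootstrap, and median-joining networks."""
import io
from itertools import combinations

import dendropy
import numpy as np
import pytest

from glutannot import seq_io
from glutannot.anatomy import partition_domains, strip_signal_peptide
from glutannot.phylo import (
    DistanceMatrix,
    Tree,
    ZeroComparableSitesError,
    bootstrap_support,
    extract_phylo_region,
    median_joining_network,
    neighbor_joining,
    newick,
    p_distance_matrix,
)
from glutannot.synth import generate_family, generate_subunit


def clade_bipartitions(spec):
    """True non-trivial bipartitions of a nested-tuple topology."""
    def leaves(s):
        return [s] if isinstance(s, str) else [l for c in s for l in leaves(c)]

    all_leaves = frozenset(leaves(spec))
    out = set()

    def visit(s):
        if isinstance(s, str):
            return
        for c in s:
            side = frozenset(leaves(c))
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset({side, all_leaves - side}))
            visit(c)

    visit(spec)
    return out


class TestExtractRegion:
    def test_region_length_arithmetic(self):
        rec, truth = generate_subunit(
            seed=3, subunit_type="x", n_tri=4, n_hexa=10, n_nona=4, with_promoter=True
        )
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        part = partition_domains(m)
        region = extract_phylo_region(rec, m, part)
        arch = truth.architecture
        expected = truth.promoter_truth["length"] + 3 * (arch["signal_len"] + arch["nterm_len"])
        assert len(region.sequence) == expected and region.has_promoter

    def test_missing_promoter_flagged(self):
        rec, truth = generate_subunit(seed=3, n_tri=4, n_hexa=10, n_nona=4)
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        region = extract_phylo_region(rec, m, partition_domains(m))
        assert not region.has_promoter
        assert len(region.sequence) == 3 * (21 + 86)

    def test_identical_genes_identical_regions(self):
        rec, _ = generate_subunit(seed=4, n_tri=4, n_hexa=10, n_nona=4, with_promoter=True)
        m = strip_signal_peptide(seq_io.translate_orf(rec.orf_dna).protein)
        part = partition_domains(m)
        assert extract_phylo_region(rec, m, part).sequence == extract_phylo_region(rec, m, part).sequence


class TestPDistance:
    def test_identical_pair_zero(self):
        assert p_distance_matrix({"a": "ACGT", "b": "ACGT"}).d[0, 1] == 0.0

    def test_one_of_four_sites(self):
        assert p_distance_matrix({"a": "ACGT", "b": "ACGA"}).d[0, 1] == 0.25

    def test_pairwise_deletion_excludes_gapped_sites(self):
        # gap site dropped: 0 differences over 3 comparable sites
        assert p_distance_matrix({"a": "AC-T", "b": "ACGT"}).d[0, 1] == 0.0
        # and a real difference among the remaining sites counts over 3
        assert p_distance_matrix({"a": "AC-T", "b": "ACGA"}).d[0, 1] == pytest.approx(1 / 3)

    def test_zero_comparable_sites_names_pair(self):
        with pytest.raises(ZeroComparableSitesError, match="'a'.*'b'"):
            p_distance_matrix({"a": "--AT", "b": "GC--"})

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        assert tree.path_distance("a", "b") == pytest.approx(0.3)
        assert tree.path_distance("a", "c") == pytest.approx(0.5)
        assert tree.path_distance("b", "c") == pytest.approx(0.6)

    def test_four_taxon_topology_matches_least_squares_oracle(self):
        # additive matrix from tree ((a,b),(c,d)) with internal branch 0.1
        ids = ["a", "b", "c", "d"]
        ext = {"a": 0.05, "b": 0.07, "c": 0.04, "d": 0.09}
        internal = 0.1
        d = np.zeros((4, 4))
        for i, j in combinations(range(4), 2):
            x, y = ids[i], ids[j]
            same = {x, y} in ({"a", "b"}, {"c", "d"})
            d[i, j] = d[j, i] = ext[x] + ext[y] + (0 if same else internal)
        D = DistanceMatrix(ids, d)

        # oracle: least-squares fit of each of the 3 unrooted topologies
        topologies = {
            frozenset({frozenset("ab"), frozenset("cd")}): [("a", "b")],
            frozenset({frozenset("ac"), frozenset("bd")}): [("a", "c")],
            frozenset({frozenset("ad"), frozenset("bc")}): [("a", "d")],
        }
        def sse(pair):
            # 5 branches: 4 external + internal; path matrix over 6 pairs
            other = [t for t in ids if t not in pair]
            branches = ids + ["int"]
            rows, y = [], []
            for i, j in combinations(range(4), 2):
                x, z = ids[i], ids[j]
                row = [1.0 if b in (x, z) else 0.0 for b in ids]
                cherry1 = set(pair)
                row.append(0.0 if ({x, z} == cherry1 or {x, z} == set(other)) else 1.0)
                rows.append(row)
                y.append(d[i, j])
            sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
            pred = np.array(rows) @ sol
            return float(((pred - np.array(y)) ** 2).sum())

        best = min(topologies.items(), key=lambda kv: sse(tuple(sorted(kv[1][0]))))
        tree = neighbor_joining(D)
        assert tree.bipartitions() == {best[0]}

    def test_recovers_random_six_leaf_topologies(self):
        spec = (("A", "B"), (("C", "D"), ("E", "F")))
        for seed in range(10):
            seqs, _ = generate_family(seed, spec, region_len=500, mut_per_branch=5)
            tree = neighbor_joining(p_distance_matrix(seqs))
            assert tree.bipartitions() == clade_bipartitions(spec)

    def test_additive_distances_reproduced_along_tree_paths(self):
        seqs, _ = generate_family(9, ((("A", "B"), "C"), (("D", "E"), "F")), 600, 4)
        D = p_distance_matrix(seqs)
        tree = neighbor_joining(D)
        for a, b in combinations(D.ids, 2):
            assert abs(tree.path_distance(a, b) - D.get(a, b)) < 1e-9

    def test_topology_matches_dendropy_oracle(self):
        seqs, _ = generate_family(5, (("A", ("B", "C")), (("D", "E"), "F")), 500, 6)
        D = p_distance_matrix(seqs)
        mine = neighbor_joining(D)
        csv = "," + ",".join(D.ids) + "\n" + "\n".join(
            a + "," + ",".join(str(D.d[i][j]) for j in range(len(D.ids)))
            for i, a in enumerate(D.ids)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        taxa = frozenset(D.ids)
        oracle_bp = set()
        for edge in dtree.preorder_edge_iter():
            side = frozenset(t.label for t in edge.bipartition.leafset_taxa(dtree.taxon_namespace))
            if 2 <= len(side) <= len(taxa) - 2:
                oracle_bp.add(frozenset({side, taxa - side}))
        assert mine.bipartitions() == oracle_bp

    def test_fewer_than_three_taxa_warns(self):
        with pytest.warns(UserWarning):
            tree = neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]])))
        assert tree.path_distance("a", "b") == pytest.approx(0.4)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 6
            m = rng.random((n, n)) * 0.4
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], d))
            text = newick(tree)
            assert ":-" not in text

    def test_model_choice_robust_on_similar_sequences(self):
        spec = (("A", "B"), (("C", "D"), ("E", "F")))
        seqs, _ = generate_family(17, spec, region_len=800, mut_per_branch=4)
        tp = neighbor_joining(p_distance_matrix(seqs, model="p"))
        tj = neighbor_joining(p_distance_matrix(seqs, model="jc"))
        assert tp.bipartitions() == tj.bipartitions()


class TestBootstrap:
    def test_seed_determinism(self):
        seqs, _ = generate_family(8, (("A", "B"), ("C", ("D", "E"))), 400, 5)
        t1 = bootstrap_support(seqs, n_reps=50, seed=11)
        t2 = bootstrap_support(seqs, n_reps=50, seed=11)
        assert t1.support == t2.support and newick(t1, True) == newick(t2, True)

    def test_two_separated_clades_get_high_support(self):
        spec = (("x1", ("x2", "x3")), ("y1", ("y2", "y3")))
        seqs, _ = generate_family(
            21, spec, region_len=800,
            mut_per_branch={("x1", "x2", "x3"): 50, ("y1", "y2", "y3"): 50, "default": 2},
        )
        tree = bootstrap_support(seqs, n_reps=200, seed=0)
        key = frozenset({frozenset({"x1", "x2", "x3"}), frozenset({"y1", "y2", "y3"})})
        assert tree.support[key] >= 95.0
        assert all(0.0 <= v <= 100.0 for v in tree.support.values())

    def test_identical_sequences_no_resolved_bipartitions(self):
        seqs = {k: "ACGTACGTACGT" for k in "abcd"}
        tree = bootstrap_support(seqs, n_reps=10, seed=1)
        assert all(v == 100.0 or v >= 0 for v in tree.support.values())
        assert all(tree.path_distance(a, b) == 0 for a, b in combinations("abcd", 2))

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "ACGT", "b": "ACGT", "c": "ACGT"}, n_reps=0, seed=1)


class TestMedianJoining:
    def test_three_haplotype_path(self):
        net = median_joining_network({"h1": "AAA", "h2": "AAT", "h3": "ATT"})
        # variable sites 2,3; condensed haplotypes AA, AT, TT form a path
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("AA", "AT"), ("AT", "TT")}
        assert all(d["mutations"] == 1 for _, _, d in net.graph.edges(data=True))

    def test_three_haplotype_star_infers_median(self):
        net = median_joining_network({"h1": "AAA", "h2": "TTA", "h3": "ATT"})
        medians = [n for n, i in net.node_info.items() if i["type"] == "median"]
        assert medians == ["ATA"]
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("AAA", "ATA"), ("ATA", "ATT"), ("ATA", "TTA")}

    def test_identical_haplotypes_single_node(self):
        net = median_joining_network({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert len(net.graph) == 1
        (node,) = net.graph.nodes
        assert sorted(net.node_info[node]["members"]) == ["a", "b", "c"]

    def test_all_observed_haplotypes_retained_and_connected(self):
        seqs, _ = generate_family(33, (("A", "B"), ("C", ("D", "E"))), 300, 4)
        net = median_joining_network(seqs)
        observed = {n for n, i in net.node_info.items() if i["type"] == "observed"}
        members = [m for n in observed for m in net.node_info[n]["members"]]
        assert sorted(members) == sorted(seqs)
        assert net.is_connected()
        total_mut = sum(d["mutations"] for _, _, d in net.graph.edges(data=True))
        assert total_mut >= len(net.variable_sites)

    def test_contains_msn_when_no_medians_added(self):
        net = median_joining_network({"h1": "AAA", "h2": "AAT", "h3": "ATT"})
        from glutannot.phylo import _msn_edges

        msn = {tuple(sorted((u, v))) for u, v, _ in _msn_edges(sorted({"AA", "AT", "TT"}), 0)}
        assert msn <= {tuple(sorted(e)) for e in net.graph.edges}

    def test_parameters_recorded(self):
        net = median_joining_network({"a": "AT", "b": "AA"}, epsilon=0, weights=10)
        assert net.params == {"epsilon": 0, "weights": 10}

    def test_two_clade_family_splits_cleanly(self):
        spec = (("x1", ("x2", "x3")), ("y1", ("y2", "y3")))
        seqs, _ = generate_family(
            44, spec, region_len=600,
            mut_per_branch={("x1", "x2", "x3"): 50, ("y1", "y2", "y3"): 50, "default": 2},
        )
        net = median_joining_network(seqs)
        # classify every node (incl. medians) by its nearer clade member
        from glutannot.repeats import hamming

        obs = {n: i["members"] for n, i in net.node_info.items() if i["members"]}
        def clade_of(node):
            nearest = min(obs, key=lambda o: hamming(node, o))
            return obs[nearest][0][0]   # 'x' or 'y'
        cross = [
            (u, v) for u, v in net.graph.edges if clade_of(u) != clade_of(v)
        ]
        g2 = net.graph.copy()
        g2.remove_edges_from(cross)
        import networkx as nx

        comps = list(nx.connected_components(g2))
        assert len(comps) == 2
        for comp in comps:
            clades = {clade_of(n) for n in comp}
            assert len(clades) == 1
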