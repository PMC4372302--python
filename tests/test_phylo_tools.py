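"""Distances, neighbor joining, independent contrasts, reconciliation."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pytest

from silkgland import synthetic_data as synth
from silkgland.io_formats import SequenceSet, parse_newick, write_newick
from silkgland.phylo_tools import (
    ContrastResult,
    DistanceMatrix,
    default_leaf_map,
    distance_matrix,
    nj_tree,
    p_distance,
    pic,
    pic_correlation,
    reconcile,
    resolve_polytomies,
    tajima_nei_distance,
)


class TestDistances:
    def test_identical_rows_zero(self):
        aln = SequenceSet(records=[("a", "ACGT"), ("b", "ACGT")], alphabet="dna")
        dm = distance_matrix(aln, model="p")
        assert np.allclose(dm.matrix, 0.0)

    def test_p_distance_direct_count(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_tajima_nei_hand_formula(self):
        # 20-site toy pair with two A<->T differences, worked through the
        # published formula: p=0.1, g=(0.3,0.25,0.25,0.2),
        # h = 0.01/(2*0.3*0.2), b = (1-0.255+0.01/h')/2 = 0.4325,
        # d = -0.4325*ln(1-0.1/0.4325)
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACGTACGAACGA"
        assert tajima_nei_distance(a, b) == pytest.approx(0.1137226, abs=1e-6)

    def test_gap_columns_deleted_pairwise(self):
        assert p_distance("AC-T", "ACGT") == 0.0

    def test_saturated_pair_names_taxa(self):
        aln = SequenceSet(
            records=[("x", "AAAAAAAA"), ("y", "TTTTTTTT")], alphabet="dna"
        )
        with pytest.raises(ValueError, match=r"\(x, y\)"):
            distance_matrix(aln, model="tajima_nei")


ADDITIVE = DistanceMatrix(
    taxa=["A", "B", "C", "D"],
    matrix=np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    ),
)


class TestNeighborJoining:
    def test_additive_matrix_recovers_split_and_lengths(self):
        tree = nj_tree(ADDITIVE)
        # AB|CD split with exact branch lengths 1,2,3,4 and internal 1
        newick = write_newick(tree)
        bip = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        assert frozenset("AB") in bip or frozenset("CD") in bip
        pdm = tree.phylogenetic_distance_matrix()
        tn = tree.taxon_namespace
        for a, b, d in [("A", "B", 3), ("C", "D", 7), ("A", "C", 5),
                        ("A", "D", 6), ("B", "C", 6), ("B", "D", 7)]:
            assert pdm.distance(tn.get_taxon(a), tn.get_taxon(b)) == pytest.approx(d, abs=1e-9)

    def test_three_taxa_three_point_equations(self):
        dm = DistanceMatrix(
            taxa=["A", "B", "C"],
            matrix=np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float),
        )
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(taxa=["A", "B"], matrix=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_additive_property_on_random_tree_distances(self, rng):
        # distances taken from a random tree must be reproduced exactly
        taxa = [f"t{i}" for i in range(6)]
        sim = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
            rng=__import__("random").Random(42),
        )
        for leaf, label in zip(sim.leaf_node_iter(), taxa):
            leaf.taxon.label = label
        pdm = sim.phylogenetic_distance_matrix()
        tn = sim.taxon_namespace
        mat = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                d = pdm.distance(tn.get_taxon(taxa[i]), tn.get_taxon(taxa[j]))
                mat[i, j] = mat[j, i] = d
        tree = nj_tree(DistanceMatrix(taxa=taxa, matrix=mat))
        out_pdm = tree.phylogenetic_distance_matrix()
        out_tn = tree.taxon_namespace
        for i in range(6):
            for j in range(i + 1, 6):
                got = out_pdm.distance(out_tn.get_taxon(taxa[i]), out_tn.get_taxon(taxa[j]))
                assert got == pytest.approx(mat[i, j], abs=1e-9)

    def test_recovers_species_topology_from_simulated_codons(self, species_tree):
        aln = synth.simulate_codon_alignment(species_tree, 500, 0.3, 2.0, seed=12)
        seqs = SequenceSet(
            records=list(zip(aln.taxa, aln.rows)), alphabet="dna"
        )
        tree = nj_tree(distance_matrix(seqs, model="tajima_nei"))
        # check the nested Saturniidae splits as unrooted bipartitions
        bip = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        full = set(synth.SPECIES)
        for clade in (
            {"A.pernyi", "A.yamamai"},
            {"A.pernyi", "A.yamamai", "A.assama"},
            {"A.pernyi", "A.yamamai", "A.assama", "Ac.selene"},
            {"A.pernyi", "A.yamamai", "A.assama", "Ac.selene", "R.newara"},
        ):
            assert frozenset(clade) in bip or frozenset(full - clade) in bip


class TestPIC:
    def test_hand_recursion_three_taxa(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        res = pic(tree, {"A": 1.0, "B": 3.0, "C": 6.0})
        assert res.contrasts[0] == pytest.approx(-2 / np.sqrt(2))
        assert res.node_values[0] == pytest.approx(2.0)
        assert res.contrasts[1] == pytest.approx(-4 / np.sqrt(3.5))

    def test_constant_trait_zero_contrasts(self, species_tree):
        res = pic(species_tree, {s: 5.0 for s in synth.SPECIES})
        assert np.allclose(res.contrasts, 0.0)
        assert len(res.contrasts) == 6  # leaves - 1 on a bifurcating tree

    def test_star_limit_approaches_plain_differences(self):
        for eps in (1.0, 1e-3, 1e-6):
            tree = parse_newick(f"((A:1,B:1):{eps},C:1);")
            res = pic(tree, {"A": 0.0, "B": 2.0, "C": 4.0})
            if eps == 1e-6:
                # internal branch ~0: second contrast ~ (mean(A,B)-C)/sqrt(1.5)
                assert res.contrasts[1] == pytest.approx(
                    (1.0 - 4.0) / np.sqrt(1.5), abs=1e-4
                )

    def test_polytomy_rejected_and_resolvable(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytomy"):
            pic(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        fixed = resolve_polytomies(tree)
        res = pic(fixed, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(res.contrasts) == 2

    def test_matches_ape_pic_reference(self, species_tree):
        trait = {
            "A.pernyi": 1.2, "A.yamamai": 3.4, "A.assama": 0.7,
            "Ac.selene": 2.2, "R.newara": 5.1, "S.cynthia": 0.3, "B.mori": 1.9,
        }
        ours = sorted(abs(c) for c in pic(species_tree, trait).contrasts)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(ape))
            t <- read.tree(text='{write_newick(species_tree)}')
            x <- c({', '.join(f"'{k}'={v}" for k, v in trait.items())})
            cat(sort(abs(pic(x[t$tip.label], t))), sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        theirs = sorted(float(x) for x in out.stdout.split())
        assert np.allclose(ours, theirs, atol=1e-6)


class TestPICCorrelation:
    def test_identical_traits_perfect_correlation(self, species_tree):
        trait = {s: float(i) for i, s in enumerate(synth.SPECIES)}
        res = pic_correlation(species_tree, trait, trait)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self, species_tree):
        const = {s: 2.0 for s in synth.SPECIES}
        varying = {s: float(i) for i, s in enumerate(synth.SPECIES)}
        res = pic_correlation(species_tree, const, varying)
        assert res.zero_variance and res.p == 1.0

    def test_sign_flip_of_one_trait_flips_r(self, species_tree):
        x = {s: float(i) for i, s in enumerate(synth.SPECIES)}
        y = {s: float(i**2) for i, s in enumerate(synth.SPECIES)}
        neg_y = {k: -v for k, v in y.items()}
        a = pic_correlation(species_tree, x, y)
        b = pic_correlation(species_tree, x, neg_y)
        assert a.r == pytest.approx(-b.r)
        assert a.p == pytest.approx(b.p)

    def test_null_brownian_rejection_near_alpha(self, species_tree, rng):
        # independent Brownian traits: the origin-constrained t-test is
        # exact, so rejection at alpha=0.05 stays near 0.05
        def brownian():
            vals = {}
            node_state = {id(species_tree.seed_node): 0.0}
            for node in species_tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                parent = node_state[id(node.parent_node)]
                state = parent + rng.normal(0, np.sqrt(node.edge.length))
                node_state[id(node)] = state
                if node.is_leaf():
                    vals[node.taxon.label] = state
            return vals

        reps = 400
        rejected = sum(
            pic_correlation(species_tree, brownian(), brownian()).p < 0.05
            for _ in range(reps)
        )
        assert 0.02 <= rejected / reps <= 0.09


class TestReconciliation:
    SP = parse_newick("(A,B);")

    def test_congruent_tree_no_events(self):
        g = parse_newick("(f|A|1,f|B|1);")
        res = reconcile(g, self.SP, default_leaf_map(g))
        assert res.total_duplications == 0
        assert res.total_losses == 0

    def test_root_duplication_two_full_copies(self):
        g = parse_newick("((f|A|1,f|B|1),(f|A|2,f|B|2));")
        res = reconcile(g, self.SP, default_leaf_map(g))
        assert res.total_duplications == 1
        assert res.duplications == {"A|B": 1}
        assert res.total_losses == 0

    def test_duplication_with_loss(self):
        g = parse_newick("(f|A|1,(f|A|2,f|B|1));")
        res = reconcile(g, self.SP, default_leaf_map(g))
        assert res.total_duplications == 1
        assert res.losses == {"B": 1}

    def test_leaf_mapping_enforced(self):
        g = parse_newick("(f|A|1,f|Z|1);")
        with pytest.raises(ValueError, match="Z"):
            reconcile(g, self.SP, default_leaf_map(g))

    def test_gene_leaves_map_to_own_species(self, species_tree):
        _, gene_trees, _ = synth.simulate_families(species_tree, 5, 0.1, 0.0, seed=4)
        for gt in gene_trees:
            res = reconcile(gt, species_tree, default_leaf_map(gt))
            for leaf in gt.leaf_node_iter():
                assert res.mapping[leaf.taxon.label] == leaf.taxon.label.split("|")[1]

    def test_loss_free_simulation_duplications_recovered(self, species_tree):
        _, gene_trees, truth = synth.simulate_families(
            species_tree, 80, dup_rate=0.08, loss_rate=0.0, seed=19
        )
        planted = sum(
            sum(1 for _, kind in ev if kind == "duplication")
            for ev in truth.family_events.values()
        )
        inferred = sum(
            reconcile(gt, species_tree, default_leaf_map(gt)).total_duplications
            for gt in gene_trees
        )
        assert planted > 0
        assert inferred == planted
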