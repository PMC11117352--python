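import numpy as np
import pytest

from tetraltr import synth_genome as sg
from tetraltr.classify import (
    Cluster,
    assign_family,
    build_consensus,
    greedy_cluster,
    nj_tree,
    pairwise_identity,
    refine_ltr_boundaries,
)
from tetraltr.seq_core import GenomeSequence

from .conftest import random_dna
from .oracles import greedy_cluster_oracle

EXAMPLE_SCORING = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -2}


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_all_mismatch(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_single_mismatch_example(self):
        ident = pairwise_identity(
            "ACGTACGT", "ACGAACGT", method="affine", scoring=EXAMPLE_SCORING
        )
        assert ident == pytest.approx(87.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_edlib_matches_affine_for_substitution_divergence(self):
        a = random_dna(3000, seed=1)
        rng = np.random.default_rng(2)
        b = "".join(
            rng.choice([c for c in "ACGT" if c != x]) if rng.random() < 0.05 else x
            for x in a
        )
        assert pairwise_identity(a, b, method="edlib") == pytest.approx(
            pairwise_identity(a, b, method="affine"), abs=0.2
        )

    def test_unrelated_long_dna_below_cluster_threshold(self):
        a, b = random_dna(5000, seed=3), random_dna(5000, seed=4)
        assert pairwise_identity(a, b) < 50.0


class _Stub:
    def __init__(self, sid, length):
        self.id = sid
        self.residues = "A" * length

    def __len__(self):
        return len(self.residues)


def _matrix_identity_fn(ident):
    def fn(a, b):
        return ident[(min(a.id, b.id), max(a.id, b.id))]

    return fn


class TestGreedyCluster:
    def test_documented_example(self):
        ident = {("A", "B"): 60.0, ("A", "C"): 30.0, ("B", "C"): 28.0}
        seqs = [_Stub("A", 100), _Stub("B", 90), _Stub("C", 80)]
        clusters = greedy_cluster(seqs, 50.0, _matrix_identity_fn(ident))
        assert [sorted(c.member_ids) for c in clusters] == [["A", "B"], ["C"]]

    def test_singleton(self):
        assert greedy_cluster([_Stub("A", 10)], 50.0, lambda a, b: 0.0)[0].size == 1

    def test_boundary_exactly_threshold_joins(self):
        seqs = [_Stub("A", 100), _Stub("B", 90)]
        clusters = greedy_cluster(seqs, 50.0, lambda a, b: 50.0)
        assert len(clusters) == 1

    def test_matches_definition_oracle_on_random_suite(self):
        """Library greedy clustering equals the independent by-definition
        oracle on every instance of a fixed random suite (n <= 6)."""
        rng = np.random.default_rng(77)
        for trial in range(30):
            n = int(rng.integers(2, 7))
            ids = [f"s{i}" for i in range(n)]
            lengths = {sid: int(rng.integers(50, 150)) for sid in ids}
            ident = {}
            for i in range(n):
                for j in range(i + 1, n):
                    ident[(f"s{i}", f"s{j}")] = float(rng.uniform(0, 100))
            seqs = [_Stub(sid, lengths[sid]) for sid in ids]
            got = greedy_cluster(seqs, 50.0, _matrix_identity_fn(ident))
            want = greedy_cluster_oracle(ids, lengths, ident, 50.0)
            assert [c.member_ids for c in got] == want
            # partition property
            flat = [m for c in got for m in c.member_ids]
            assert sorted(flat) == sorted(ids)


class TestBuildConsensus:
    def test_identical_members(self):
        s = GenomeSequence("a", "ACGTTGCA")
        assert build_consensus([s, s, s]).residues == "ACGTTGCA"

    def test_column_majority(self):
        seqs = [
            GenomeSequence("a", "ACGT"),
            GenomeSequence("b", "ACGA"),
            GenomeSequence("c", "ACGT"),
        ]
        assert build_consensus(seqs).residues == "ACGT"

    def test_tie_breaks_lexicographic(self):
        seqs = [
            GenomeSequence("a", "ACGTACGT"),
            GenomeSequence("b", "ACGTACGT"),
            GenomeSequence("c", "ACCTACGT"),
            GenomeSequence("d", "ACCTACGT"),
        ]
        # column 2 splits 2 G / 2 C -> lexicographically smallest base (C)
        assert build_consensus(seqs).residues == "ACCTACGT"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            build_consensus([])


class TestRefineLtrBoundaries:
    def test_large_cluster_recalls_template_ltr(self, clustered_genome, models):
        """Clusters of 3 copies from one template refine LTR lengths to
        within 10 bp of the template's LTR length."""
        from tetraltr.pipeline import run_pipeline

        out = run_pipeline(clustered_genome.genome, models=models, classify=True, date_elements=False)
        lens = {t.name: t.ltr_length for t in sg.default_templates()}
        assert len(out.clusters) == 3
        by_family = {a.family: cl for cl, a in zip(out.clusters, out.assignments)}
        expect = {"V-clade": lens["V-clade1"], "Gmr": lens["Gmr1"], "Epsilon retrovirus": lens["Epsilon2"]}
        for fam, cl in by_family.items():
            assert cl.size == 3
            assert cl.ltr5 is not None and cl.ltr3 is not None
            got = cl.ltr5[1] - cl.ltr5[0]
            assert abs(got - expect[fam]) <= 10

    def test_singleton_adopts_defined_ltr(self, templates):
        big = sg.build_template_consensus(templates["V-clade1"], seed=1)
        copies = [
            sg.mutate_copy(big.sequence, 1.0, seed=s)[0] for s in range(3)
        ]
        big_cluster = Cluster("c0", ["m0", "m1", "m2"], build_consensus(
            [GenomeSequence(f"m{i}", c.residues) for i, c in enumerate(copies)], "c0"
        ))
        # singleton from the same family at ~85% identity to the defined LTR
        single, _, _ = sg.mutate_copy(big.sequence, 8.0, seed=9)
        small_cluster = Cluster("c1", ["s0"], GenomeSequence("c1", single.residues))
        refined = refine_ltr_boundaries([big_cluster, small_cluster])
        assert refined[0].ltr5 is not None
        assert refined[1].ltr5 is not None and not refined[1].boundary_flagged

    def test_singleton_without_match_is_flagged(self):
        lone = Cluster("c0", ["x"], GenomeSequence("c0", random_dna(5000, seed=5)))
        refined = refine_ltr_boundaries([lone])
        assert refined[0].boundary_flagged


class TestAssignFamily:
    def test_generator_seeded_cluster_fused_layout(self, templates, models):
        b = sg.build_template_consensus(templates["Gmr1"], seed=2)
        cl = Cluster("g", ["g"], b.sequence)
        a = assign_family(cl, layout="gag-pol fused", models=models)
        assert (a.family, a.superfamily, a.support) == ("Gmr", "Gypsy", "both")
        assert a.best_identity > 90

    def test_env_layout_forces_erv(self, templates, models):
        b = sg.build_template_consensus(templates["V-clade1"], seed=3)
        cl = Cluster("v", ["v"], b.sequence)
        a = assign_family(cl, layout="gag+pol+env", models=models)
        assert a.superfamily == "ERV"
        assert a.support == "structural" and a.conflict is not None

    def test_no_rt_orf_raises(self, models):
        cl = Cluster("r", ["r"], GenomeSequence("r", random_dna(4000, seed=6)))
        with pytest.raises(ValueError):
            assign_family(cl, models=models)


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        nwk = nj_tree(d, ["A", "B", "C"])
        import dendropy

        t = dendropy.Tree.get(data=nwk, schema="newick")
        lens = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lens["A"] == pytest.approx(2.0)
        assert lens["B"] == pytest.approx(3.0)
        assert lens["C"] == pytest.approx(7.0)

    def test_four_taxon_additive_recovery(self):
        """NJ reconstructs the generating topology and branch lengths from
        an additive 4-taxon matrix: ((A:2,B:3):1,C:4,D:5)."""
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        nwk = nj_tree(d, ["A", "B", "C", "D"])
        import dendropy

        t = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        labels = ["A", "B", "C", "D"]
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                j = labels.index(b)
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        assert nj_tree(d, list("ABCD")) == nj_tree(d, list("ABCD"))

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, ["A", "B"])

    def test_matches_skbio_on_random_additive_matrix(self):
        """Cross-check: identical topology to scikit-bio's NJ on a random
        additive matrix derived from a 6-leaf tree."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        # random additive matrix via random leaf-pair path lengths on a tree
        import dendropy

        taxa = [f"t{i}" for i in range(6)]
        base = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6,
            rng=__import__("random").Random(4),
        )
        for i, leaf in enumerate(base.leaf_node_iter()):
            leaf.taxon.label = taxa[i]
        pdm = base.phylogenetic_distance_matrix()
        tx = {x.label: x for x in base.taxon_namespace if x.label in taxa}
        d = np.zeros((6, 6))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d[i, j] = d[j, i] = pdm.distance(tx[a], tx[b])
        ours = nj_tree(d, taxa)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(d, ids=taxa)
        )
        ours_t = skbio.TreeNode.read([ours])
        assert ours_t.compare_rfd(theirs) == 0.0


class TestClusterSeparation:
    def test_nine_templates_separate_and_classify(self, models):
        """All 9 family templates at low divergence: cluster count equals
        template count and every family assignment is correct."""
        from tetraltr.pipeline import run_pipeline

        plans = [
            sg.ImplantPlan(t, n_full=2, age_My=1.0) for t in sg.default_templates()
        ]
        res = sg.implant(700_000, 0.45, plans, seed=55)
        out = run_pipeline(res.genome, models=models, date_elements=False)
        assert len(out.clusters) == 9
        assert sorted(a.family for a in out.assignments) == sorted(
            t.family for t in sg.default_templates()
        )
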