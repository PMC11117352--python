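import numpy as np
import pytest

from tetraltr import synth_genome as sg
from tetraltr.annotate import scan_orfs
from tetraltr.seq_core import GenomeSequence


class TestTemplates:
    def test_vclade1_geometry(self, templates):
        """Representative V-clade template: 5558 bp consensus, 538 bp LTRs
        initially identical, gag 371 aa + pol 1119 aa ORFs."""
        b = sg.build_template_consensus(templates["V-clade1"], seed=5)
        assert len(b.sequence) == 5558
        assert b.ltr5 == (0, 538) and b.ltr3 == (5020, 5558)
        assert (
            b.sequence.residues[0:538] == b.sequence.residues[5020:5558]
        )
        names = [n for n, _, _ in b.orfs]
        assert names == ["gag", "pol"]

    def test_encoded_orf_lengths_exact(self, templates):
        b = sg.build_template_consensus(templates["V-clade1"], seed=5)
        orfs = scan_orfs(b.sequence, min_aa=300)
        assert sorted(o.length_aa for o in orfs) == [371, 1119]

    def test_zero_ltr_length_rejected(self):
        with pytest.raises(sg.TemplateError):
            sg.FamilyTemplate("bad", "Gmr", "pol-only", 5000, 0, pol_length=1000)

    def test_oversized_orfs_rejected(self):
        with pytest.raises(sg.TemplateError):
            sg.FamilyTemplate("bad", "Gmr", "pol-only", 4000, 500, pol_length=1200)

    def test_same_seed_is_deterministic(self, templates):
        a = sg.build_template_consensus(templates["Gmr1"], seed=9)
        b = sg.build_template_consensus(templates["Gmr1"], seed=9)
        assert a.sequence.residues == b.sequence.residues

    def test_all_default_templates_buildable(self):
        for t in sg.default_templates():
            b = sg.build_template_consensus(t, seed=1)
            assert len(b.sequence) == t.consensus_length
            assert b.sequence.residues.startswith("TG")
            assert b.sequence.residues.endswith("CA")


class TestMutateCopy:
    def test_age_zero_identity(self):
        g = GenomeSequence("x", "ACGT" * 100)
        m, ts, tv = sg.mutate_copy(g, 0.0, seed=1)
        assert m.residues == g.residues and ts == 0 and tv == 0

    def test_substitution_count_matches_closed_form(self):
        """Mean changed-site count over 200 seeds within 3 SE of the exact
        two-parameter site-difference expectation (1 My, r=1e-8, 10 kb)."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        d = 2 * 1e-8 * 1.0 * 1e6
        P, Q = sg.k2p_site_probabilities(d, sg.DEFAULT_KAPPA)
        expected = 10_000 * (P + Q)
        counts = []
        for s in range(200):
            _, ts, tv = sg.mutate_copy(seq, 1.0, seed=s)
            counts.append(ts + tv)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-9

    def test_large_kappa_gives_only_transitions(self):
        g = GenomeSequence("x", "ACGT" * 500)
        _, ts, tv = sg.mutate_copy(g, 5.0, kappa=1e9, seed=2)
        assert ts > 0 and tv == 0

    def test_protected_orfs_stay_stop_free(self, templates):
        b = sg.build_template_consensus(templates["CsRN1-1"], seed=3)
        protect = [(s, e - 3) for _, s, e in b.orfs]
        m, _, _ = sg.mutate_copy(b.sequence, 8.0, seed=4, protect_orfs=protect)
        orfs = scan_orfs(m, min_aa=1000)
        assert orfs and orfs[0].length_aa >= 1061

    def test_invalid_args(self):
        g = GenomeSequence("x", "ACGT")
        with pytest.raises(ValueError):
            sg.mutate_copy(g, -1.0)
        with pytest.raises(ValueError):
            sg.mutate_copy(g, 1.0, rate_r=0)


class TestImplant:
    def test_zero_plans_pure_background(self):
        res = sg.implant(50_000, 0.5, [], seed=1)
        assert len(res.genome) == 50_000 and res.truth == []

    def test_single_full_copy_bookkeeping(self, templates):
        plan = sg.ImplantPlan(templates["V-clade1"], n_full=1, age_My=0.0,
                              minus_strand_fraction=0.0)
        res = sg.implant(100_000, 0.45, [plan], seed=2)
        assert len(res.truth) == 1
        t = res.truth[0]
        assert t.copy_class == "full" and len(t.ltrs) == 2
        extracted = res.genome.residues[t.interval.start : t.interval.end]
        assert len(extracted) == 5558
        # age 0: the two LTRs are still identical
        ltr5 = res.genome.residues[t.ltrs[0].start : t.ltrs[0].end]
        ltr3 = res.genome.residues[t.ltrs[1].start : t.ltrs[1].end]
        assert ltr5 == ltr3  # identical at insertion time

    def test_class_counts_match_plan(self, templates):
        plans = [
            sg.ImplantPlan(templates["Gmr1"], 3, 2, 1, age_My=0.5),
            sg.ImplantPlan(templates["Mag1"], 2, 1, 1, age_My=1.0),
        ]
        res = sg.implant(400_000, 0.45, plans, seed=3)
        from collections import Counter

        c = Counter(t.copy_class for t in res.truth)
        assert c == {"full": 5, "truncated": 3, "solo_ltr": 2}

    def test_truth_inside_genome_and_classes_partition(self, templates):
        plans = [sg.ImplantPlan(templates["CsRN1-1"], 2, 1, 1, age_My=1.0)]
        res = sg.implant(200_000, 0.4, plans, seed=4)
        for t in res.truth:
            assert 0 <= t.interval.start < t.interval.end <= len(res.genome)
            assert t.copy_class in sg.COPY_CLASSES
            want = 2 if t.copy_class == "full" else 1
            assert len(t.ltrs) == want
            for ltr in t.ltrs:
                assert t.interval.start <= ltr.start < ltr.end <= t.interval.end

    def test_truncated_loses_one_ltr_and_internal(self, templates):
        plan = sg.ImplantPlan(templates["Gmr1"], 0, 1, 0, age_My=0.0)
        res = sg.implant(100_000, 0.45, plan and [plan], seed=5)
        t = res.truth[0]
        full_len = templates["Gmr1"].consensus_length
        ltr = templates["Gmr1"].ltr_length
        internal = full_len - 2 * ltr
        lost = full_len - t.interval.length
        assert lost >= ltr + 0.3 * internal

    def test_no_fit_raises(self, templates):
        plan = sg.ImplantPlan(templates["Gmr1"], n_full=3, age_My=0.0)
        with pytest.raises(sg.PlacementError):
            sg.implant(20_000, 0.45, [plan], seed=6)

    def test_outputs_round_trip(self, templates, tmp_path):
        plan = sg.ImplantPlan(templates["Mag1"], 1, 0, 1, age_My=0.5)
        res = sg.implant(120_000, 0.45, [plan], seed=7)
        paths = sg.write_outputs(res, tmp_path)
        from tetraltr.seq_core import read_fasta, read_gff3

        g = read_fasta(paths["fasta"])[0]
        assert g.residues == res.genome.residues
        recs = read_gff3(paths["gff3"])
        elements = [r for r in recs if r.feature_type == "LTR_retrotransposon"]
        assert len(elements) == len(res.truth)
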