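import numpy as np
import pytest

from tetraltr import synth_genome as sg
from tetraltr.annotate import (
    DdeTriad,
    ElementRecord,
    annotate_element,
    full_length_verdict,
    locate_dde,
    scan_domains,
    scan_orfs,
    type_layout,
)
from tetraltr.ltr_detect import LTRCandidate
from tetraltr.profiles import ProfileHit, best_local_hit
from tetraltr.seq_core import GenomeSequence, Interval, ProteinSequence

from .conftest import random_dna


def _encode(pep: str, seed: int = 0) -> str:
    return sg._encode_protein(pep, np.random.default_rng(seed))


class TestScanOrfs:
    def test_vclade1_pol_orf(self, templates):
        b = sg.build_template_consensus(templates["V-clade1"], seed=2)
        orfs = scan_orfs(b.sequence)
        assert len(orfs) == 1  # gag (371 aa) is below the 500 aa default
        assert orfs[0].length_aa == 1119

    def test_exactly_min_aa_excluded(self):
        rng = np.random.default_rng(4)
        from tetraltr.profiles import AA_ALPHABET

        pep = "M" + "".join(rng.choice(list(AA_ALPHABET), size=499))  # 500 aa
        region = GenomeSequence("r", "TAA" + _encode(pep) + "TAA")
        assert scan_orfs(region, min_aa=500) == []
        assert scan_orfs(region, min_aa=499)[0].length_aa == 500

    def test_random_sequence_has_no_long_orf(self):
        region = GenomeSequence("r", random_dna(2000, seed=8))
        assert scan_orfs(region) == []

    def test_reverse_strand_orf_coordinates(self):
        rng = np.random.default_rng(6)
        from tetraltr.profiles import AA_ALPHABET

        pep = "M" + "".join(rng.choice(list(AA_ALPHABET), size=600))
        from tetraltr.seq_core import revcomp

        fwd = "TAA" + _encode(pep) + "TAA"
        pad = random_dna(90, seed=1)
        region = GenomeSequence("r", pad + revcomp(fwd) + pad)
        orfs = scan_orfs(region)
        assert len(orfs) == 1
        o = orfs[0]
        assert o.interval.strand == "-"
        sub = region.residues[o.interval.start : o.interval.end]
        from tetraltr.seq_core import translate_frame

        assert translate_frame(GenomeSequence("s", revcomp(sub)), 0).residues == pep


class TestScanDomains:
    def test_embedded_consensus_recovered(self, models):
        """A pol ORF built around the RT consensus yields an RT hit covering
        at least 90% of the implanted segment."""
        from tetraltr.families import family_pol_protein

        pol = family_pol_protein("V-clade", 1119)
        p = ProteinSequence("pol", pol)
        hits = scan_domains(p, models)
        rt = [h for h in hits if h.model == "RT"]
        assert rt
        start = pol.index(models["RT"].consensus)
        covered = min(rt[0].protein_end, start + 90) - max(rt[0].protein_start, start)
        assert covered >= 0.9 * 90

    def test_shuffled_protein_no_hits(self, models):
        from tetraltr.families import family_pol_protein

        rng = np.random.default_rng(1)
        pol = family_pol_protein("V-clade", 1119)
        for _ in range(20):
            shuffled = "".join(rng.permutation(list(pol)))
            assert scan_domains(ProteinSequence("s", shuffled), models) == []

    def test_empty_model_list(self):
        assert scan_domains(ProteinSequence("p", "MKLV" * 50), []) == []

    def test_hits_lie_within_protein(self, models):
        from tetraltr.families import family_gagpol_protein

        p = ProteinSequence("gp", family_gagpol_protein("Gmr", 1634))
        for h in scan_domains(p, models):
            assert 0 <= h.protein_start < h.protein_end <= len(p.residues)


def _int_hit(protein: str, models) -> ProfileHit:
    hit = best_local_hit(models["INT"], protein)
    assert hit is not None
    return hit


class TestLocateDde:
    def test_canonical_triad_on_consensus(self, models):
        cons = models["INT"].consensus
        p = ProteinSequence("i", "G" * 10 + cons + "G" * 10)
        triad = locate_dde(p, _int_hit(p.residues, models), models["INT"])
        assert triad is not None
        assert triad.spacing_d2_e == 35 and triad.canonical

    def test_bel_pao_spacing_not_canonical(self, models):
        from tetraltr.families import _int_core, domain_consensus_peptides

        core = _int_core("BEL-PAO", domain_consensus_peptides())
        p = ProteinSequence("i", core)
        triad = locate_dde(p, _int_hit(p.residues, models), models["INT"])
        assert triad is not None
        assert triad.spacing_d2_e == 42 and not triad.canonical

    def test_no_e_after_second_d_absent(self, models):
        cons = list(models["INT"].consensus)
        cons[105] = "K"  # remove the catalytic E; padding holds no other D/E
        p = ProteinSequence("i", "".join(cons))
        hit = best_local_hit(models["INT"], p.residues)
        assert hit is not None
        assert locate_dde(p, hit, models["INT"]) is None

    def test_triad_ordering_invariant(self):
        with pytest.raises(ValueError):
            DdeTriad(10, 5, 40, 35, True)


def _record_with_hits(orf_models: list[set[str]]) -> ElementRecord:
    cand = LTRCandidate(
        Interval("c", 0, 5000), Interval("c", 0, 200), Interval("c", 4800, 5000), 95.0
    )
    orfs = []
    hits = []
    for i, mods in enumerate(orf_models):
        p = ProteinSequence(f"o{i}", "M" + "A" * 600)
        from tetraltr.annotate import OrfAnnotation

        orfs.append(OrfAnnotation(p, 0, Interval("c", 300 + 2000 * i, 2100 + 2000 * i)))
        for m in mods:
            hits.append((i, ProfileHit(m, 0, 50, 99.0)))
    return ElementRecord(cand, orfs, hits)


class TestTypeLayout:
    def test_separate_gag_pol_env(self):
        r = _record_with_hits([{"GAG"}, {"RT", "RH", "INT"}, {"ENV"}])
        assert type_layout(r) == "gag+pol+env"

    def test_fused_gag_pol(self):
        r = _record_with_hits([{"GAG", "RT", "INT"}])
        assert type_layout(r) == "gag-pol fused"

    def test_pol_only(self):
        r = _record_with_hits([{"RT", "RH", "INT"}])
        assert type_layout(r) == "pol-only"

    def test_separate_gag_pol(self):
        r = _record_with_hits([{"GAG"}, {"RT"}])
        assert type_layout(r) == "gag+pol"


class TestFullLengthVerdict:
    def test_all_criteria_met(self):
        r = _record_with_hits([{"RT"}])
        ok, reasons = full_length_verdict(r)
        assert ok and reasons == []

    def test_solo_ltr_missing(self):
        cand = LTRCandidate(
            Interval("c", 0, 200), Interval("c", 0, 200), None, 100.0
        )
        r = ElementRecord(cand)
        ok, reasons = full_length_verdict(r)
        assert not ok and "LTR missing" in reasons

    def test_truth_fixture_verdicts(self, templates, models):
        """10 implants (6 full / 2 truncated / 2 solo) at age 0: verdicts
        reproduce the generator's copy classes exactly."""
        plans = [
            sg.ImplantPlan(templates["V-clade1"], 3, 1, 1, age_My=0.0),
            sg.ImplantPlan(templates["Gmr1"], 3, 1, 1, age_My=0.0),
        ]
        res = sg.implant(500_000, 0.45, plans, seed=31)
        verdicts = []
        for t in res.truth:
            ltrs = sorted(t.ltrs, key=lambda l: l.start)
            if len(ltrs) == 2:
                cand = LTRCandidate(t.interval, ltrs[0], ltrs[1], 100.0)
            else:
                cand = LTRCandidate(
                    Interval(t.interval.contig, ltrs[0].start, ltrs[0].end, t.interval.strand),
                    ltrs[0],
                    None,
                    100.0,
                )
            rec = annotate_element(res.genome, cand, models)
            verdicts.append((t.copy_class, rec.full_length))
        assert sum(full for _, full in verdicts) == 6
        for cls, full in verdicts:
            assert full == (cls == "full")
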