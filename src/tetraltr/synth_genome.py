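"""Synthetic genomes with implanted LTR retrotransposons and known truth.

Elements are built from family templates (consensus length, LTR length,
ORF layout and protein lengths), aged by a two-parameter (transition /
transversion) substitution clock, and implanted into an i.i.d. background of
configurable GC.  Every implant is recorded in a truth table, so detection,
annotation, classification and dating can each be scored against ground
truth.

Clock convention: a copy of age ``t`` My carries an expected divergence of
``K = 2 * r * t * 1e6`` substitutions/site from its template (the molecular
clock ``t = K/2r`` read generatively).  Substitutions are drawn from the
exact Kimura two-parameter site probabilities, so the K2P estimator is
self-inverting on this generator at any divergence.  No indels in v1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import families
from .seq_core import (
    GenomeSequence,
    GffRecord,
    Interval,
    revcomp,
    write_fasta,
    write_gff3,
)

LAYOUTS = ("gag+pol", "gag-pol fused", "gag+pol+env", "pol-only")

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T (ascii)
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}

#: default neutral substitution rate, substitutions/site/year
DEFAULT_RATE_R = 1e-8
#: default transition/transversion rate ratio
DEFAULT_KAPPA = 2.0


class TemplateError(ValueError):
    """Template geometry cannot be realized."""


class PlacementError(RuntimeError):
    """Implants could not be placed without violating spacing constraints."""


@dataclass(frozen=True)
class FamilyTemplate:
    """Geometry of one element family's consensus.

    Lengths follow the tabulated geometry of tetraodontiform LTR
    retrotransposons: consensus 4337-9854 bp, LTRs ~174-1116 bp, with the
    four observed ORF layouts.
    """

    name: str
    family: str
    layout: str
    consensus_length: int
    ltr_length: int
    gag_length: int = 0  # aa; 0 = absent
    pol_length: int = 0  # aa; gag-pol fused length for fused layout
    env_length: int = 0  # aa; 0 = absent
    ltr_motif: bool = True  # TG...CA termini

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise TemplateError(f"unknown layout {self.layout!r}")
        if self.family not in families.FAMILY_TO_SUPERFAMILY:
            raise TemplateError(f"unknown family {self.family!r}")
        if self.ltr_length <= 0:
            raise TemplateError("ltr_length must be positive")
        if self.pol_length <= 0:
            raise TemplateError("pol_length required for every layout")
        needs_gag = self.layout in ("gag+pol", "gag+pol+env")
        if needs_gag and self.gag_length <= 0:
            raise TemplateError(f"layout {self.layout} requires gag_length")
        if self.layout == "gag+pol+env" and self.env_length <= 0:
            raise TemplateError("gag+pol+env layout requires env_length")
        if self._internal_deficit() > 0:
            raise TemplateError(
                f"template {self.name}: ORFs + LTRs exceed consensus_length "
                f"by {self._internal_deficit()} bp"
            )

    def orf_proteins(self) -> list[tuple[str, str]]:
        """(orf name, peptide) pairs encoded by this template, in order."""
        fam = self.family
        if self.layout == "gag-pol fused":
            return [("gag-pol", families.family_gagpol_protein(fam, self.pol_length))]
        orfs = []
        if self.layout in ("gag+pol", "gag+pol+env"):
            orfs.append(("gag", families.family_gag_protein(fam, self.gag_length)))
        orfs.append(("pol", families.family_pol_protein(fam, self.pol_length)))
        if self.layout == "gag+pol+env":
            orfs.append(("env", families.family_env_protein(fam, self.env_length)))
        return orfs

    def _orf_aa_lengths(self) -> list[int]:
        if self.layout == "gag-pol fused":
            return [self.pol_length]
        out = []
        if self.layout in ("gag+pol", "gag+pol+env"):
            out.append(self.gag_length)
        out.append(self.pol_length)
        if self.layout == "gag+pol+env":
            out.append(self.env_length)
        return out

    def _internal_deficit(self) -> int:
        aa = self._orf_aa_lengths()
        coding = sum(3 * n + 3 for n in aa) + 3 * len(aa)  # ORFs + framing stops
        return coding + 2 * self.ltr_length - self.consensus_length


def default_templates() -> list[FamilyTemplate]:
    """One representative template per family (tabulated geometry)."""
    return [
        FamilyTemplate("Gmr1", "Gmr", "gag-pol fused", 6465, 518, pol_length=1634),
        FamilyTemplate("Mag1", "Mag", "gag-pol fused", 4696, 208, pol_length=1365),
        FamilyTemplate("V-clade1", "V-clade", "gag+pol", 5558, 538, 371, 1119),
        FamilyTemplate("CsRN1-1", "CsRN1", "pol-only", 4337, 174, pol_length=1061),
        FamilyTemplate("Barthez1", "Barthez", "gag+pol", 7871, 1116, 355, 1394),
        FamilyTemplate("BEL1", "BEL-PAO", "pol-only", 7624, 728, pol_length=1434),
        FamilyTemplate("Copia1", "Copia", "gag+pol", 4794, 233, 454, 653),
        FamilyTemplate(
            "Orthoretrovirinae1", "Orthoretrovirinae", "pol-only", 8626, 433, pol_length=1108
        ),
        FamilyTemplate(
            "Epsilon2", "Epsilon retrovirus", "gag+pol+env", 8158, 382, 219, 951, 554
        ),
    ]


# --- codon encoding --------------------------------------------------------

def _codon_table() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table

    inv: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        inv.setdefault(aa, []).append(codon)
    for v in inv.values():
        v.sort()
    return inv


_INV_CODONS = _codon_table()


def _encode_protein(pep: str, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    for aa in pep[1:]:
        opts = _INV_CODONS[aa]
        codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.take(_NT, rng.choice(4, size=n, p=p)).tobytes().decode()


@dataclass(frozen=True)
class TemplateBuild:
    """A template consensus plus its embedded feature map (local coords)."""

    sequence: GenomeSequence
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    orfs: list[tuple[str, int, int]]  # (name, start, end) of coding spans


def build_template_consensus(template: FamilyTemplate, seed: int) -> TemplateBuild:
    """Construct the family consensus: 5'LTR + framed ORFs + identical 3'LTR.

    Each ORF is preceded by an in-frame stop codon so the maximal
    stop-to-stop ORF length equals the requested protein length exactly.
    """
    rng = np.random.default_rng(seed)
    ltr = _random_dna(rng, template.ltr_length)
    if template.ltr_motif and template.ltr_length >= 4:
        ltr = "TG" + ltr[2:-2] + "CA"

    orf_parts = [(name, _encode_protein(pep, rng)) for name, pep in template.orf_proteins()]
    internal_len = template.consensus_length - 2 * template.ltr_length
    leftover = internal_len - sum(len(d) + 3 for _, d in orf_parts)
    spacers = _spread(leftover, len(orf_parts) + 1)

    pieces: list[str] = []
    orf_map: list[tuple[str, int, int]] = []
    pos = template.ltr_length
    for (name, dna), spacer in zip(orf_parts, spacers):
        gap = _random_dna(rng, spacer) + "TAA"  # in-frame stop right before ATG
        pieces.append(gap)
        pos += len(gap)
        orf_map.append((name, pos, pos + len(dna)))
        pieces.append(dna)
        pos += len(dna)
    pieces.append(_random_dna(rng, spacers[-1]))

    seq = ltr + "".join(pieces) + ltr
    assert len(seq) == template.consensus_length
    L = template.consensus_length
    return TemplateBuild(
        GenomeSequence(template.name, seq),
        (0, template.ltr_length),
        (L - template.ltr_length, L),
        orf_map,
    )


def _spread(total: int, n: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


# --- substitution clock ----------------------------------------------------

def k2p_site_probabilities(divergence: float, kappa: float) -> tuple[float, float]:
    """Exact K2P (P, Q) site-difference probabilities at a given divergence.

    ``divergence`` is expected substitutions/site (branch length); ``kappa``
    the transition/transversion rate ratio.  Closed forms:
    P = 1/4 + 1/4 e^{-4bt} - 1/2 e^{-2(a+b)t},  Q = 1/2 - 1/2 e^{-4bt}
    with a = kappa*b and (a + 2b)t = divergence.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    bt = divergence / (kappa + 2.0)
    at = kappa * bt
    P = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    Q = 0.5 - 0.5 * np.exp(-4.0 * bt)
    return float(P), float(Q)


_STOPS = (b"TAA", b"TAG", b"TGA")


def _is_stop(codon: np.ndarray) -> bool:
    return codon.tobytes() in _STOPS


def mutate_copy(
    seq: GenomeSequence | str,
    age_My: float,
    rate_r: float = DEFAULT_RATE_R,
    kappa: float = DEFAULT_KAPPA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protect_orfs: Sequence[tuple[int, int]] = (),
) -> tuple[GenomeSequence, int, int]:
    """Age a copy by the K2P clock; returns (sequence, transitions, transversions).

    Expected divergence from the input is ``2 * rate_r * age_My * 1e6``
    substitutions/site; every site (LTRs and internal region alike) mutates
    independently.  Counts are numbers of sites changed by class.

    ``protect_orfs`` lists codon-aligned coding spans in which substitutions
    may not create in-frame stop codons (emulating the purifying selection
    that keeps recently active elements coding-intact): an offending
    substitution is retargeted to another base, or as a last resort
    reverted (and not counted).
    """
    if age_My < 0 or rate_r <= 0 or kappa <= 0:
        raise ValueError("need age_My >= 0, rate_r > 0, kappa > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    residues = seq.residues if isinstance(seq, GenomeSequence) else seq
    sid = seq.id if isinstance(seq, GenomeSequence) else "copy"
    d = 2.0 * rate_r * age_My * 1e6
    P, Q = k2p_site_probabilities(d, kappa)
    orig = np.frombuffer(residues.encode(), dtype=np.uint8)
    arr = orig.copy()
    u = rng.random(arr.size)
    acgt = (arr != ord("N"))
    ts_mask = (u < P) & acgt
    tv_mask = (u >= P) & (u < P + Q) & acgt
    for base, target in _TRANSITION.items():
        arr[ts_mask & (orig == base)] = target
    pick = rng.integers(2, size=arr.size)
    for base, (t0, t1) in _TRANSVERSIONS.items():
        sel = tv_mask & (orig == base)
        arr[sel & (pick == 0)] = t0
        arr[sel & (pick == 1)] = t1
    n_ts, n_tv = int(ts_mask.sum()), int(tv_mask.sum())

    for a, b in protect_orfs:
        span_hits = np.flatnonzero(ts_mask[a:b] | tv_mask[a:b]) + a
        codons = {(p - a) // 3 for p in span_hits}
        for ci in codons:
            s = a + 3 * ci
            if not _is_stop(arr[s : s + 3]):
                continue
            for p in range(s, s + 3):
                if not (ts_mask[p] or tv_mask[p]):
                    continue
                was_ts = bool(ts_mask[p])
                # candidate retargets: keep the site substituted if possible
                t0, t1 = _TRANSVERSIONS[int(orig[p])]
                alts = [t0, t1, _TRANSITION[int(orig[p])]]
                fixed = False
                for alt in alts:
                    if alt == arr[p] or alt == orig[p]:
                        continue
                    old = arr[p]
                    arr[p] = alt
                    if _is_stop(arr[s : s + 3]):
                        arr[p] = old
                        continue
                    now_ts = _TRANSITION[int(orig[p])] == alt
                    n_ts += int(now_ts) - int(was_ts)
                    n_tv += int(not now_ts) - int(not was_ts)
                    ts_mask[p], tv_mask[p] = now_ts, not now_ts
                    fixed = True
                    break
                if not fixed:
                    arr[p] = orig[p]
                    n_ts -= int(was_ts)
                    n_tv -= int(not was_ts)
                    ts_mask[p] = tv_mask[p] = False
                if not _is_stop(arr[s : s + 3]):
                    break
    return (GenomeSequence(sid, arr.tobytes().decode()), n_ts, n_tv)


# --- implantation ----------------------------------------------------------

COPY_CLASSES = ("full", "truncated", "solo_ltr")

#: gap (bp) kept between implants so no pair of distinct insertions can
#: mimic a single element's 4-10 kb repeat geometry (see docs/methods.md)
DEFAULT_MIN_GAP = 10_000


@dataclass(frozen=True)
class ImplantPlan:
    """How many copies of one template to implant, and at what age."""

    template: FamilyTemplate
    n_full: int = 1
    n_truncated: int = 0
    n_solo_ltr: int = 0
    age_My: float | Sequence[float] = 1.0
    rate_r: float = DEFAULT_RATE_R
    kappa: float = DEFAULT_KAPPA
    minus_strand_fraction: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_full, self.n_truncated, self.n_solo_ltr) < 0:
            raise ValueError("copy counts must be >= 0")

    def ages(self) -> list[tuple[str, float]]:
        n = self.n_full + self.n_truncated + self.n_solo_ltr
        if np.isscalar(self.age_My):
            per_copy = [float(self.age_My)] * n
        else:
            seq = list(self.age_My)
            per_copy = [float(seq[i % len(seq)]) for i in range(n)]
        classes = (
            ["full"] * self.n_full
            + ["truncated"] * self.n_truncated
            + ["solo_ltr"] * self.n_solo_ltr
        )
        return list(zip(classes, per_copy))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted copy."""

    interval: Interval
    template: str
    family: str
    copy_class: str
    age_My: float
    n_transitions: int
    n_transversions: int
    ltrs: tuple[Interval, ...]
    ltr_length: int

    def __post_init__(self) -> None:
        want = 2 if self.copy_class == "full" else 1
        if len(self.ltrs) != want:
            raise ValueError(f"{self.copy_class} copy must have {want} LTR interval(s)")


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    truth: list[TruthRecord]
    config: dict = field(default_factory=dict)


def _copy_sequence(
    build: TemplateBuild,
    copy_class: str,
    age: float,
    plan: ImplantPlan,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]], int, int]:
    """Mutated residues for one copy, local LTR spans, ts/tv counts."""
    mutated, n_ts, n_tv = mutate_copy(
        build.sequence,
        age,
        plan.rate_r,
        plan.kappa,
        rng=rng,
        protect_orfs=[(s, e - 3) for _, s, e in build.orfs],
    )
    res = mutated.residues
    ltr_len = build.ltr5[1] - build.ltr5[0]
    L = len(res)
    if copy_class == "full":
        return res, [(0, ltr_len), (L - ltr_len, L)], n_ts, n_tv
    if copy_class == "solo_ltr":
        return res[:ltr_len], [(0, ltr_len)], n_ts, n_tv
    # truncated: lose the 5' LTR plus 30-60% of the internal region
    internal = L - 2 * ltr_len
    cut = ltr_len + int(internal * rng.uniform(0.3, 0.6))
    kept = res[cut:]
    return kept, [(len(kept) - ltr_len, len(kept))], n_ts, n_tv


def implant(
    genome_size: int,
    gc: float,
    plans: Sequence[ImplantPlan],
    seed: int,
    contig_id: str = "synth1",
    min_gap: int = DEFAULT_MIN_GAP,
    max_tries: int = 2000,
) -> SyntheticGenome:
    """Implant planned copies into an i.i.d. background genome.

    Placement is uniform subject to non-overlap and ``min_gap`` spacing;
    implants overwrite the background so genome length is exactly
    ``genome_size``.  Roughly ``minus_strand_fraction`` of copies are
    reverse-complemented before insertion.
    """
    rng = np.random.default_rng(seed)
    background = _random_dna(rng, genome_size, gc)

    # (template, family, class, age, ts, tv, ltr spans, residues, strand)
    pieces: list[tuple] = []
    for plan in plans:
        build = build_template_consensus(plan.template, int(rng.integers(2**31)))
        for copy_class, age in plan.ages():
            res, ltr_spans, n_ts, n_tv = _copy_sequence(build, copy_class, age, plan, rng)
            strand = "-" if rng.random() < plan.minus_strand_fraction else "+"
            if strand == "-":
                L = len(res)
                res = revcomp(res)
                ltr_spans = [(L - b, L - a) for a, b in reversed(ltr_spans)]
            pieces.append(
                (plan.template.name, plan.template.family, copy_class, age, n_ts, n_tv, ltr_spans, res, strand)
            )
    total = sum(len(p[7]) for p in pieces)
    if total + min_gap * max(0, len(pieces) - 1) >= genome_size:
        raise PlacementError(
            f"implants ({total} bp + spacing) do not fit in {genome_size} bp"
        )

    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    for _, _, _, _, _, _, _, res, _ in pieces:
        n = len(res)
        for attempt in range(max_tries):
            s = int(rng.integers(0, genome_size - n + 1))
            if all(s < a - min_gap - n or s > b + min_gap for a, b in placed):
                placed.append((s, s + n))
                starts.append(s)
                break
        else:
            raise PlacementError(
                f"could not place a {n} bp implant after {max_tries} tries"
            )

    arr = bytearray(background.encode())
    truth: list[TruthRecord] = []
    for (tname, fam, copy_class, age, n_ts, n_tv, ltr_spans, res, strand), s in zip(
        pieces, starts
    ):
        arr[s : s + len(res)] = res.encode()
        ltrs = tuple(Interval(contig_id, s + a, s + b, strand) for a, b in ltr_spans)
        ltr_len = ltr_spans[0][1] - ltr_spans[0][0]
        truth.append(
            TruthRecord(
                Interval(contig_id, s, s + len(res), strand),
                tname,
                fam,
                copy_class,
                age,
                n_ts,
                n_tv,
                ltrs,
                ltr_len,
            )
        )
    truth.sort(key=lambda t: t.interval.start)
    cfg = {
        "genome_size": genome_size,
        "gc": gc,
        "seed": seed,
        "min_gap": min_gap,
        "n_implants": len(truth),
    }
    return SyntheticGenome(GenomeSequence(contig_id, arr.decode()), truth, cfg)


# --- truth output ----------------------------------------------------------

def truth_gff_records(truth: Sequence[TruthRecord]) -> list[GffRecord]:
    recs = []
    for i, t in enumerate(truth):
        eid = f"truth{i:04d}"
        attrs = {
            "ID": eid,
            "template": t.template,
            "family": t.family.replace(" ", "_"),
            "copy_class": t.copy_class,
            "age_My": f"{t.age_My:g}",
        }
        recs.append(GffRecord(t.interval, "LTR_retrotransposon", None, attrs))
        for j, ltr in enumerate(t.ltrs):
            recs.append(
                GffRecord(
                    ltr,
                    "long_terminal_repeat",
                    None,
                    {"ID": f"{eid}.ltr{j}", "Parent": eid},
                )
            )
    return recs


def write_outputs(result: SyntheticGenome, outdir: str | Path, prefix: str = "synth") -> dict[str, Path]:
    """Write genome FASTA, truth GFF3, manifest TSV and config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fa",
        "gff3": outdir / f"{prefix}.truth.gff3",
        "manifest": outdir / f"{prefix}.manifest.tsv",
        "config": outdir / f"{prefix}.config.json",
    }
    write_fasta([result.genome], paths["fasta"])
    write_gff3(
        truth_gff_records(result.truth),
        paths["gff3"],
        {result.genome.id: len(result.genome)},
    )
    lines = ["template\tfamily\tcopy_class\tage_My\tcontig\tstart\tend\tstrand"]
    for t in result.truth:
        iv = t.interval
        lines.append(
            f"{t.template}\t{t.family}\t{t.copy_class}\t{t.age_My:g}\t"
            f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.strand}"
        )
    paths["manifest"].write_text("\n".join(lines) + "\n")
    paths["config"].write_text(json.dumps(result.config, indent=2) + "\n")
    return paths
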