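"""ORF discovery, domain detection, DDE-triad localization and the
full-length verdict.

A candidate element is *full length* when it has LTRs at both ends, encodes
a protein longer than 500 aa, and carries a detectable reverse-transcriptase
domain.  Layout typing follows retroelement convention: separate gag and pol
ORFs, a single fused gag-pol ORF (Gmr/Mag pattern), pol-only (CsRN1 /
BEL-PAO / Orthoretrovirinae pattern), or gag+pol+env (epsilonretrovirus
pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .families import CANONICAL_DDE_SPACING
from .ltr_detect import LTRCandidate
from .profiles import DomainModel, ProfileHit, load_bundled_models, scan_protein
from .seq_core import GenomeSequence, Interval, ProteinSequence, translate_frame

logger = logging.getLogger(__name__)

DomainHit = ProfileHit  # domain hits are profile hits

MIN_ORF_AA = 500
#: ORF floor for structural (domain/layout) scanning; gag and env ORFs are
#: routinely shorter than the 500 aa full-length criterion
STRUCTURE_MIN_ORF_AA = 100
POL_REGION_MODELS = frozenset({"POL", "RT", "RH", "INT"})

LAYOUT_LABELS = ("gag+pol", "gag-pol fused", "pol-only", "gag+pol+env")


@dataclass(frozen=True)
class OrfAnnotation:
    """A maximal stop-to-stop open reading frame within a scanned region.

    ``interval`` is relative to the scanned region (same contig id),
    0-based half-open on the forward strand of that region.
    """

    protein: ProteinSequence
    frame: int
    interval: Interval

    @property
    def length_aa(self) -> int:
        return self.protein.length_aa


def scan_orfs(region: GenomeSequence, min_aa: int = MIN_ORF_AA) -> list[OrfAnnotation]:
    """All maximal stop-to-stop ORFs across six frames, strictly longer than
    ``min_aa`` amino acids, sorted by length descending."""
    out: list[OrfAnnotation] = []
    L = len(region)
    for frame in range(6):
        prot = translate_frame(region, frame)
        aa = prot.residues
        off = frame % 3
        start = 0  # aa index where current ORF begins
        for seg in aa.split("*"):
            if len(seg) > min_aa:
                a, b = start, start + len(seg)
                nt0, nt1 = off + 3 * a, off + 3 * b
                if frame < 3:
                    iv = Interval(region.id, nt0, nt1, "+")
                else:
                    iv = Interval(region.id, L - nt1, L - nt0, "-")
                out.append(
                    OrfAnnotation(
                        ProteinSequence(f"{region.id}|f{frame}|{a}", seg), frame, iv
                    )
                )
            start += len(seg) + 1
    out.sort(key=lambda o: (-o.length_aa, o.frame, o.interval.start))
    return out


def scan_domains(
    p: ProteinSequence, models: dict[str, DomainModel] | list[DomainModel]
) -> list[DomainHit]:
    """Non-overlapping local profile hits of every model against ``p``,
    at/above each model's bit threshold, best score first."""
    if isinstance(models, dict):
        models = list(models.values())
    hits: list[DomainHit] = []
    for mdl in models:
        hits.extend(scan_protein(mdl, p.residues))
    hits.sort(key=lambda h: (-h.bit_score, h.model, h.protein_start))
    return hits


@dataclass(frozen=True)
class DdeTriad:
    """Integrase catalytic D..D..E triad within an INT domain hit.

    Positions are aa indices relative to the hit start; ``canonical`` marks
    the conserved D2->E spacing of 35 aa.
    """

    d1: int
    d2: int
    e: int
    spacing_d2_e: int
    canonical: bool

    def __post_init__(self) -> None:
        if not self.d1 < self.d2 < self.e:
            raise ValueError("triad must satisfy D1 < D2 < E")


def _column_of(hit: ProfileHit, pos: int) -> int:
    """Model column aligned to protein position ``pos`` (nearest-diagonal
    interpolation for positions inside gaps)."""
    if pos in hit.column_map:
        return hit.column_map[pos]
    if not hit.column_map:
        return pos - hit.protein_start
    nearest = min(hit.column_map, key=lambda q: abs(q - pos))
    return hit.column_map[nearest] + (pos - nearest)


def locate_dde(
    p: ProteinSequence,
    int_hit: DomainHit,
    model: DomainModel | None = None,
    expected_spacing: int = CANONICAL_DDE_SPACING,
) -> DdeTriad | None:
    """Best-scoring ordered D..D..E triple within an INT hit.

    The triad score is the (negated) total deviation of the three residues
    from the model's catalytic columns under the hit alignment; on ties the
    leftmost D1 (then D2, then E) wins.  Returns None when the window holds
    no ordered D..D..E triple.
    """
    if int_hit.model != "INT":
        raise ValueError(f"expected an INT hit, got {int_hit.model}")
    if model is None:
        model = load_bundled_models()["INT"]
    if len(model.catalytic) != 3:
        raise ValueError("INT model must declare 3 catalytic columns")
    c1, c2, c3 = model.catalytic
    window = p.residues[int_hit.protein_start : int_hit.protein_end]
    ds = [i for i, aa in enumerate(window) if aa == "D"]
    es = [i for i, aa in enumerate(window) if aa == "E"]
    if len(ds) < 2 or not es:
        return None
    base = int_hit.protein_start
    best: tuple[float, int, int, int] | None = None
    for a_i, d1 in enumerate(ds):
        for d2 in ds[a_i + 1 :]:
            for e in es:
                if e <= d2:
                    continue
                dev = (
                    abs(_column_of(int_hit, base + d1) - c1)
                    + abs(_column_of(int_hit, base + d2) - c2)
                    + abs(_column_of(int_hit, base + e) - c3)
                )
                key = (dev, d1, d2, e)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    _, d1, d2, e = best
    spacing = e - d2
    return DdeTriad(d1, d2, e, spacing, spacing == expected_spacing)


@dataclass
class ElementRecord:
    """A candidate with its ORF/domain annotation and full-length verdict."""

    candidate: LTRCandidate
    orfs: list[OrfAnnotation] = field(default_factory=list)
    hits: list[tuple[int, DomainHit]] = field(default_factory=list)  # (orf index, hit)
    triad: DdeTriad | None = None
    layout: str | None = None
    full_length: bool = False
    failure_reasons: list[str] = field(default_factory=list)
    strand: str = "+"

    def orf_hit_models(self, orf_index: int) -> set[str]:
        return {h.model for i, h in self.hits if i == orf_index}

    def has_hit(self, model: str) -> bool:
        return any(h.model == model for _, h in self.hits)


def type_layout(r: ElementRecord) -> str:
    """Structural layout from the domain-hit pattern.

    gag-pol fused: one ORF carries both GAG and pol-region hits; env layout
    whenever an ENV hit exists; pol-only when no GAG hit anywhere.
    """
    if r.has_hit("ENV"):
        return "gag+pol+env"
    for i in range(len(r.orfs)):
        models = r.orf_hit_models(i)
        if "GAG" in models and models & POL_REGION_MODELS:
            return "gag-pol fused"
    if not r.has_hit("GAG"):
        return "pol-only"
    return "gag+pol"


def full_length_verdict(r: ElementRecord, min_aa: int = MIN_ORF_AA) -> tuple[bool, list[str]]:
    """Conjunction of the three full-length criteria, with failure reasons."""
    reasons = []
    if r.candidate.ltr3 is None:
        reasons.append("LTR missing")
    if not any(o.length_aa > min_aa for o in r.orfs):
        reasons.append(f"no ORF longer than {min_aa} aa")
    if not r.has_hit("RT"):
        reasons.append("no RT domain hit")
    return not reasons, reasons


def annotate_element(
    genome: GenomeSequence,
    candidate: LTRCandidate,
    models: dict[str, DomainModel] | None = None,
    region: Interval | None = None,
    min_aa: int = MIN_ORF_AA,
    structure_min_aa: int = STRUCTURE_MIN_ORF_AA,
) -> ElementRecord:
    """Run the full annotation stack on one candidate.

    ``region`` defaults to the candidate's element interval; pass a
    flank-extended interval to tolerate imprecise element boundaries.
    ORF intervals are shifted into genome coordinates.  Element strand is
    resolved from the orientation of the longest ORF.

    ORFs are scanned down to ``structure_min_aa`` so that sub-500 aa gag and
    env ORFs still inform layout typing; the full-length verdict keeps the
    strict ``min_aa`` criterion.
    """
    if models is None:
        models = load_bundled_models()
    iv = region or candidate.element
    sub = genome.slice(iv.start, iv.end, genome.id)
    orfs_local = scan_orfs(sub, structure_min_aa)
    orfs = [
        OrfAnnotation(
            o.protein,
            o.frame,
            Interval(iv.contig, iv.start + o.interval.start, iv.start + o.interval.end, o.interval.strand),
        )
        for o in orfs_local
    ]
    rec = ElementRecord(candidate, orfs)
    for i, orf in enumerate(orfs):
        for hit in scan_domains(orf.protein, models):
            rec.hits.append((i, hit))
    int_hits = [(i, h) for i, h in rec.hits if h.model == "INT"]
    if int_hits:
        i, h = max(int_hits, key=lambda ih: ih[1].bit_score)
        rec.triad = locate_dde(orfs[i].protein, h, models["INT"])
    rec.layout = type_layout(rec)
    rec.full_length, rec.failure_reasons = full_length_verdict(rec, min_aa)
    if orfs:
        rec.strand = orfs[0].interval.strand
    return rec


def records_to_frame(records: list[ElementRecord]):
    """Flatten element records to a DataFrame (one row per element)."""
    import pandas as pd

    rows = []
    for idx, r in enumerate(records):
        c = r.candidate
        rows.append(
            {
                "element_id": f"elem{idx:04d}",
                "contig": c.element.contig,
                "start": c.element.start,
                "end": c.element.end,
                "strand": r.strand,
                "ltr5_start": c.ltr5.start,
                "ltr5_end": c.ltr5.end,
                "ltr3_start": c.ltr3.start if c.ltr3 else -1,
                "ltr3_end": c.ltr3.end if c.ltr3 else -1,
                "ltr_identity": round(c.ltr_pair_identity, 2),
                "motif_ok": c.motif_ok,
                "tsd": c.tsd or "",
                "n_orfs": len(r.orfs),
                "max_orf_aa": max((o.length_aa for o in r.orfs), default=0),
                "domains": ",".join(sorted({h.model for _, h in r.hits})),
                "layout": r.layout or "",
                "triad_spacing": r.triad.spacing_d2_e if r.triad else -1,
                "triad_canonical": bool(r.triad.canonical) if r.triad else False,
                "full_length": r.full_length,
                "failure_reasons": ";".join(r.failure_reasons),
            }
        )
    return pd.DataFrame(rows)


def annotate_candidates(
    genome: GenomeSequence,
    candidates: list[LTRCandidate],
    models: dict[str, DomainModel] | None = None,
    flank: int = 0,
    min_aa: int = MIN_ORF_AA,
) -> list[ElementRecord]:
    """Annotate a candidate list; ``flank`` expands the scanned region."""
    if models is None:
        models = load_bundled_models()
    out = []
    for c in candidates:
        region = None
        if flank:
            region = Interval(
                c.element.contig,
                max(0, c.element.start - flank),
                min(len(genome), c.element.end + flank),
                c.element.strand,
            )
        out.append(annotate_element(genome, c, models, region, min_aa))
    n_full = sum(r.full_length for r in out)
    logger.info("annotate_candidates: %d candidates, %d full-length", len(out), n_full)
    return out
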