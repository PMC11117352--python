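"""Sequence and interval primitives shared by every pipeline stage.

Genomic coordinates are 0-based half-open internally; GFF3 emitted by
:func:`write_gff3` is 1-based inclusive, and :func:`read_gff3` converts back,
so a write/read round trip is the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for empty FASTA input or duplicate record ids."""


@dataclass(frozen=True)
class GenomeSequence:
    """A contig: identifier plus residues over the {A,C,G,T,N} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeSequence id must be nonempty")
        bad = _NON_ACGTN.search(self.residues)
        if bad:
            raise ValueError(
                f"invalid residue {bad.group()!r} in sequence {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, sid: str | None = None) -> "GenomeSequence":
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(f"slice [{start},{end}) outside {self.id} (len {len(self)})")
        return GenomeSequence(sid or f"{self.id}:{start}-{end}", self.residues[start:end])


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min of mutual overlap fractions; 1.0 for identical intervals."""
        ov = self.overlap_length(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = frozenset(_AA + "X*")


@dataclass(frozen=True)
class ProteinSequence:
    """Amino-acid sequence; ``*`` marks stop codons."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        extra = set(self.residues) - _VALID_AA
        if extra:
            raise ValueError(f"invalid amino acids {sorted(extra)} in {self.id!r}")

    @property
    def length_aa(self) -> int:
        """Residue count excluding a terminal stop."""
        r = self.residues
        return len(r) - 1 if r.endswith("*") else len(r)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file of nucleotide sequences.

    Residues are uppercased; IUPAC ambiguity codes and any other non-ACGTN
    characters are collapsed to N with a logged count.  Empty files and
    duplicate ids raise :class:`FastaFormatError`.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    n_masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        masked = _NON_ACGTN.sub("N", raw)
        n_masked += sum(1 for a, b in zip(raw, masked) if a != b)
        records.append(GenomeSequence(rec.id, masked))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    if n_masked:
        logger.info("read_fasta(%s): %d non-ACGTN residues mapped to N", path, n_masked)
    return records


def write_fasta(seqs: Iterable[GenomeSequence | ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


def reverse_complement(s: GenomeSequence) -> GenomeSequence:
    """Reverse complement; involution with A<->T, C<->G, N<->N."""
    return GenomeSequence(s.id, s.residues.translate(_COMPLEMENT)[::-1])


def revcomp(residues: str) -> str:
    """Reverse-complement a raw residue string."""
    return residues.translate(_COMPLEMENT)[::-1]


def translate_frame(s: GenomeSequence, frame: int) -> ProteinSequence:
    """Translate one of six reading frames under the standard genetic code.

    Frames 0-2 are offsets on the forward strand, 3-5 the same offsets on
    the reverse complement.  Incomplete trailing codons are dropped; stop
    codons render as ``*``; codons containing N render as X.
    """
    if not 0 <= frame <= 5:
        raise ValueError(f"frame must be 0..5, got {frame}")
    nt = s.residues if frame < 3 else revcomp(s.residues)
    off = frame % 3
    usable = nt[off : off + 3 * ((len(nt) - off) // 3)]
    if not usable:
        return ProteinSequence(f"{s.id}|frame{frame}", "")
    aa = str(Seq(usable).translate())
    # Bio renders N-containing codons as X already; normalize any leftovers
    aa = "".join(c if c in _VALID_AA else "X" for c in aa)
    return ProteinSequence(f"{s.id}|frame{frame}", aa)


# --- GFF3 -----------------------------------------------------------------

GFF_SOURCE = "tetraltr"


@dataclass
class GffRecord:
    """One GFF3 feature line (internal 0-based half-open coordinates)."""

    interval: Interval
    feature_type: str = "LTR_retrotransposon"
    score: float | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)


def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(
    records: Sequence[GffRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write features as GFF3, converting to 1-based inclusive coordinates.

    When ``contig_lengths`` is given, intervals are validated against it and
    ``##sequence-region`` pragmas are emitted.
    """
    lines = ["##gff-version 3"]
    if contig_lengths:
        for name, ln in contig_lengths.items():
            lines.append(f"##sequence-region {name} 1 {ln}")
        for rec in records:
            iv = rec.interval
            if iv.contig in contig_lengths and iv.end > contig_lengths[iv.contig]:
                raise ValueError(
                    f"interval [{iv.start},{iv.end}) exceeds contig "
                    f"{iv.contig} length {contig_lengths[iv.contig]}"
                )
    for rec in records:
        iv = rec.interval
        score = "." if rec.score is None else f"{rec.score:.3f}"
        lines.append(
            "\t".join(
                [
                    iv.contig,
                    GFF_SOURCE,
                    rec.feature_type,
                    str(iv.start + 1),
                    str(iv.end),
                    score,
                    iv.strand,
                    ".",
                    _fmt_attrs(rec.attributes),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Read GFF3 features back into internal 0-based half-open records."""
    import gffutils

    out: list[GffRecord] = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        attrs = {k: v[0] for k, v in feat.attributes.items()}
        score = None if feat.score in (".", "", None) else float(feat.score)
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        out.append(
            GffRecord(
                Interval(feat.seqid, feat.start - 1, feat.end, strand),
                feature_type=feat.featuretype,
                score=score,
                attributes=attrs,
            )
        )
    return out
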