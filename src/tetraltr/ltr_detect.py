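"""De novo detection of candidate LTR elements as paired direct repeats.

A full-length LTR retrotransposon presents as two similar direct repeats
(the LTRs) bounding a 4-10 kb span.  Detection is seed-and-extend: exact
k-mer seeds shared by two loci at an element-compatible separation are
chained per diagonal and extended without gaps under an X-drop rule; the
extended repeat pair becomes an :class:`LTRCandidate`.

Direct-repeat geometry is orientation-symmetric — an element inserted on
the minus strand still presents its LTR pair as a plus-strand direct repeat
(and the TG...CA terminus motif is its own reverse complement) — so a single
plus-strand scan covers both strands.  Candidates are reported on plus
coordinates; element strand is resolved later from ORF orientation during
annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seq_core import GenomeSequence, GffRecord, Interval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectConfig:
    """Detector parameters; element bounds default to the 4-10 kb window."""

    k: int = 13
    min_ltr_identity: float = 80.0  # percent
    ltr_len_bounds: tuple[int, int] = (100, 1500)
    element_len_bounds: tuple[int, int] = (4000, 10000)
    max_gap_in_extension: int = 500
    flank: int = 4000
    xdrop: int = 20


@dataclass(frozen=True)
class LTRCandidate:
    """A candidate element: paired terminal repeats and the spanned interval."""

    element: Interval
    ltr5: Interval
    ltr3: Interval | None
    ltr_pair_identity: float  # percent
    motif_ok: bool = False
    tsd: str | None = None

    def __post_init__(self) -> None:
        if self.ltr3 is not None:
            if self.ltr5.end > self.ltr3.start:
                raise ValueError("5' LTR must precede 3' LTR without overlap")
            if self.element.start != self.ltr5.start or self.element.end != self.ltr3.end:
                raise ValueError("element must span ltr5.start..ltr3.end")

    @property
    def score(self) -> float:
        """identity x mean LTR length, used for overlap resolution."""
        mean_len = (
            self.ltr5.length
            if self.ltr3 is None
            else (self.ltr5.length + self.ltr3.length) / 2
        )
        return self.ltr_pair_identity / 100.0 * mean_len


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def _kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer value of each k-mer window; -1 where the window contains N."""
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for i in range(k):
        window = codes[i : i + m]
        vals = vals * 4 + np.where(window == 4, 0, window)
        bad |= window == 4
    vals[bad] = -1
    return vals


def _seed_pairs(codes: np.ndarray, cfg: DetectConfig) -> dict[int, list[int]]:
    """Map diagonal (separation) -> sorted seed start positions."""
    vals = _kmer_values(codes, cfg.k)
    if vals.size == 0:
        return {}
    lo = max(1, cfg.element_len_bounds[0] - cfg.ltr_len_bounds[1])
    hi = cfg.element_len_bounds[1]
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    boundaries = np.flatnonzero(np.diff(sv)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [sv.size]))
    diagonals: dict[int, list[int]] = {}
    for a, b in zip(starts, ends):
        if b - a < 2 or sv[a] < 0:
            continue
        pos = np.sort(order[a:b])
        if b - a > 200:  # low-complexity k-mer; skip pathological groups
            continue
        diff = pos[None, :] - pos[:, None]
        ii, jj = np.nonzero((diff >= lo) & (diff <= hi))
        for i, j in zip(ii, jj):
            diagonals.setdefault(int(diff[i, j]), []).append(int(pos[i]))
    for d in diagonals:
        diagonals[d] = sorted(set(diagonals[d]))
    return diagonals


def _merge_runs(positions: list[int], k: int, max_gap: int) -> list[tuple[int, int]]:
    """Merge seed starts on one diagonal into runs [start, end)."""
    runs = []
    s = e = positions[0]
    for p in positions[1:]:
        if p <= e + k + max_gap:
            e = p
        else:
            runs.append((s, e + k))
            s = e = p
    runs.append((s, e + k))
    return runs


def _xdrop_extend(
    codes: np.ndarray, s: int, e: int, d: int, xdrop: int
) -> tuple[int, int]:
    """Ungapped X-drop extension of the repeat [s,e) vs [s+d,e+d)."""
    n = codes.size
    # right
    best = 0
    score = 0
    best_e = e
    j = e
    while j + d < n and score > best - xdrop:
        score += 1 if (codes[j] == codes[j + d] and codes[j] != 4) else -1
        j += 1
        if score > best:
            best, best_e = score, j
    # left
    best = 0
    score = 0
    best_s = s
    j = s - 1
    while j >= 0 and score > best - xdrop:
        score += 1 if (codes[j] == codes[j + d] and codes[j] != 4) else -1
        if score > best:
            best, best_s = score, j
        j -= 1
    return best_s, best_e


def _identity(codes: np.ndarray, s: int, e: int, d: int) -> float:
    a = codes[s:e]
    b = codes[s + d : e + d]
    ok = (a == b) & (a != 4)
    return 100.0 * ok.sum() / (e - s)


def _find_tsd(residues: str, s: int, e: int, max_len: int = 6, min_len: int = 4) -> str | None:
    for m in range(max_len, min_len - 1, -1):
        if s - m >= 0 and e + m <= len(residues) and residues[s - m : s] == residues[e : e + m]:
            return residues[s - m : s]
    return None


def find_repeat_pairs(g: GenomeSequence, cfg: DetectConfig | None = None) -> list[LTRCandidate]:
    """Detect candidate LTR pairs in one contig.

    Overlapping candidates are resolved by maximum-total-score weighted
    interval scheduling on element intervals (score = identity x mean LTR
    length), which reduces to "keep the higher score" for a conflicting
    pair and prefers two compatible true pairs over one chimera spanning
    them.  Ties break to the leftmost candidate.
    """
    cfg = cfg or DetectConfig()
    codes = _encode(g.residues)
    raw: list[LTRCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    for d, positions in sorted(_seed_pairs(codes, cfg).items()):
        for s0, e0 in _merge_runs(positions, cfg.k, cfg.max_gap_in_extension):
            s, e = _xdrop_extend(codes, s0, e0, d, cfg.xdrop)
            if (s, e, d) in seen:
                continue
            seen.add((s, e, d))
            length = e - s
            if not cfg.ltr_len_bounds[0] <= length <= cfg.ltr_len_bounds[1]:
                continue
            if e > s + d:  # LTR copies may not overlap each other
                continue
            ident = _identity(codes, s, e, d)
            if ident < cfg.min_ltr_identity:
                continue
            ltr5 = Interval(g.id, s, e)
            ltr3 = Interval(g.id, s + d, e + d)
            element = Interval(g.id, s, e + d)
            motif = (
                g.residues[s : s + 2] == "TG" and g.residues[e + d - 2 : e + d] == "CA"
            )
            raw.append(
                LTRCandidate(
                    element,
                    ltr5,
                    ltr3,
                    ident,
                    motif_ok=motif,
                    tsd=_find_tsd(g.residues, s, e + d),
                )
            )
    resolved = resolve_overlaps(raw)
    logger.info(
        "find_repeat_pairs(%s): %d raw -> %d resolved candidates", g.id, len(raw), len(resolved)
    )
    return resolved


def resolve_overlaps(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    """Max-total-score set of mutually non-overlapping candidates.

    Weighted interval scheduling on element intervals; on equal totals the
    leftmost-starting candidate is preferred (deterministic).
    """
    if len(cands) <= 1:
        return list(cands)
    cands = sorted(cands, key=lambda c: (c.element.end, c.element.start))
    ends = [c.element.end for c in cands]
    import bisect

    n = len(cands)
    p = [bisect.bisect_right(ends, cands[i].element.start) - 1 for i in range(n)]
    dp = [0.0] * (n + 1)
    take = [False] * n
    for i in range(n):
        incl = dp[p[i] + 1] + cands[i].score
        if incl >= dp[i]:
            dp[i + 1] = incl
            take[i] = True
        else:
            dp[i + 1] = dp[i]
    out = []
    i = n - 1
    while i >= 0:
        if take[i]:
            out.append(cands[i])
            i = p[i]
        else:
            i -= 1
    out.reverse()
    return out


def filter_by_element_length(
    cands: list[LTRCandidate], cfg: DetectConfig | None = None
) -> list[LTRCandidate]:
    """Keep candidates whose element length lies in the configured bounds
    (inclusive at both ends); order preserved, counts logged."""
    cfg = cfg or DetectConfig()
    lo, hi = cfg.element_len_bounds
    kept = [c for c in cands if lo <= c.element.length <= hi]
    logger.info(
        "filter_by_element_length: %d -> %d (bounds %d-%d)", len(cands), len(kept), lo, hi
    )
    return kept


def extend_flanks(c: LTRCandidate, g: GenomeSequence, flank: int | None = None) -> Interval:
    """Element interval grown by ``flank`` bp each side, clipped to the contig."""
    if flank is None:
        flank = DetectConfig().flank
    iv = c.element
    if iv.end > len(g):
        raise ValueError(f"candidate {iv} outside contig {g.id} (len {len(g)})")
    return Interval(
        iv.contig, max(0, iv.start - flank), min(len(g), iv.end + flank), iv.strand
    )


def candidates_to_gff(cands: list[LTRCandidate]) -> list[GffRecord]:
    recs = []
    for i, c in enumerate(cands):
        cid = f"cand{i:05d}"
        attrs = {
            "ID": cid,
            "ltr_identity": f"{c.ltr_pair_identity:.2f}",
            "motif_ok": str(c.motif_ok).lower(),
        }
        if c.tsd:
            attrs["tsd"] = c.tsd
        recs.append(GffRecord(c.element, "LTR_retrotransposon", c.score, attrs))
        recs.append(
            GffRecord(c.ltr5, "long_terminal_repeat", None, {"ID": f"{cid}.ltr5", "Parent": cid})
        )
        if c.ltr3 is not None:
            recs.append(
                GffRecord(c.ltr3, "long_terminal_repeat", None, {"ID": f"{cid}.ltr3", "Parent": cid})
            )
    return recs


def gff_to_candidates(recs: list[GffRecord]) -> list[LTRCandidate]:
    """Rebuild candidates from GFF records written by :func:`candidates_to_gff`."""
    elements = {r.attributes["ID"]: r for r in recs if r.feature_type == "LTR_retrotransposon"}
    ltrs: dict[str, dict[str, GffRecord]] = {}
    for r in recs:
        if r.feature_type == "long_terminal_repeat":
            parent = r.attributes["Parent"]
            which = "ltr5" if r.attributes["ID"].endswith("ltr5") else "ltr3"
            ltrs.setdefault(parent, {})[which] = r
    out = []
    for cid, er in elements.items():
        pair = ltrs.get(cid, {})
        if "ltr5" not in pair:
            continue
        out.append(
            LTRCandidate(
                er.interval,
                pair["ltr5"].interval,
                pair["ltr3"].interval if "ltr3" in pair else None,
                float(er.attributes.get("ltr_identity", "0")),
                motif_ok=er.attributes.get("motif_ok") == "true",
                tsd=er.attributes.get("tsd"),
            )
        )
    out.sort(key=lambda c: (c.element.contig, c.element.start))
    return out
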