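"""Divergence estimation and insertion-age dating.

Divergence between an element copy and its family representative (or
between the copy's own two LTRs) is corrected with the Kimura two-parameter
model, K = -1/2 ln((1-2P-Q) sqrt(1-2Q)), and converted to an insertion time
by the molecular clock t = K/2r with r = 1e-8 substitutions/site/year by
default.

Because each copy accrues divergence 2rt from its ancestor under that clock
(the generative reading of t = K/2r), the two LTRs of one copy separate at
4r per year; ``inter_ltr`` mode therefore converts with t = K/(4r).  Both
modes recover true age on the synthetic generator.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import edlib
import pandas as pd

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = frozenset("ACGT")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_RATE_R = 1e-8
RECENT_THRESHOLD_MY = 5.0
DEFAULT_BIN_WIDTH_MY = 1.0


@dataclass(frozen=True)
class DivergenceStats:
    """Observed transition (P) and transversion (Q) proportions."""

    sites: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("need P, Q >= 0 and P + Q <= 1")


@dataclass(frozen=True)
class ClockConfig:
    """Molecular clock: rate r (substitutions/site/year) and divergence mode."""

    r: float = DEFAULT_RATE_R
    mode: str = "vs_consensus"  # or "inter_ltr"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("rate r must be > 0")
        if self.mode not in ("vs_consensus", "inter_ltr"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    K: float  # corrected divergence; NaN = saturated
    t_My: float  # insertion time, millions of years; NaN = saturated


def count_divergence(a: str, b: str) -> DivergenceStats:
    """P/Q proportions over comparable columns of two aligned sequences.

    Columns containing a gap ('-') or N on either side are excluded from
    the site count.  Raises on length mismatch or zero comparable sites.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    sites = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _ACGT or y not in _ACGT:
            continue
        sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable (gap/N-free) sites")
    return DivergenceStats(sites, ts / sites, tv / sites)


def kimura2p(s: DivergenceStats) -> float:
    """K2P-corrected divergence; NaN sentinel when saturated.

    K = -1/2 ln((1-2P-Q) sqrt(1-2Q)); undefined when 1-2P-Q <= 0 or
    1-2Q <= 0 (substitution saturation).
    """
    w1 = 1.0 - 2.0 * s.P - s.Q
    w2 = 1.0 - 2.0 * s.Q
    if w1 <= 0 or w2 <= 0:
        logger.info("kimura2p: saturated alignment (P=%.3f, Q=%.3f)", s.P, s.Q)
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_time(K: float, clock: ClockConfig | None = None) -> float:
    """Insertion time in My from corrected divergence.

    vs_consensus: t = K / (2r); inter_ltr: t = K / (4r) (two independently
    diverging LTRs).  NaN K propagates.
    """
    clock = clock or ClockConfig()
    if math.isnan(K):
        return float("nan")
    if K < 0:
        raise ValueError("K must be >= 0")
    denom = 2.0 * clock.r if clock.mode == "vs_consensus" else 4.0 * clock.r
    return K / denom / 1e6


def _global_alignment_rows(a: str, b: str) -> tuple[str, str]:
    """Gapped rows of a global edit-distance alignment of a vs b."""
    r = edlib.align(a, b, task="path", mode="NW")
    ra, rb = [], []
    qi = ti = 0
    for n, op in _CIGAR_RE.findall(r["cigar"]):
        n = int(n)
        if op in ("=", "X", "M"):
            ra.append(a[qi : qi + n])
            rb.append(b[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":
            ra.append(a[qi : qi + n])
            rb.append("-" * n)
            qi += n
        else:
            ra.append("-" * n)
            rb.append(b[ti : ti + n])
            ti += n
    return "".join(ra), "".join(rb)


def estimate_age(
    element_id: str,
    seq_a: str,
    seq_b: str,
    clock: ClockConfig | None = None,
) -> AgeEstimate:
    """Align two sequences, correct divergence, convert to insertion time.

    In ``vs_consensus`` mode pass (copy, representative); in ``inter_ltr``
    mode pass the copy's two LTR sequences.
    """
    clock = clock or ClockConfig()
    if len(seq_a) == len(seq_b):
        # substitution-only divergence model: equal-length pairs compare
        # positionally (an edit alignment would trade mismatches for
        # spurious indels and deflate P/Q)
        rows = (seq_a, seq_b)
    else:
        rows = _global_alignment_rows(seq_a, seq_b)
    stats = count_divergence(*rows)
    K = kimura2p(stats)
    return AgeEstimate(element_id, K, insertion_time(K, clock))


# --- landscapes ------------------------------------------------------------


@dataclass
class AgeLandscape:
    """Genome coverage per insertion-age bin for one family."""

    family: str
    bin_edges: list[float]  # contiguous from 0, My
    coverage: list[float]  # percent of genome length per bin
    recent_activity: bool  # modal bin below the recent threshold
    n_excluded_saturated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "bin_start_My": self.bin_edges[:-1],
                "bin_end_My": self.bin_edges[1:],
                "coverage_pct": self.coverage,
            }
        )


def build_landscape(
    elements: list[tuple[AgeEstimate, int, str]],
    genome_length: int,
    bin_width_My: float = DEFAULT_BIN_WIDTH_MY,
    recent_threshold_My: float = RECENT_THRESHOLD_MY,
) -> list[AgeLandscape]:
    """Per-family age landscapes from (age estimate, element length, family).

    Coverage of a bin is the summed element length whose age falls in the
    bin, divided by genome length, times 100.  Saturated (NaN) ages are
    excluded with a logged count.  Bins are contiguous from 0.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_family: dict[str, list[tuple[float, int]]] = {}
    excluded: dict[str, int] = {}
    for est, length, family in elements:
        if math.isnan(est.t_My):
            excluded[family] = excluded.get(family, 0) + 1
            continue
        by_family.setdefault(family, []).append((est.t_My, length))
    out = []
    for family in sorted(set(by_family) | set(excluded)):
        pairs = by_family.get(family, [])
        max_age = max((t for t, _ in pairs), default=0.0)
        n_bins = max(1, int(math.floor(max_age / bin_width_My)) + 1)
        edges = [i * bin_width_My for i in range(n_bins + 1)]
        cov = [0.0] * n_bins
        for t, length in pairs:
            b = min(int(t / bin_width_My), n_bins - 1)
            cov[b] += 100.0 * length / genome_length
        modal = max(range(n_bins), key=lambda i: (cov[i], -i)) if pairs else 0
        recent = bool(pairs) and edges[modal] < recent_threshold_My
        n_exc = excluded.get(family, 0)
        if n_exc:
            logger.info("landscape %s: %d saturated ages excluded", family, n_exc)
        out.append(AgeLandscape(family, edges, cov, recent, n_exc))
    return out


def landscapes_to_frame(landscapes: list[AgeLandscape]) -> pd.DataFrame:
    if not landscapes:
        return pd.DataFrame(
            columns=["family", "bin_start_My", "bin_end_My", "coverage_pct"]
        )
    return pd.concat([l.to_frame() for l in landscapes], ignore_index=True)
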