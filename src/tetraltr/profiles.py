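"""Position-specific score models for retroelement protein domains.

Domains (GAG, POL, RT, RH, INT, ENV) are modelled as per-column log-odds
score vectors over the 20 amino acids, scanned against query proteins by
affine-gap Smith-Waterman.  This is a deliberately lightweight stand-in for
full profile HMMs: scores are in bits, a hit is reported when the best local
alignment reaches the model's bit threshold.

The bundled profiles (``data/domain_profiles.synthetic.tsv``) are synthetic
constructions built from fixed consensus peptides — they are internally
consistent with the synthetic-genome generator (which encodes the same
consensus peptides into implanted elements) but are not distilled from any
curated seed alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

DEFAULT_MATCH_BITS = 3.0
DEFAULT_MISMATCH_BITS = -1.0
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 2.0
DEFAULT_BIT_THRESHOLD = 25.0


@dataclass
class DomainModel:
    """Per-column log-odds model for one protein domain.

    ``catalytic`` holds model-column indices of catalytic residues (used by
    the DDE-triad locator for INT models; empty otherwise).
    """

    name: str
    consensus: str
    scores: np.ndarray  # shape (n_columns, 20), bits
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    bit_threshold: float = DEFAULT_BIT_THRESHOLD
    catalytic: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.consensus), 20):
            raise ValueError(
                f"model {self.name}: scores shape {self.scores.shape} "
                f"!= ({len(self.consensus)}, 20)"
            )
        if len(self.consensus) < 20:
            raise ValueError(f"model {self.name}: needs >= 20 columns")
        if self.bit_threshold <= 0:
            raise ValueError(f"model {self.name}: threshold must be > 0")

    @property
    def n_columns(self) -> int:
        return len(self.consensus)


def build_profile(
    name: str,
    consensus: str,
    match_bits: float = DEFAULT_MATCH_BITS,
    mismatch_bits: float = DEFAULT_MISMATCH_BITS,
    catalytic: tuple[int, ...] = (),
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
) -> DomainModel:
    """Build a model whose columns reward the consensus residue."""
    cols = np.full((len(consensus), 20), mismatch_bits)
    for i, aa in enumerate(consensus):
        cols[i, _AA_INDEX[aa]] = match_bits
    return DomainModel(name, consensus, cols, catalytic=catalytic, bit_threshold=bit_threshold)


@dataclass(frozen=True)
class ProfileHit:
    """Best local alignment of a model to a protein.

    ``protein_start``/``protein_end`` are 0-based half-open amino-acid
    coordinates; ``column_map`` maps aligned protein positions to model
    columns (diagonal moves only).
    """

    model: str
    protein_start: int
    protein_end: int
    bit_score: float
    column_map: dict[int, int] = field(hash=False, default_factory=dict)


def _residue_scores(model: DomainModel, protein: str) -> np.ndarray:
    """(len(protein), n_columns) substitution score matrix in bits."""
    n_cols = model.n_columns
    out = np.empty((len(protein), n_cols))
    unknown = np.full(n_cols, -2.0)  # X / * / masked
    for i, aa in enumerate(protein):
        j = _AA_INDEX.get(aa)
        out[i] = model.scores[:, j] if j is not None else unknown
    return out


@njit(cache=True)
def _sw_kernel(sub, go, ge, H, E, F, tb, tbe, tbf):  # pragma: no cover - jitted
    n = sub.shape[0]
    m = sub.shape[1]
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                tbe[i, j] = 1
            else:
                E[i, j] = e_open
                tbe[i, j] = 0
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                tbf[i, j] = 1
            else:
                F[i, j] = f_open
                tbf[i, j] = 0
            h = H[i - 1, j - 1] + sub[i - 1, j - 1]
            ptr = 1
            if E[i, j] > h:
                h = E[i, j]
                ptr = 2
            if F[i, j] > h:
                h = F[i, j]
                ptr = 3
            if h <= 0.0:
                h = 0.0
                ptr = 0
            H[i, j] = h
            tb[i, j] = ptr
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def best_local_hit(model: DomainModel, protein: str, masked: Iterable[tuple[int, int]] = ()) -> ProfileHit | None:
    """Affine-gap Smith-Waterman of a score model against a protein.

    Returns the single best local hit at/above the model threshold, or None.
    ``masked`` protein spans are excluded (used for non-overlapping
    multi-hit scanning).
    """
    n, m = len(protein), model.n_columns
    if n == 0:
        return None
    sub = _residue_scores(model, protein)
    for a, b in masked:
        sub[a:b, :] = -1e9

    go, ge = model.gap_open, model.gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e18)  # gap in protein (consumes model column)
    F = np.full((n + 1, m + 1), -1e18)  # gap in model (consumes protein residue)
    # traceback: 0 stop, 1 diag, 2 from E, 3 from F; E/F own pointers: 0 open, 1 extend
    tb = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbe = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbf = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, bi, bj = _sw_kernel(sub, go, ge, H, E, F, tb, tbe, tbf)

    if best < model.bit_threshold:
        return None

    # traceback
    column_map: dict[int, int] = {}
    i, j, state = bi, bj, "H"
    start_i = bi
    while i > 0 and j > 0:
        if state == "H":
            ptr = tb[i, j]
            if ptr == 0:
                break
            if ptr == 1:
                column_map[i - 1] = j - 1
                start_i = i - 1
                i, j = i - 1, j - 1
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            nxt = tbe[i, j]
            j -= 1
            state = "E" if nxt == 1 else "H"
        else:
            nxt = tbf[i, j]
            start_i = i - 1
            i -= 1
            state = "F" if nxt == 1 else "H"
    return ProfileHit(model.name, start_i, bi, float(best), column_map)


def scan_protein(model: DomainModel, protein: str, max_hits: int = 4) -> list[ProfileHit]:
    """All non-overlapping hits of a model at/above its threshold, best first."""
    hits: list[ProfileHit] = []
    masked: list[tuple[int, int]] = []
    while len(hits) < max_hits:
        h = best_local_hit(model, protein, masked)
        if h is None:
            break
        hits.append(h)
        masked.append((h.protein_start, h.protein_end))
    return hits


# --- bundled profile TSV ---------------------------------------------------

BUNDLED_PROFILES = "domain_profiles.synthetic.tsv"


def save_models_tsv(models: Iterable[DomainModel], path: str | Path) -> None:
    """Write models to the documented TSV of log-odds columns."""
    lines = [
        "# Position-specific score models (bits). One block per model.",
        "# meta lines: model, bit_threshold, gap_open, gap_extend, catalytic columns.",
        "\t".join(["model", "pos", "consensus", "catalytic"] + list(AA_ALPHABET)),
    ]
    for mdl in models:
        cat = ",".join(map(str, mdl.catalytic)) if mdl.catalytic else "-"
        lines.append(
            f"#meta\t{mdl.name}\tthreshold={mdl.bit_threshold}\t"
            f"gap_open={mdl.gap_open}\tgap_extend={mdl.gap_extend}\tcatalytic={cat}"
        )
        for i, aa in enumerate(mdl.consensus):
            row = [mdl.name, str(i), aa, "1" if i in mdl.catalytic else "0"]
            row += [f"{v:g}" for v in mdl.scores[i]]
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_models_tsv(path: str | Path) -> dict[str, DomainModel]:
    """Read models written by :func:`save_models_tsv`."""
    meta: dict[str, dict] = {}
    rows: dict[str, list[tuple[int, str, list[float]]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("# ") or line.startswith("model\t"):
            continue
        parts = line.split("\t")
        if parts[0] == "#meta":
            name = parts[1]
            kv = dict(p.split("=", 1) for p in parts[2:])
            cat = () if kv["catalytic"] == "-" else tuple(int(x) for x in kv["catalytic"].split(","))
            meta[name] = {
                "bit_threshold": float(kv["threshold"]),
                "gap_open": float(kv["gap_open"]),
                "gap_extend": float(kv["gap_extend"]),
                "catalytic": cat,
            }
            continue
        name, pos, aa = parts[0], int(parts[1]), parts[2]
        rows.setdefault(name, []).append((pos, aa, [float(v) for v in parts[4:]]))
    models = {}
    for name, rws in rows.items():
        rws.sort()
        consensus = "".join(aa for _, aa, _ in rws)
        scores = np.array([v for _, _, v in rws])
        models[name] = DomainModel(name, consensus, scores, **meta[name])
    return models


def load_bundled_models() -> dict[str, DomainModel]:
    """Load the synthetic domain profiles shipped with the package."""
    ref = resources.files("tetraltr.data") / BUNDLED_PROFILES
    with resources.as_file(ref) as p:
        return load_models_tsv(p)
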