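"""Pairwise identity, greedy 50%-identity clustering, consensus building,
LTR boundary refinement, reference-panel classification, and a
neighbor-joining tree.

Identity is matches / alignment columns (terminal gaps included) under
global affine-gap alignment.  For long nucleotide sequences an edit-distance
alignment (edlib) computes the same quantity orders of magnitude faster; the
affine path is used for short sequences and proteins.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from .annotate import ElementRecord, scan_orfs
from .families import FAMILY_TO_SUPERFAMILY, PanelEntry, load_bundled_panel
from .ltr_detect import DetectConfig, find_repeat_pairs
from .profiles import DomainModel, load_bundled_models, scan_protein
from .seq_core import GenomeSequence, ProteinSequence

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_THRESHOLD = 50.0  # percent
PANEL_FLOOR_IDENTITY = 20.0  # percent; below -> unclassified
_EDLIB_MIN_LEN = 2000  # nt; above this use the edit-distance fast path

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _res(x) -> str:
    return x.residues if hasattr(x, "residues") else str(x)


#: default global-alignment scoring (the clustering tool's stringent
#: convention).  Permissive scores such as match 1 / mismatch -1 / gap -2
#: let unrelated DNA align at >50% "identity", which would defeat a 50%
#: clustering threshold; under these defaults unrelated DNA scores ~40%.
DEFAULT_SCORING = {"match": 2, "mismatch": -4, "gap_open": -20, "gap_extend": -2}

_GATE_K = 13
#: k-mer containment below which a long DNA pair is reported as 0%:
#: a pair diverged by substitutions at <= ~20% (the clustering regime for
#: element copies) retains containment >= 0.8^13 ~ 0.05, while unrelated
#: sequences and mosaic cross-family pairs fall well below.  Unit-cost edit
#: alignment would otherwise report ~55% "identity" for such pairs and
#: defeat the 50% threshold.
_GATE_MIN_CONTAINMENT = 0.05


def _affine_identity(a: str, b: str, scoring: dict | None = None) -> float:
    sc = {**DEFAULT_SCORING, **(scoring or {})}
    aligner = Align.PairwiseAligner(
        match_score=sc["match"],
        mismatch_score=sc["mismatch"],
        open_gap_score=sc["gap_open"],
        extend_gap_score=sc["gap_extend"],
        mode="global",
    )
    aln = aligner.align(a, b)[0]
    return 100.0 * aln.counts().identities / aln.length


def _edlib_identity(a: str, b: str) -> float:
    r = edlib.align(a, b, task="path", mode="NW")
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(r["cigar"]))
    return 100.0 * (columns - r["editDistance"]) / columns


def _kmer_containment(a: str, b: str, k: int = _GATE_K) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / min(len(ka), len(kb))


def pairwise_identity(a, b, method: str = "auto", scoring: dict | None = None) -> float:
    """Percent identity of a global alignment: matches / alignment columns,
    terminal gaps included.

    ``method``:

    - ``"affine"``: Biopython global affine-gap alignment under ``scoring``
      (defaults to :data:`DEFAULT_SCORING`) — the reference definition.
    - ``"edlib"``: unit-cost edit alignment (fast; equivalent for
      substitution-only divergence).
    - ``"auto"``: for nucleotide pairs longer than 2 kb, a k-mer containment
      gate followed by the edlib path; pairs failing the gate cannot reach
      the 50% clustering threshold and are reported as 0%.  Shorter or
      protein input uses the affine path.  Use "affine" when the exact
      identity of distant pairs matters.
    """
    ra, rb = _res(a), _res(b)
    if not ra or not rb:
        raise ValueError("pairwise_identity requires nonempty sequences")
    if method == "affine":
        return _affine_identity(ra, rb, scoring)
    if method == "edlib":
        return _edlib_identity(ra, rb)
    if min(len(ra), len(rb)) > _EDLIB_MIN_LEN and set(ra + rb) <= set("ACGTN"):
        if _kmer_containment(ra, rb) < _GATE_MIN_CONTAINMENT:
            return 0.0
        return _edlib_identity(ra, rb)
    return _affine_identity(ra, rb, scoring)


# --- greedy clustering -----------------------------------------------------


@dataclass
class Cluster:
    """A greedy identity cluster around a centroid sequence."""

    centroid_id: str
    member_ids: list[str]
    consensus: GenomeSequence | None = None
    ltr5: tuple[int, int] | None = None  # refined LTR spans on the consensus
    ltr3: tuple[int, int] | None = None
    boundary_flagged: bool = False

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    seqs: list,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    identity_fn=pairwise_identity,
) -> list[Cluster]:
    """Greedy centroid clustering at an identity threshold (>= semantics).

    Sequences are taken longest first (ties by id); each joins the first
    existing centroid reaching the threshold, else founds a new cluster.
    Deterministic for a fixed input set.
    """
    ordered = sorted(seqs, key=lambda s: (-len(_res(s)), s.id))
    clusters: list[Cluster] = []
    centroids: list = []
    for s in ordered:
        for cl, cent in zip(clusters, centroids):
            if identity_fn(s, cent) >= threshold:
                cl.member_ids.append(s.id)
                break
        else:
            clusters.append(Cluster(s.id, [s.id]))
            centroids.append(s)
    return clusters


# --- consensus -------------------------------------------------------------


def _alignment_columns(member: str, center: str):
    """Yield (center_pos | None, member_residue | None) columns from an
    edit-distance global alignment of member against center."""
    r = edlib.align(member, center, task="path", mode="NW")
    qi = ti = 0
    for n, op in _CIGAR_RE.findall(r["cigar"]):
        n = int(n)
        if op in ("=", "X", "M"):
            for _ in range(n):
                yield ti, member[qi]
                qi += 1
                ti += 1
        elif op == "I":  # consumes member (insertion relative to center)
            for _ in range(n):
                yield None, member[qi]
                qi += 1
        else:  # 'D': consumes center
            for _ in range(n):
                yield ti, None
                ti += 1


def build_consensus(members: list[GenomeSequence], cid: str = "consensus") -> GenomeSequence:
    """Center-star consensus: majority base per column around the longest
    member; ties go to the lexicographically smallest base; columns that are
    majority-gap are dropped.  Insertions relative to the center are kept as
    extra columns keyed by (center position, offset)."""
    if not members:
        raise ValueError("build_consensus requires at least one member")
    center_idx = max(
        range(len(members)), key=lambda i: (len(members[i].residues), members[i].id)
    )
    center = members[center_idx]
    n = len(members)
    L = len(center.residues)
    # column key: (center_pos, insert_offset); insert_offset 0 = the center
    # base itself, >0 = insertion columns following it
    counts: dict[tuple[int, int], dict[str, int]] = {}
    covered: dict[tuple[int, int], int] = {}

    def bump(key, base):
        counts.setdefault(key, {})
        counts[key][base] = counts[key].get(base, 0) + 1
        covered[key] = covered.get(key, 0) + 1

    for i, b in enumerate(center.residues):
        bump((i, 0), b)
    for mi, m in enumerate(members):
        if mi == center_idx:
            continue
        last_t = -1
        offset = 0
        for t, res in _alignment_columns(m.residues, center.residues):
            if t is not None:
                last_t, offset = t, 0
                if res is not None:
                    bump((t, 0), res)
                else:
                    covered[(t, 0)] = covered.get((t, 0), 0) + 1  # gap vote
            else:
                offset += 1
                bump((last_t, offset), res)
    out = []
    for key in sorted(counts):
        col = counts[key]
        present = sum(col.values())
        gaps = n - present
        if gaps > present:
            continue
        best = min(col.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(best)
    return GenomeSequence(cid, "".join(out))


# --- LTR boundary refinement ----------------------------------------------


def refine_ltr_boundaries(
    clusters: list[Cluster],
    cfg: DetectConfig | None = None,
    adopt_min_identity: float = 70.0,
) -> list[Cluster]:
    """Re-call LTR termini on cluster consensuses.

    Clusters with >= 3 members get termini from a repeat-pair search on
    their own consensus (search restricted to element-end geometry); smaller
    clusters adopt the best-matching already-defined end LTR by infix
    alignment, or are flagged when nothing aligns at the minimum identity.
    """
    cfg = cfg or DetectConfig()
    defined: list[tuple[str, str]] = []  # (cluster id, LTR residues)
    for cl in clusters:
        if cl.size >= 3 and cl.consensus is not None:
            L = len(cl.consensus)
            ends_cfg = DetectConfig(
                k=cfg.k,
                min_ltr_identity=cfg.min_ltr_identity,
                ltr_len_bounds=cfg.ltr_len_bounds,
                element_len_bounds=(int(L * 0.6), L),
                max_gap_in_extension=cfg.max_gap_in_extension,
                xdrop=cfg.xdrop,
            )
            cands = find_repeat_pairs(cl.consensus, ends_cfg)
            if cands:
                best = max(cands, key=lambda c: c.score)
                cl.ltr5 = (best.ltr5.start, best.ltr5.end)
                cl.ltr3 = (best.ltr3.start, best.ltr3.end)
                defined.append((cl.centroid_id, cl.consensus.residues[slice(*cl.ltr5)]))
            else:
                cl.boundary_flagged = True
    for cl in clusters:
        if cl.size >= 3 or cl.consensus is None:
            continue
        res = cl.consensus.residues
        best = None
        for src, ltr in defined:
            hit = edlib.align(ltr, res, task="locations", mode="HW")
            if hit["editDistance"] < 0:
                continue
            ident = 100.0 * (len(ltr) - hit["editDistance"]) / len(ltr)
            if best is None or ident > best[0]:
                best = (ident, hit["locations"][0], len(ltr))
        if best is not None and best[0] >= adopt_min_identity:
            loc5 = best[1]
            cl.ltr5 = (loc5[0], loc5[1] + 1)
            # mirror at the 3' end: best infix match within the last quarter
            tail_off = max(0, len(res) - 2 * best[2])
            ltr_seq = res[cl.ltr5[0] : cl.ltr5[1]]
            hit3 = edlib.align(ltr_seq, res[tail_off:], task="locations", mode="HW")
            if hit3["editDistance"] >= 0:
                a, b = hit3["locations"][-1]
                cl.ltr3 = (tail_off + a, tail_off + b + 1)
        else:
            cl.boundary_flagged = True
    return clusters


# --- family assignment -----------------------------------------------------


@dataclass(frozen=True)
class FamilyAssignment:
    cluster_id: str
    family: str
    superfamily: str
    best_identity: float  # percent, vs the reference panel
    support: str  # structural | similarity | both
    conflict: str | None = None


def _structural_superfamily(layout: str | None) -> str | None:
    if layout == "gag+pol+env":
        return "ERV"
    if layout == "gag-pol fused":
        return "Gypsy"
    return None


def assign_family(
    cluster: Cluster,
    panel: list[PanelEntry] | None = None,
    layout: str | None = None,
    models: dict[str, DomainModel] | None = None,
    floor: float = PANEL_FLOOR_IDENTITY,
    query: ProteinSequence | None = None,
) -> FamilyAssignment:
    """Family/superfamily for a cluster consensus.

    Best-hit identity of the cluster's RT-bearing ORF against the reference
    panel, with structural overrides: an env layout forces the ERV
    superfamily, a fused gag-pol layout restricts to Gmr/Mag.  Conflicts
    resolve in favor of structure and are recorded.

    ``query`` overrides the RT-bearing ORF scanned from the consensus (small
    clusters can have majority-vote consensuses with broken frames; a member
    ORF is then the better representative).
    """
    if cluster.consensus is None and query is None:
        raise ValueError("cluster has no consensus; build it first")
    panel = panel if panel is not None else load_bundled_panel()
    models = models or load_bundled_models()
    rt_model = models["RT"]
    if query is None:
        for orf in scan_orfs(cluster.consensus):
            if scan_protein(rt_model, orf.protein.residues, max_hits=1):
                query = orf.protein
                break
    if query is None:
        raise ValueError(f"cluster {cluster.centroid_id}: no RT-bearing ORF >500 aa")

    idents = [(pairwise_identity(query, e.protein, method="affine"), e) for e in panel]
    idents.sort(key=lambda t: (-t[0], t[1].family))
    best_ident, best_entry = idents[0]

    struct_sf = _structural_superfamily(layout)
    restrict = None
    if layout == "gag-pol fused":
        restrict = {"Gmr", "Mag"}
    elif struct_sf is not None:
        restrict = {f for f, sf in FAMILY_TO_SUPERFAMILY.items() if sf == struct_sf}

    if best_ident < floor:
        sf = struct_sf or "unclassified"
        return FamilyAssignment(cluster.centroid_id, "unclassified", sf, best_ident, "structural" if struct_sf else "similarity")

    if restrict is None:
        return FamilyAssignment(
            cluster.centroid_id,
            best_entry.family,
            best_entry.superfamily,
            best_ident,
            "similarity",
        )
    if best_entry.family in restrict:
        return FamilyAssignment(
            cluster.centroid_id, best_entry.family, best_entry.superfamily, best_ident, "both"
        )
    ident_r, entry_r = next((i, e) for i, e in idents if e.family in restrict)
    conflict = (
        f"best similarity hit {best_entry.family} ({best_ident:.1f}%) outside "
        f"structural restriction {sorted(restrict)}"
    )
    logger.info("assign_family(%s): %s", cluster.centroid_id, conflict)
    if ident_r < floor:
        return FamilyAssignment(
            cluster.centroid_id, "unclassified", struct_sf, ident_r, "structural", conflict
        )
    return FamilyAssignment(
        cluster.centroid_id, entry_r.family, entry_r.superfamily, ident_r, "structural", conflict
    )


# --- neighbor joining ------------------------------------------------------


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining tree from a distance matrix, as a Newick string.

    Standard Saitou-Nei NJ with deterministic tie-breaks (lowest index
    pair on equal Q) and negative branch lengths clamped to zero.  The
    result is unrooted (trifurcating root for n >= 3).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n == 1:
        return f"{labels[0]};"
    if n == 2:
        h = max(d[0, 1] / 2, 0.0)
        return f"({labels[0]}:{h:.6g},{labels[1]}:{h:.6g});"

    nodes = list(labels)  # Newick fragment per active node
    D = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        # distances from the new node u to every other k
        row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.vstack([D, row])
        D = np.hstack([D, np.append(row, 0.0)[:, None]])
        nodes.append(new)
        u = D.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = max(0.5 * (D[i, j] + D[i, k] - D[j, k]), 0.0)
    lj = max(0.5 * (D[i, j] + D[j, k] - D[i, k]), 0.0)
    lk = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)
    return f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g},{nodes[k]}:{lk:.6g});"


def distance_matrix_from_identity(
    seqs: list, method: str = "auto"
) -> tuple[np.ndarray, list[str]]:
    """Square matrix of (100 - identity)/100 distances plus labels."""
    labels = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[i], seqs[j], method=method)
            d[i, j] = d[j, i] = (100.0 - ident) / 100.0
    return d, labels


def cluster_elements(
    records: list[ElementRecord],
    genome: GenomeSequence,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> tuple[list[Cluster], dict[str, GenomeSequence]]:
    """Cluster full-length element sequences and build consensuses.

    Element sequences are extracted in coding orientation (minus-strand
    elements are reverse-complemented) so copies of one family cluster
    together regardless of insertion strand.  Returns clusters (with
    consensus) and the id -> oriented element sequence map.
    """
    from .seq_core import reverse_complement

    seqs = {}
    for idx, r in enumerate(records):
        iv = r.candidate.element
        s = genome.slice(iv.start, iv.end, f"elem{idx:04d}")
        if r.strand == "-":
            s = reverse_complement(s)
        seqs[f"elem{idx:04d}"] = s
    clusters = greedy_cluster(list(seqs.values()), threshold)
    for cl in clusters:
        cl.consensus = build_consensus(
            [seqs[m] for m in cl.member_ids], cid=f"cons_{cl.centroid_id}"
        )
    return clusters, seqs
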