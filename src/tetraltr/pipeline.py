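"""End-to-end orchestration: detect -> annotate -> cluster/classify -> age.

One :func:`run_pipeline` call takes a genome and returns every intermediate
product plus the mining-funnel counts, so the CLI stages and the tests share
a single code path.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .age import AgeEstimate, AgeLandscape, ClockConfig, build_landscape, estimate_age
from .annotate import ElementRecord, annotate_candidates
from .classify import (
    Cluster,
    FamilyAssignment,
    assign_family,
    cluster_elements,
    refine_ltr_boundaries,
)
from .families import PanelEntry, load_bundled_panel
from .ltr_detect import (
    DetectConfig,
    LTRCandidate,
    filter_by_element_length,
    find_repeat_pairs,
)
from .profiles import DomainModel, load_bundled_models
from .seq_core import GenomeSequence

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    genome: GenomeSequence
    candidates: list[LTRCandidate]
    filtered: list[LTRCandidate]
    records: list[ElementRecord]
    full_records: list[ElementRecord]
    clusters: list[Cluster]
    element_seqs: dict[str, GenomeSequence]
    assignments: list[FamilyAssignment]
    ages: list[AgeEstimate] = field(default_factory=list)
    landscapes: list[AgeLandscape] = field(default_factory=list)

    @property
    def funnel_counts(self) -> tuple[int, int, int]:
        return len(self.candidates), len(self.filtered), len(self.full_records)

    def ages_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"element_id": a.element_id, "K": a.K, "t_My": a.t_My}
                for a in self.ages
            ]
        )


def _cluster_layout(cluster: Cluster, records_by_id: dict[str, ElementRecord]) -> str | None:
    layouts = [
        records_by_id[m].layout for m in cluster.member_ids if m in records_by_id
    ]
    layouts = [l for l in layouts if l]
    if not layouts:
        return None
    return Counter(layouts).most_common(1)[0][0]


def _rt_orf_protein(cluster: Cluster, records_by_id: dict[str, ElementRecord]):
    """Longest RT-hit ORF protein among cluster members (classification query)."""
    best = None
    for mid in cluster.member_ids:
        rec = records_by_id.get(mid)
        if rec is None:
            continue
        for i, hit in rec.hits:
            if hit.model != "RT":
                continue
            orf = rec.orfs[i]
            if best is None or orf.length_aa > best.length_aa:
                best = orf
    return best.protein if best is not None else None


def run_pipeline(
    genome: GenomeSequence,
    cfg: DetectConfig | None = None,
    models: dict[str, DomainModel] | None = None,
    panel: list[PanelEntry] | None = None,
    clock: ClockConfig | None = None,
    cluster_threshold: float = 50.0,
    classify: bool = True,
    date_elements: bool = True,
) -> PipelineResult:
    """Run the full mining/filtering/classification/dating pipeline."""
    cfg = cfg or DetectConfig()
    models = models or load_bundled_models()
    clock = clock or ClockConfig()

    candidates = find_repeat_pairs(genome, cfg)
    filtered = filter_by_element_length(candidates, cfg)
    records = annotate_candidates(genome, filtered, models, flank=cfg.flank)
    full_records = [r for r in records if r.full_length]
    logger.info(
        "funnel %s: %d candidates -> %d length-filtered -> %d full-length",
        genome.id,
        len(candidates),
        len(filtered),
        len(full_records),
    )

    clusters: list[Cluster] = []
    seqs: dict[str, GenomeSequence] = {}
    assignments: list[FamilyAssignment] = []
    ages: list[AgeEstimate] = []
    landscapes: list[AgeLandscape] = []
    if classify and full_records:
        panel = panel if panel is not None else load_bundled_panel()
        clusters, seqs = cluster_elements(full_records, genome, cluster_threshold)
        refine_ltr_boundaries(clusters, cfg)
        records_by_id = {
            f"elem{idx:04d}": r for idx, r in enumerate(full_records)
        }
        for cl in clusters:
            layout = _cluster_layout(cl, records_by_id)
            query = _rt_orf_protein(cl, records_by_id)
            assignments.append(assign_family(cl, panel, layout, models, query=query))
        if date_elements:
            fam_by_cluster = {
                cl.centroid_id: asg.family for cl, asg in zip(clusters, assignments)
            }
            triples = []
            for cl in clusters:
                assert cl.consensus is not None
                for mid in cl.member_ids:
                    member = seqs[mid]
                    if clock.mode == "inter_ltr":
                        rec = records_by_id[mid]
                        c = rec.candidate
                        if c.ltr3 is None:
                            continue
                        est = estimate_age(
                            mid,
                            genome.residues[c.ltr5.start : c.ltr5.end],
                            genome.residues[c.ltr3.start : c.ltr3.end],
                            clock,
                        )
                    else:
                        est = estimate_age(mid, member.residues, cl.consensus.residues, clock)
                    ages.append(est)
                    triples.append((est, len(member), fam_by_cluster[cl.centroid_id]))
            landscapes = build_landscape(triples, len(genome))
    return PipelineResult(
        genome,
        candidates,
        filtered,
        records,
        full_records,
        clusters,
        seqs,
        assignments,
        ages,
        landscapes,
    )
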