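"""End-to-end orchestration: dedupe -> span filter -> promoter calls ->
frame filter -> classification -> frequency tables -> junction support.

Every stage logs its counts and the final :class:`RunReport` carries the full
conservation accounting (every input read lands in exactly one bucket), the
promoter-scoped frequency tables, the usage of each reference junction, and
optional short-read support flags.  Reports serialize deterministically, so
two runs with the same inputs and seed are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import __version__ as _pkg_version
from .locus_model import (
    GenomeSeq,
    LocusAnnotation,
    SpliceJunction,
    TranscriptAlignment,
)
from .longread_filter import (
    UNASSIGNED,
    FilterReport,
    assign_promoter,
    collapse_duplicates,
    span_filter,
)
from .orf_engine import OrfResult, frame_filter, predict_orf
from .isoform_classifier import (
    FrequencyTable,
    IsoformClass,
    classify,
    frequency_table,
    junction_usage,
    name_novel_classes,
    windowed_signature,
)
from .shortread_support import bpm_coverage, count_junctions, support_check

log = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Machine-readable result of one reannotation run."""

    n_input: int
    duplicates_removed: int
    span_removed: int
    skipped_wrong_reference: int
    orf_rejections: dict[str, int]
    n_survivors: int
    promoter_counts: dict[str, int]          # among span-filter survivors
    survivor_promoter_counts: dict[str, int]  # among frame-filter survivors
    frequency_tables: dict[str, dict]
    junction_usage_table: list[dict]
    support: list[dict] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = _pkg_version
    class_assignments: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        accounted = (self.n_survivors + self.duplicates_removed + self.span_removed
                     + self.skipped_wrong_reference + sum(self.orf_rejections.values()))
        if accounted != self.n_input:
            raise AssertionError(
                f"conservation violated: {self.n_input} in, {accounted} accounted")

    def to_json(self, handle=None) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if handle is not None:
            handle.write(text + "\n")
        return text


def _orf_call(
    read: TranscriptAlignment,
    promoter: str,
    locus: LocusAnnotation,
    genome: GenomeSeq,
) -> OrfResult:
    """ORF status under the read's promoter; unassigned reads try both starts.

    An unassigned read is kept if either start yields an in-frame ORF (the
    B start preferred when both do) and its result is flagged by the start
    label actually used.
    """
    if promoter != UNASSIGNED:
        return predict_orf(read, locus, genome, promoter)
    results = {lab: predict_orf(read, locus, genome, lab)
               for lab in sorted(locus.start_codons)}
    for lab in sorted(results, reverse=True):  # prefer the downstream (B) start
        if results[lab].frame_status == "in_frame":
            return results[lab]
    return results[sorted(results)[0]]


def run_reannotation(
    genome: GenomeSeq,
    locus: LocusAnnotation,
    long_reads: Sequence[TranscriptAlignment],
    short_reads: Sequence[TranscriptAlignment] | None = None,
    *,
    end_tolerance: int = 0,
    min_support: int = 1,
    bin_size: int = 5,
    seed: int | None = None,
    config_echo: Mapping | None = None,
) -> tuple[RunReport, dict]:
    """Run the full long-read reannotation pipeline.

    Returns the :class:`RunReport` plus a dict of in-memory artifacts
    (surviving reads, class assignment, junction counts, coverage track) for
    callers that want more than the serializable report.
    """
    n_input = len(long_reads)
    log.info("input: %d long reads", n_input)

    deduped, n_dup = collapse_duplicates(list(long_reads), end_tolerance=end_tolerance)
    log.info("dedupe: removed %d PCR duplicates", n_dup)

    kept, span_removed, skipped = span_filter(deduped, locus)
    log.info("span filter: kept %d, removed %d, skipped %d",
             len(kept), len(span_removed), len(skipped))

    promoters = {r.read_id: assign_promoter(r, locus) for r in kept}
    promoter_counts = {lab: 0 for lab in [*sorted(locus.promoters), UNASSIGNED]}
    for lab in promoters.values():
        promoter_counts[lab] += 1
    log.info("promoter assignment: %s", promoter_counts)

    orf_results = {r.read_id: _orf_call(r, promoters[r.read_id], locus, genome)
                   for r in kept}
    survivors, rejected = frame_filter(kept, orf_results)
    orf_rejections: dict[str, int] = {}
    for _, reason in rejected:
        orf_rejections[reason] = orf_rejections.get(reason, 0) + 1
    log.info("frame filter: %d in frame, rejections %s", len(survivors), orf_rejections)

    survivor_promoter_counts = {lab: 0 for lab in promoter_counts}
    for r in survivors:
        survivor_promoter_counts[promoters[r.read_id]] += 1

    assignment: dict[str, IsoformClass] = classify(survivors, locus) if survivors else {}
    tables: dict[str, FrequencyTable] = {}
    for scope in sorted(locus.promoters):
        scope_ids = [r.read_id for r in survivors if promoters[r.read_id] == scope]
        if not scope_ids:
            continue
        assignment = name_novel_classes(assignment, scope_ids, scope)
        tables[scope] = frequency_table(assignment, scope_ids, scope)

    # usage of each reference junction over all frame-filter survivors
    usage_rows: list[dict] = []
    if survivors:
        ref_junctions: dict[SpliceJunction, str] = {}
        for name, iso in locus.reference_isoforms.items():
            for j in windowed_signature(iso, locus):
                ref_junctions.setdefault(j, name)
        for j in sorted(ref_junctions):
            count, denom, pct = junction_usage(survivors, j)
            usage_rows.append({
                "junction": [j.start, j.end],
                "first_seen_in": ref_junctions[j],
                "count": count,
                "denominator": denom,
                "percent": pct,
            })

    support_rows: list[dict] = []
    jmap: dict[SpliceJunction, int] = {}
    track = None
    if short_reads is not None:
        jmap = count_junctions(short_reads)
        track = bpm_coverage(short_reads, bin_size, genome.length(locus.contig),
                             contig=locus.contig)
        seen: set[str] = set()
        for cls in assignment.values():
            if cls.label in seen:
                continue
            seen.add(cls.label)
            supported, evidence = support_check(cls, jmap, min_reads=min_support)
            support_rows.append({
                "class": cls.label,
                "supported": supported,
                "evidence": {f"{j.start}-{j.end}": c for j, c in sorted(evidence.items())},
            })
        support_rows.sort(key=lambda row: row["class"])

    report = RunReport(
        n_input=n_input,
        duplicates_removed=n_dup,
        span_removed=len(span_removed),
        skipped_wrong_reference=len(skipped),
        orf_rejections=orf_rejections,
        n_survivors=len(survivors),
        promoter_counts=promoter_counts,
        survivor_promoter_counts=survivor_promoter_counts,
        frequency_tables={s: t.as_dict() for s, t in tables.items()},
        junction_usage_table=usage_rows,
        support=support_rows,
        config_echo=dict(config_echo or {}),
        seed=seed,
        class_assignments={rid: cls.label for rid, cls in sorted(assignment.items())},
    )
    report.validate()
    artifacts = {
        "survivors": survivors,
        "promoters": promoters,
        "orf_results": orf_results,
        "assignment": assignment,
        "tables": tables,
        "junction_counts": jmap,
        "coverage": track,
        "span_removed": span_removed,
        "filter_report": FilterReport(
            input_count=n_input,
            duplicates_removed=n_dup,
            span_removed=len(span_removed),
            skipped_wrong_reference=len(skipped),
            promoter_counts=promoter_counts,
            surviving_ids=[r.read_id for r in kept],
        ),
    }
    return report, artifacts
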