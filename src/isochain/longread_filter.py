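"""Read-level filters: PCR-duplicate collapse, locus span filter, promoter calls.

The span filter implements the full-length criterion: a read is kept only if
its transcription-direction 5' terminus lies strictly upstream of the shared
exon-2 splice acceptor (so it can carry promoter evidence) and its 3' terminus
reaches at least the final base of the shared stop triplet (so the whole
reading frame is observed).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .locus_model import (
    AnnotationError,
    ConfigError,
    LocusAnnotation,
    TranscriptAlignment,
    junction_chain,
)

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class FilterReport:
    """Bookkeeping for the read-level filters; conserves every input read."""

    input_count: int = 0
    duplicates_removed: int = 0
    span_removed: int = 0
    skipped_wrong_reference: int = 0
    promoter_counts: dict[str, int] = field(default_factory=dict)
    surviving_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        total = (len(self.surviving_ids) + self.duplicates_removed
                 + self.span_removed + self.skipped_wrong_reference)
        if total != self.input_count:
            raise AssertionError(
                f"read conservation violated: {self.input_count} in, {total} accounted")

    def to_json(self, handle) -> None:
        json.dump(self.__dict__, handle, indent=2, sort_keys=True)


def collapse_duplicates(
    reads: list[TranscriptAlignment],
    end_tolerance: int = 0,
) -> tuple[list[TranscriptAlignment], int]:
    """Collapse PCR duplicates to their first-seen representative.

    Two reads are duplicates when they share the strand and the identical
    junction chain, and both the 5' and the 3' end lie within
    ``end_tolerance`` nt of the representative's.  The default tolerance of 0
    (exact coordinate identity) is the most conservative reproducible rule;
    survivors keep input order.
    """
    if end_tolerance < 0:
        raise ConfigError(f"end_tolerance must be >= 0, got {end_tolerance}")
    if len({(r.contig, r.strand) for r in reads}) > 1:
        raise AnnotationError("duplicate collapse expects reads on one contig/strand")

    kept: list[TranscriptAlignment] = []
    reps: dict[tuple, list[tuple[int, int]]] = {}
    removed = 0
    for r in reads:
        sig = (r.strand, junction_chain(r))
        ends = (r.start, r.end)
        bucket = reps.setdefault(sig, [])
        if any(abs(ends[0] - s) <= end_tolerance and abs(ends[1] - e) <= end_tolerance
               for s, e in bucket):
            removed += 1
            continue
        bucket.append(ends)
        kept.append(r)
    return kept, removed


def span_filter(
    reads: list[TranscriptAlignment],
    locus: LocusAnnotation,
) -> tuple[list[TranscriptAlignment], list[TranscriptAlignment], list[TranscriptAlignment]]:
    """Keep potentially full-length reads; returns (kept, removed, skipped).

    ``skipped`` holds reads on the wrong contig or strand, which are warned
    about and counted separately from span-based removals.
    """
    kept, removed, skipped = [], [], []
    stop_last = locus.stop_last_base()
    for r in reads:
        if r.contig != locus.contig or r.strand != locus.strand:
            log.warning("read %s on %s%s does not match locus %s%s; skipped",
                        r.read_id, r.contig, r.strand, locus.contig, locus.strand)
            skipped.append(r)
            continue
        starts_upstream = locus.is_upstream(r.five_prime, locus.exon2_acceptor)
        reaches_stop = not locus.is_upstream(r.three_prime, stop_last)
        (kept if starts_upstream and reaches_stop else removed).append(r)
    return kept, removed, skipped


def assign_promoter(read: TranscriptAlignment, locus: LocusAnnotation) -> str:
    """Promoter label whose first exon contains the read's 5' terminus.

    Because the upstream promoter's first exon precedes the downstream one, a
    read starting inside the upstream exon is assigned there even though it
    also spans the downstream promoter region.  A 5' terminus inside no
    promoter first exon yields ``"unassigned"``.
    """
    p5 = read.five_prime
    for label, exon in locus.promoters.items():
        if exon.contains(p5):
            return label
    return UNASSIGNED
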