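"""Short-read junction counting, BPM coverage, and class support checks."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .locus_model import (
    ConfigError,
    SpliceJunction,
    TranscriptAlignment,
    junction_chain,
)
from .isoform_classifier import IsoformClass


def count_junctions(reads: Iterable[TranscriptAlignment]) -> dict[SpliceJunction, int]:
    """Junction -> number of reads spanning it.

    Every multi-block read contributes one count to each of its junctions;
    mono-block reads contribute nothing.
    """
    counts: dict[SpliceJunction, int] = {}
    for r in reads:
        for j in junction_chain(r):
            counts[j] = counts.get(j, 0) + 1
    return counts


@dataclass
class CoverageTrack:
    """BPM-normalized binned coverage over one contig."""

    contig: str
    bin_size: int
    values: np.ndarray  # one value per bin, tiling [0, contig_length)
    total_reads: int

    def to_bedgraph(self, handle) -> None:
        if isinstance(handle, str):
            with open(handle, "w") as fh:
                self.to_bedgraph(fh)
            return
        for i, v in enumerate(self.values):
            if v:
                handle.write(f"{self.contig}\t{i * self.bin_size}"
                             f"\t{(i + 1) * self.bin_size}\t{v:.6g}\n")


def bpm_coverage(
    reads: Sequence[TranscriptAlignment],
    bin_size: int,
    contig_length: int,
    contig: str | None = None,
) -> CoverageTrack:
    """Bins-per-million coverage: binned read counts / (total reads / 1e6).

    A read overlaps a bin when any of its exon blocks intersects it, and
    counts once per bin however many blocks fall inside.  With zero reads the
    track is all zero.  BPM depends only on the total mapped-read count; no
    genome-size correction applies.
    """
    if bin_size < 1:
        raise ConfigError(f"bin_size must be >= 1, got {bin_size}")
    n_bins = -(-contig_length // bin_size)
    raw = np.zeros(n_bins, dtype=float)
    contig = contig or (reads[0].contig if reads else "")
    for r in reads:
        bins: set[int] = set()
        for ex in r.exons:
            bins.update(range(ex.start // bin_size, -(-ex.end // bin_size)))
        for b in bins:
            raw[b] += 1.0
    total = len(reads)
    values = raw / (total / 1e6) if total else raw
    return CoverageTrack(contig=contig, bin_size=bin_size, values=values,
                         total_reads=total)


def support_check(
    cls: IsoformClass,
    jmap: Mapping[SpliceJunction, int],
    min_reads: int = 1,
) -> tuple[bool, dict[SpliceJunction, int]]:
    """Is every junction of the class signature seen in >= min_reads reads?

    Returns the flag plus the per-junction evidence.  A class with an empty
    signature (no window junctions) is trivially supported.
    """
    if min_reads < 1:
        raise ConfigError(f"min_reads must be >= 1, got {min_reads}")
    evidence = {j: jmap.get(j, 0) for j in cls.signature}
    return all(c >= min_reads for c in evidence.values()), evidence
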