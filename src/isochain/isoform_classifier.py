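"""Junction-chain isoform classes, novel-class naming, frequency tables.

Reads are grouped by their *windowed junction signature*: the ordered introns
falling inside the analysis window from the shared exon-2 splice acceptor to
the shared stop codon.  Restricting signatures to this window means 5'-end
(promoter/UTR) and 3'-end variability never split classes — only ORF-region
splicing differences do.  Classes whose signature equals a reference
isoform's windowed signature inherit the reference name; the rest are novel
and are named ``<scope>-Alt-k`` by descending abundance within a promoter
scope.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .locus_model import (
    ConfigError,
    LocusAnnotation,
    SpliceJunction,
    TranscriptAlignment,
    junction_chain,
)

Signature = tuple[SpliceJunction, ...]


def round_half_up_percent(count: int, denominator: int) -> int:
    """Integer percent with exact round-half-up (0.5 always rounds up)."""
    if denominator <= 0:
        raise ConfigError("denominator must be positive")
    return math.floor(100 * count / denominator + 0.5)


@dataclass(frozen=True)
class IsoformClass:
    """A splice-isoform class: its windowed signature and display label."""

    signature: Signature
    label: str
    scope: str | None = None


@dataclass
class FrequencyTable:
    """Per-class counts and integer percentages over one scope's denominator."""

    scope: str
    rows: list[tuple[str, int, int]]  # (label, count, percent)
    denominator: int

    def __post_init__(self) -> None:
        total = sum(c for _, c, _ in self.rows)
        if total != self.denominator:
            raise AssertionError(
                f"scope {self.scope}: counts {total} != denominator {self.denominator}")
        for label, count, pct in self.rows:
            if pct != round_half_up_percent(count, self.denominator):
                raise AssertionError(f"{label}: percent {pct} inconsistent with count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["class", "count", "percent"])

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "denominator": self.denominator,
            "rows": [list(r) for r in self.rows],
        }


# ---------------------------------------------------------------------------
# Signatures and classification
# ---------------------------------------------------------------------------

def windowed_signature(chain: TranscriptAlignment, locus: LocusAnnotation) -> Signature:
    """Junctions of ``chain`` whose intron lies inside the analysis window."""
    lo = min(locus.exon2_acceptor, locus.stop_last_base())
    hi = max(locus.exon2_acceptor, locus.stop_last_base())
    return tuple(j for j in junction_chain(chain) if lo <= j.start and j.end - 1 <= hi)


def classify(
    reads: Iterable[TranscriptAlignment],
    locus: LocusAnnotation,
) -> dict[str, IsoformClass]:
    """Assign each read its isoform class by windowed junction signature.

    Signatures matching a reference isoform take the reference's name; other
    signatures become provisional novel classes (``novel-k`` in first-seen
    order) until :func:`name_novel_classes` renames them within a scope.
    """
    # references from different promoters can share a windowed signature
    # (same ORF-region splicing); the first-listed reference keeps the label
    ref_sigs: dict[Signature, str] = {}
    for name, iso in locus.reference_isoforms.items():
        ref_sigs.setdefault(windowed_signature(iso, locus), name)
    by_sig: dict[Signature, IsoformClass] = {}
    out: dict[str, IsoformClass] = {}
    novel_seen = 0
    for r in reads:
        sig = windowed_signature(r, locus)
        cls = by_sig.get(sig)
        if cls is None:
            if sig in ref_sigs:
                cls = IsoformClass(sig, ref_sigs[sig])
            else:
                novel_seen += 1
                cls = IsoformClass(sig, f"novel-{novel_seen}")
            by_sig[sig] = cls
        out[r.read_id] = cls
    return out


def _transcription_order_key(sig: Signature, strand: str):
    """Sort key putting the more upstream distinguishing junction first."""
    if strand == "+":
        return tuple((j.start, j.end) for j in sig)
    return tuple((-j.end, -j.start) for j in reversed(sig))


def name_novel_classes(
    assignment: Mapping[str, IsoformClass],
    scope_ids: Sequence[str],
    scope: str,
) -> dict[str, IsoformClass]:
    """Rename novel classes ``<scope>-Alt-k`` by descending count in scope.

    Ties are broken in favour of the class whose earliest distinguishing
    junction is more upstream in transcription direction.  Reference-labelled
    classes are untouched apart from having the scope recorded.
    """
    counts: dict[IsoformClass, int] = {}
    for rid in scope_ids:
        cls = assignment[rid]
        counts[cls] = counts.get(cls, 0) + 1
    strand = next(iter(assignment.values())).signature[0].strand if any(
        c.signature for c in counts) else "+"

    novel = [c for c in counts if c.label.startswith("novel-")]
    novel.sort(key=lambda c: (-counts[c], _transcription_order_key(c.signature, strand)))
    rename = {c: f"{scope}-Alt-{k}" for k, c in enumerate(novel, 1)}

    out = dict(assignment)
    for rid in scope_ids:
        cls = assignment[rid]
        out[rid] = replace(cls, label=rename.get(cls, cls.label), scope=scope)
    return out


def frequency_table(
    assignment: Mapping[str, IsoformClass],
    scope_ids: Sequence[str],
    scope: str,
) -> FrequencyTable:
    """Integer-percent abundance table of classes among ``scope_ids``."""
    if not scope_ids:
        raise ConfigError(f"empty scope {scope!r}: no reads to tabulate")
    counts: dict[str, int] = {}
    for rid in scope_ids:
        label = assignment[rid].label
        counts[label] = counts.get(label, 0) + 1
    denom = len(scope_ids)
    rows = [
        (label, count, round_half_up_percent(count, denom))
        for label, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return FrequencyTable(scope=scope, rows=rows, denominator=denom)


def junction_usage(
    reads: Sequence[TranscriptAlignment],
    junction: SpliceJunction,
) -> tuple[int, int, int]:
    """(count, denominator, integer percent) of reads using ``junction`` exactly."""
    if not reads:
        raise ConfigError("empty scope: no reads for junction usage")
    count = sum(1 for r in reads if junction in junction_chain(r))
    return count, len(reads), round_half_up_percent(count, len(reads))


def verify_printed_fraction(count: int, denominator: int, printed_percent: int) -> dict:
    """Check a reported count/denominator pair against its printed percent.

    Returns the recomputed round-half-up percent and whether it matches; used
    to flag arithmetically inconsistent published fractions rather than
    silently reconciling them.
    """
    computed = round_half_up_percent(count, denominator)
    return {
        "count": count,
        "denominator": denominator,
        "printed_percent": printed_percent,
        "computed_percent": computed,
        "consistent": computed == printed_percent,
    }
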