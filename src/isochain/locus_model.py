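"""Coordinate and gene-model primitives shared by the whole pipeline.

Conventions
-----------
* All internal coordinates are 0-based, half-open ``[start, end)`` on the
  forward genomic axis, regardless of strand.
* GTF I/O converts to/from the format's 1-based inclusive coordinates;
  BED12 is natively 0-based half-open.
* Strand is carried on every interval-bearing object and all
  transcription-direction logic (5'/3' termini, upstream/downstream) is
  strand-aware.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AnnotationError(ValueError):
    """Raised when a gene-model input is structurally invalid."""


class ConsistencyError(AnnotationError):
    """Raised when locus-config coordinates disagree with the gene models."""


class BoundsError(IndexError):
    """Raised when an interval escapes its contig."""


class ConfigError(ValueError):
    """Raised for invalid run/simulation parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: the gap between two consecutive exons of one read.

    ``start``/``end`` bound the intron half-open; ``start`` is the donor-side
    boundary and ``end`` the acceptor-side boundary on the forward axis (the
    biological donor/acceptor swap roles on the minus strand, but the genomic
    interval is the signature either way).
    """

    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"empty junction [{self.start}, {self.end})")


@dataclass(frozen=True)
class TranscriptAlignment:
    """One spliced read alignment: an ordered chain of exon blocks."""

    read_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"read {self.read_id}: no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.contig != self.contig or ex.strand != self.strand:
                raise AnnotationError(
                    f"read {self.read_id}: exon on {ex.contig}{ex.strand} "
                    f"inside chain on {self.contig}{self.strand}"
                )
            if ex.start <= prev_end:
                raise AnnotationError(
                    f"read {self.read_id}: exons unsorted/overlapping/abutting at {ex.start}"
                )
            prev_end = ex.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic position of the read's last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)


def junction_chain(chain: TranscriptAlignment) -> tuple[SpliceJunction, ...]:
    """The ordered introns implied by a spliced alignment (genomic order).

    A mono-exon chain has no junctions.
    """
    return tuple(
        SpliceJunction(chain.contig, chain.strand, a.end, b.start)
        for a, b in zip(chain.exons, chain.exons[1:])
    )


@dataclass
class GenomeSeq:
    """Uppercase nucleotide sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise AnnotationError(f"contig {name}: invalid bases {sorted(bad)}")
            self.contigs[name] = seq

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand slice; exactly ``end - start`` characters."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise BoundsError(f"unknown contig {contig!r}") from None
        if not (0 <= start <= end <= len(seq)):
            raise BoundsError(
                f"[{start}, {end}) outside contig {contig} (length {len(seq)})"
            )
        return seq[start:end]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @classmethod
    def from_fasta(cls, handle) -> "GenomeSeq":
        if isinstance(handle, str):
            with open(handle) as fh:
                return cls.from_fasta(fh)
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")})

    def to_fasta(self, handle) -> None:
        if isinstance(handle, str):
            with open(handle, "w") as fh:
                self.to_fasta(fh)
            return
        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()]
        SeqIO.write(records, handle, "fasta")


@dataclass
class LocusAnnotation:
    """The locus-level facts the reannotation pipeline needs.

    ``start_codons`` maps promoter label to the genomic position of the first
    CDS base (for minus-strand loci this is the highest-coordinate base of the
    start triplet). ``exon2_acceptor`` is the first transcribed base of the
    shared exon 2. ``shared_stop`` is the stop triplet's genomic interval.
    """

    contig: str
    strand: str
    promoters: dict[str, GenomicInterval]
    start_codons: dict[str, int]
    exon2_acceptor: int
    shared_stop: GenomicInterval
    znf_exons: list[GenomicInterval]
    reference_isoforms: dict[str, TranscriptAlignment]

    def __post_init__(self) -> None:
        if set(self.promoters) != set(self.start_codons):
            raise AnnotationError(
                f"promoter labels {sorted(self.promoters)} != start-codon labels "
                f"{sorted(self.start_codons)}"
            )
        stop_last = self.shared_stop.end - 1 if self.strand == "+" else self.shared_stop.start
        for label, pos in self.start_codons.items():
            if not self.is_upstream(pos, stop_last):
                raise ConsistencyError(
                    f"shared stop not downstream of start codon {label!r}"
                )
        for name, iso in self.reference_isoforms.items():
            if iso.contig != self.contig or iso.strand != self.strand:
                raise AnnotationError(f"isoform {name}: wrong contig/strand")

    # -- transcription-direction helpers ------------------------------------
    def is_upstream(self, a: int, b: int) -> bool:
        """True iff position ``a`` is strictly upstream of ``b``."""
        return a < b if self.strand == "+" else a > b

    def is_downstream(self, a: int, b: int) -> bool:
        return a > b if self.strand == "+" else a < b

    def stop_last_base(self) -> int:
        """Genomic position of the final (3'-most) base of the stop triplet."""
        return self.shared_stop.end - 1 if self.strand == "+" else self.shared_stop.start


# ---------------------------------------------------------------------------
# Spliced sequence
# ---------------------------------------------------------------------------

def spliced_sequence(genome: GenomeSeq, chain: TranscriptAlignment) -> str:
    """Concatenated exon sequence in transcription order.

    Reverse-complemented for minus-strand chains; length equals the sum of
    exon lengths.
    """
    forward = "".join(genome.fetch(chain.contig, ex.start, ex.end) for ex in chain.exons)
    return forward if chain.strand == "+" else reverse_complement(forward)


def genomic_to_spliced(chain: TranscriptAlignment, pos: int) -> int:
    """Map a genomic position inside an exon to its 0-based spliced offset."""
    exons = chain.exons if chain.strand == "+" else tuple(reversed(chain.exons))
    offset = 0
    for ex in exons:
        if ex.contains(pos):
            within = (pos - ex.start) if chain.strand == "+" else (ex.end - 1 - pos)
            return offset + within
        offset += len(ex)
    raise BoundsError(f"position {pos} not exonic in read {chain.read_id}")


def spliced_to_genomic(chain: TranscriptAlignment, offset: int) -> int:
    """Inverse of :func:`genomic_to_spliced`."""
    if not 0 <= offset < chain.spliced_length():
        raise BoundsError(f"spliced offset {offset} outside read {chain.read_id}")
    exons = chain.exons if chain.strand == "+" else tuple(reversed(chain.exons))
    for ex in exons:
        if offset < len(ex):
            return ex.start + offset if chain.strand == "+" else ex.end - 1 - offset
        offset -= len(ex)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def write_gtf(isoforms: Mapping[str, TranscriptAlignment], handle, source: str = "isochain") -> None:
    """Write transcript models as GTF (1-based inclusive) transcript+exon rows."""
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_gtf(isoforms, fh, source=source)
        return
    for name, iso in isoforms.items():
        attrs = f'gene_id "{name}"; transcript_id "{name}";'
        rows = [(iso.contig, source, "transcript", iso.start + 1, iso.end, ".", iso.strand, ".", attrs)]
        for i, ex in enumerate(iso.exons, 1):
            rows.append(
                (iso.contig, source, "exon", ex.start + 1, ex.end, ".", iso.strand, ".",
                 attrs + f' exon_number "{i}";')
            )
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def read_gtf(handle) -> dict[str, TranscriptAlignment]:
    """Read transcript models (exon rows grouped by transcript_id) from GTF.

    ``handle`` may be an open text stream, a filesystem path, or GTF text
    itself (a string containing newlines).
    """
    import os

    if isinstance(handle, str) and "\n" not in handle and os.path.exists(handle):
        with open(handle) as fh:
            return read_gtf(fh)
    text = handle.read() if hasattr(handle, "read") else handle
    if not text.strip():
        raise AnnotationError("GTF contains no records")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = feat.attributes["transcript_id"][0]
        grouped.setdefault(tid, []).append(feat)
        meta[tid] = (feat.seqid, feat.strand)
    if not grouped:
        raise AnnotationError("GTF contains no exon records")
    isoforms: dict[str, TranscriptAlignment] = {}
    for tid, feats in grouped.items():
        contig, strand = meta[tid]
        exons = tuple(
            GenomicInterval(contig, f.start - 1, f.end, strand)
            for f in sorted(feats, key=lambda f: f.start)
        )
        isoforms[tid] = TranscriptAlignment(tid, contig, strand, exons)
    return isoforms


# ---------------------------------------------------------------------------
# BED12 I/O
# ---------------------------------------------------------------------------

def write_bed12(reads: Iterable[TranscriptAlignment], handle) -> None:
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_bed12(reads, fh)
        return
    for r in reads:
        sizes = ",".join(str(len(ex)) for ex in r.exons) + ","
        starts = ",".join(str(ex.start - r.start) for ex in r.exons) + ","
        handle.write(
            "\t".join(
                str(x)
                for x in (
                    r.contig, r.start, r.end, r.read_id, 0, r.strand,
                    r.start, r.end, "0,0,0", len(r.exons), sizes, starts,
                )
            )
            + "\n"
        )


def read_bed12(handle) -> list[TranscriptAlignment]:
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_bed12(fh)
    reads: list[TranscriptAlignment] = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise AnnotationError(f"BED12 line {lineno}: {len(f)} fields")
        contig, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        n = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n or len(starts) != n:
            raise AnnotationError(f"BED12 line {lineno}: blockCount mismatch")
        exons = tuple(
            GenomicInterval(contig, chrom_start + s, chrom_start + s + size, strand)
            for s, size in zip(starts, sizes)
        )
        reads.append(TranscriptAlignment(name, contig, strand, exons))
    return reads


# ---------------------------------------------------------------------------
# Locus config -> LocusAnnotation
# ---------------------------------------------------------------------------

def _as_interval(contig: str, strand: str, pair: Sequence[int]) -> GenomicInterval:
    return GenomicInterval(contig, int(pair[0]), int(pair[1]), strand)


def read_locus_annotation(gtf_stream, locus_config: Mapping) -> LocusAnnotation:
    """Assemble a validated :class:`LocusAnnotation` from a GTF plus a config.

    The config (a mapping, typically loaded from YAML) names the contig and
    strand, the promoter first exons, start-codon positions, the shared exon-2
    acceptor, the shared stop triplet, the zinc-finger exons, and which GTF
    transcripts are the reference isoforms.

    Raises
    ------
    AnnotationError
        if a named reference isoform is missing from the GTF.
    ConsistencyError
        if a configured coordinate falls outside every reference exon, or the
        shared stop is not downstream of every start codon.
    """
    cfg = dict(locus_config)
    contig, strand = cfg["contig"], cfg["strand"]
    all_isoforms = read_gtf(gtf_stream)
    wanted = list(cfg["reference_isoforms"])
    missing = [n for n in wanted if n not in all_isoforms]
    if missing:
        raise AnnotationError(f"reference isoforms missing from GTF: {missing}")
    isoforms = {n: all_isoforms[n] for n in wanted}

    exon_union = [ex for iso in isoforms.values() for ex in iso.exons]

    def _check_exonic(pos: int, what: str) -> None:
        if not any(ex.contains(pos) for ex in exon_union):
            raise ConsistencyError(f"{what} at {pos} is outside every reference exon")

    promoters = {lab: _as_interval(contig, strand, iv) for lab, iv in cfg["promoters"].items()}
    start_codons = {lab: int(p) for lab, p in cfg["start_codons"].items()}
    for lab, pos in start_codons.items():
        _check_exonic(pos, f"start codon {lab!r}")
    exon2_acceptor = int(cfg["exon2_acceptor"])
    _check_exonic(exon2_acceptor, "exon-2 acceptor")
    shared_stop = _as_interval(contig, strand, cfg["shared_stop"])
    _check_exonic(shared_stop.start, "shared stop")
    _check_exonic(shared_stop.end - 1, "shared stop")
    znf_exons = [_as_interval(contig, strand, iv) for iv in cfg["znf_exons"]]

    return LocusAnnotation(
        contig=contig,
        strand=strand,
        promoters=promoters,
        start_codons=start_codons,
        exon2_acceptor=exon2_acceptor,
        shared_stop=shared_stop,
        znf_exons=znf_exons,
        reference_isoforms=isoforms,
    )


def locus_config_dict(locus: LocusAnnotation) -> dict:
    """The config mapping that, with the matching GTF, round-trips ``locus``."""
    return {
        "contig": locus.contig,
        "strand": locus.strand,
        "promoters": {lab: [iv.start, iv.end] for lab, iv in locus.promoters.items()},
        "start_codons": dict(locus.start_codons),
        "exon2_acceptor": locus.exon2_acceptor,
        "shared_stop": [locus.shared_stop.start, locus.shared_stop.end],
        "znf_exons": [[iv.start, iv.end] for iv in locus.znf_exons],
        "reference_isoforms": list(locus.reference_isoforms),
    }
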