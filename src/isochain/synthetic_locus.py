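"""Synthetic two-promoter toy locus and read simulators.

The generator builds a single ~10 kb contig carrying, in transcription order:
a promoter-A first exon (with the upstream start codon), a promoter-B first
exon, a shared exon 2 split by an optional small intron, an exon 3 with two
alternative acceptors (extended upstream vs short downstream) and an optional
internal intron, and two zinc-finger exons ending in the shared stop triplet.

Frame safety is by construction: every optional splice difference (the exon-3
extension, the exon-3 internal intron) has length divisible by three and is
codon-aligned in the shared reading frame, and every codon slot in the coding
region is filled with a non-stop codon (start/stop triplets excepted), so all
reference isoforms translate from their start codon to the shared stop with no
internal in-frame stop.  The exon-2 internal intron lies in the 5' UTR of the
downstream (B) start codon, so its retention never breaks the B frame.

Long-read noise model: PCR duplicates are exact coordinate copies; distinct
original molecules always receive distinct (5' end, 3' end) jitter, so exact
coordinate identity is equivalent to duplication.  5'-truncated reads lose a
uniform prefix of their spliced sequence.  Artifact reads carry a single-base
deletion inside exon 3, which shifts the downstream frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .locus_model import (
    ConfigError,
    GenomeSeq,
    GenomicInterval,
    LocusAnnotation,
    TranscriptAlignment,
    reverse_complement,
    spliced_sequence,
)

STOP_CODONS = ("TAA", "TAG", "TGA")

# -- fixed toy layout on the forward template (coordinates in nt) -----------
CONTIG = "toyX"
CONTIG_LEN = 10_000
_EXON_A1 = (500, 800)
_A_START = 699          # first CDS base of the A frame; A1 CDS part = 101 nt
_EXON_B1 = (1500, 1800)
_EXON_2A = (2500, 2700)
_INTRON_2 = (2700, 2860)   # optional; 5' UTR relative to the B start codon
_EXON_2B = (2860, 3600)
_B_START = 3000         # codon-aligned with the shared downstream frame
_EXT_ACCEPTOR = 4300    # extended exon-3 acceptor
_SHORT_ACCEPTOR = 4450  # short acceptor; extension = 150 nt (3 | 150)
_INTRON_3 = (4600, 4660)   # optional internal exon-3 intron, 60 nt
_EXON_3_END = 4900
_EXON_4 = (5600, 5900)
_EXON_5 = (6600, 7200)
_STOP = (6897, 6900)    # shared stop triplet; 3' UTR follows to 7200

FIVE_PRIME_JITTER = 30   # distinct molecules draw ends on this grid
THREE_PRIME_JITTER = 300


@dataclass
class ToyLayout:
    """All toy coordinates, mirrored onto the requested strand."""

    strand: str
    contig_len: int = CONTIG_LEN
    frame_incompatible_extension: bool = False

    def _iv(self, pair: tuple[int, int]) -> GenomicInterval:
        s, e = pair
        if self.strand == "-":
            s, e = self.contig_len - e, self.contig_len - s
        return GenomicInterval(CONTIG, s, e, self.strand)

    def _pos(self, p: int) -> int:
        return p if self.strand == "+" else self.contig_len - 1 - p

    @property
    def exon_a1(self) -> GenomicInterval:
        return self._iv(_EXON_A1)

    @property
    def exon_b1(self) -> GenomicInterval:
        return self._iv(_EXON_B1)

    @property
    def short_acceptor(self) -> int:
        # +1 breaks the 3 | extension-length guarantee for negative tests
        return _SHORT_ACCEPTOR + (1 if self.frame_incompatible_extension else 0)

    def body_exons(self, pattern: str) -> tuple[GenomicInterval, ...]:
        """Exon blocks downstream of the first exon for one splice pattern.

        Patterns: ``RA`` extended acceptor, intron 2 spliced; ``Alt1`` adds
        the exon-3 internal intron; ``RC`` short acceptor; ``RD`` retains
        intron 2; combinations ``RC-Alt1`` and ``RD-Alt1``.
        """
        retained = pattern.startswith("RD")
        short = pattern.startswith("RC")
        internal3 = pattern.endswith("Alt1")
        blocks: list[tuple[int, int]] = []
        if retained:
            blocks.append((_EXON_2A[0], _EXON_2B[1]))
        else:
            blocks.append(_EXON_2A)
            blocks.append(_EXON_2B)
        e3_start = self.short_acceptor if short else _EXT_ACCEPTOR
        if internal3:
            blocks.append((e3_start, _INTRON_3[0]))
            blocks.append((_INTRON_3[1], _EXON_3_END))
        else:
            blocks.append((e3_start, _EXON_3_END))
        blocks.append(_EXON_4)
        blocks.append(_EXON_5)
        exons = tuple(self._iv(b) for b in blocks)
        return tuple(sorted(exons, key=lambda iv: iv.start))

    def chain(self, name: str, promoter: str, pattern: str) -> TranscriptAlignment:
        first = self.exon_a1 if promoter == "A" else self.exon_b1
        exons = tuple(sorted((first, *self.body_exons(pattern)), key=lambda iv: iv.start))
        return TranscriptAlignment(name, CONTIG, self.strand, exons)


BODY_PATTERNS = ("RA", "Alt1", "RC", "RD", "RC-Alt1", "RD-Alt1")

DEFAULT_ISOFORM_MIXTURE = {
    "RA": 0.41,
    "Alt1": 0.13,
    "RC": 0.10,
    "RD": 0.05,
    "RC-Alt1": 0.155,
    "RD-Alt1": 0.155,
}
DEFAULT_PROMOTER_MIXTURE = {"A": 0.01, "B": 0.99}


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def _assert_in_frame(genome: GenomeSeq, locus: LocusAnnotation, chain: TranscriptAlignment,
                     start_label: str) -> None:
    """Build-time self check: start..shared-stop is a clean open reading frame."""
    seq = spliced_sequence(genome, chain)
    from .locus_model import genomic_to_spliced

    s = genomic_to_spliced(chain, locus.start_codons[start_label])
    stop_last = locus.stop_last_base()
    t = genomic_to_spliced(chain, stop_last)
    assert seq[s:s + 3] == "ATG", f"{chain.read_id}: start codon is {seq[s:s+3]}"
    cds = seq[s:t + 1]
    assert len(cds) % 3 == 0, f"{chain.read_id}: CDS length {len(cds)} not 3n"
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    assert codons[-1] in STOP_CODONS, f"{chain.read_id}: no stop at shared stop"
    assert all(c not in STOP_CODONS for c in codons[:-1]), \
        f"{chain.read_id}: internal in-frame stop"


def build_toy_locus(
    seed: int,
    strand: str = "+",
    frame_incompatible_extension: bool = False,
) -> tuple[GenomeSeq, LocusAnnotation]:
    """Construct the toy genome and its locus annotation.

    Deterministic in ``seed``; the minus-strand build is the exact mirror of
    the plus-strand build (reverse-complemented contig, reflected
    coordinates), so spliced sequences are identical between the two.

    With ``frame_incompatible_extension`` the exon-3 extension length stops
    being a multiple of three, so short-acceptor isoforms go out of frame —
    used only for negative tests, and the short reference's build-time frame
    assertion is waived in that mode.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome_arr = rng.choice(bases, size=CONTIG_LEN)

    # A-frame CDS positions (forward template) along the A-promoter extended
    # chain; codon slots are filled with non-stop codons.
    cds_regions = [
        (_A_START, _EXON_A1[1]),
        _EXON_2A,
        (_EXON_2B[0], _EXON_2B[1]),
        (_EXT_ACCEPTOR, _EXON_3_END),
        _EXON_4,
        (_EXON_5[0], _STOP[1]),
    ]
    positions = [p for s, e in cds_regions for p in range(s, e)]
    assert len(positions) % 3 == 0
    n_codons = len(positions) // 3
    b_offset = positions.index(_B_START)
    assert b_offset % 3 == 0

    sense = [c for c in ("".join(p) for p in product("ACGT", repeat=3))
             if c not in STOP_CODONS]
    codon_choices = rng.choice(np.array(sense), size=n_codons)
    codon_choices[0] = "ATG"                 # A start
    codon_choices[b_offset // 3] = "ATG"     # B start (in-frame Met for A)
    codon_choices[-1] = "TAA"                # shared stop
    for ci, codon in enumerate(codon_choices):
        for k in range(3):
            genome_arr[positions[3 * ci + k]] = codon[k]

    forward = "".join(genome_arr)
    if strand == "-":
        forward = reverse_complement(forward)
    genome = GenomeSeq({CONTIG: forward})

    layout = ToyLayout(strand=strand, frame_incompatible_extension=frame_incompatible_extension)
    reference = {
        "RA": layout.chain("RA", "B", "RA"),
        "RC": layout.chain("RC", "B", "RC"),
        "A-ext": layout.chain("A-ext", "A", "RA"),
    }
    locus = LocusAnnotation(
        contig=CONTIG,
        strand=strand,
        promoters={"A": layout.exon_a1, "B": layout.exon_b1},
        start_codons={"A": layout._pos(_A_START), "B": layout._pos(_B_START)},
        exon2_acceptor=layout._pos(_EXON_2A[0]),
        shared_stop=layout._iv(_STOP),
        znf_exons=[layout._iv(_EXON_4), layout._iv(_EXON_5)],
        reference_isoforms=reference,
    )
    _assert_in_frame(genome, locus, reference["RA"], "B")
    _assert_in_frame(genome, locus, reference["A-ext"], "A")
    if not frame_incompatible_extension:
        _assert_in_frame(genome, locus, reference["RC"], "B")
    return genome, locus


def toy_isoform_catalog(locus: LocusAnnotation,
                        frame_incompatible_extension: bool = False) -> dict[str, tuple]:
    """Body splice patterns available to the simulators, keyed by name."""
    layout = ToyLayout(strand=locus.strand,
                       frame_incompatible_extension=frame_incompatible_extension)
    return {name: layout.body_exons(name) for name in BODY_PATTERNS}


# ---------------------------------------------------------------------------
# Simulation config and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the read simulators.

    Defaults are the pipeline's reference conditions: the body-pattern mixture
    mirrors the locus's observed class spectrum, promoter use is 1% A / 99% B,
    one read in five is a PCR duplicate, one in twenty carries a frame-breaking
    single-base deletion, and one in ten is 5'-truncated.
    """

    isoform_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOFORM_MIXTURE))
    promoter_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_MIXTURE))
    n_long_reads: int = 5_000
    n_short_reads: int = 20_000
    dup_rate: float = 0.2
    truncation_rate: float = 0.1
    artifact_rate: float = 0.05
    short_read_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (("isoform_mixture", self.isoform_mixture),
                          ("promoter_mixture", self.promoter_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(mix.values())})")
            if any(not 0.0 <= p <= 1.0 for p in mix.values()):
                raise ConfigError(f"{name} has probabilities outside [0, 1]")
        for name in ("dup_rate", "truncation_rate", "artifact_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]")
        if min(self.n_long_reads, self.n_short_reads, self.short_read_len) < 0:
            raise ConfigError("counts must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    isoform: str
    promoter: str
    is_duplicate: bool
    is_truncated: bool
    is_artifact: bool


@dataclass
class SimTruth:
    """One record per emitted read: the simulator's ground truth."""

    records: list[TruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def by_read(self) -> dict[str, TruthRecord]:
        return {r.read_id: r for r in self.records}

    def to_tsv(self, handle) -> None:
        self.to_frame().to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Long-read simulation
# ---------------------------------------------------------------------------

def _clip_five_prime(chain: TranscriptAlignment, n: int) -> TranscriptAlignment:
    """Drop the first ``n`` transcribed bases (5'-truncation)."""
    exons = list(chain.exons) if chain.strand == "+" else list(reversed(chain.exons))
    out = []
    for ex in exons:
        if n >= len(ex):
            n -= len(ex)
            continue
        if chain.strand == "+":
            out.append(GenomicInterval(ex.contig, ex.start + n, ex.end, ex.strand))
        else:
            out.append(GenomicInterval(ex.contig, ex.start, ex.end - n, ex.strand))
        n = 0
    if chain.strand == "-":
        out.reverse()
    return replace(chain, exons=tuple(out))


def _apply_deletion(chain: TranscriptAlignment, pos: int) -> TranscriptAlignment:
    """Split the exon containing genomic ``pos`` into a 1-nt-gap pair."""
    out = []
    for ex in chain.exons:
        if ex.contains(pos) and ex.start < pos < ex.end - 1:
            out.append(GenomicInterval(ex.contig, ex.start, pos, ex.strand))
            out.append(GenomicInterval(ex.contig, pos + 1, ex.end, ex.strand))
        else:
            out.append(ex)
    return replace(chain, exons=tuple(out))


def _jittered(chain: TranscriptAlignment, d5: int, d3: int) -> TranscriptAlignment:
    c = _clip_five_prime(chain, d5)
    # trim d3 from the transcription 3' side
    exons = list(c.exons)
    if chain.strand == "+":
        last = exons[-1]
        exons[-1] = GenomicInterval(last.contig, last.start, last.end - d3, last.strand)
    else:
        first = exons[0]
        exons[0] = GenomicInterval(first.contig, first.start + d3, first.end, first.strand)
    return replace(c, exons=tuple(exons))


def simulate_long_reads(
    locus: LocusAnnotation,
    genome: GenomeSeq,
    cfg: SimConfig,
) -> tuple[list[TranscriptAlignment], dict[str, str], SimTruth]:
    """Simulate full-length spliced long-read alignments with noise.

    Returns the alignments, a read-id -> spliced-sequence map, and the
    complete per-read ground truth.  Per-read draws follow a fixed order
    (promoter, isoform, end jitter, truncation, artifact, duplication) from a
    single RNG seeded by ``cfg.seed``, so output is reproducible and
    independent of any container iteration order.
    """
    catalog = toy_isoform_catalog(locus)
    for name in cfg.isoform_mixture:
        if name not in catalog:
            raise ConfigError(f"unknown isoform {name!r} in mixture")
    for label in cfg.promoter_mixture:
        if label not in locus.promoters:
            raise ConfigError(f"unknown promoter {label!r} in mixture")

    rng = np.random.default_rng(cfg.seed)
    iso_names = sorted(cfg.isoform_mixture)
    iso_p = np.array([cfg.isoform_mixture[n] for n in iso_names])
    prom_names = sorted(cfg.promoter_mixture)
    prom_p = np.array([cfg.promoter_mixture[n] for n in prom_names])

    layout = ToyLayout(strand=locus.strand)
    # artifact deletion sites live in the exon-3 core shared by every pattern
    art_lo = layout._pos(_SHORT_ACCEPTOR + 10)
    art_hi = layout._pos(_INTRON_3[0] - 10)
    art_lo, art_hi = min(art_lo, art_hi), max(art_lo, art_hi)

    seen: set[tuple] = set()
    reads: list[TranscriptAlignment] = []
    seqs: dict[str, str] = {}
    truth: list[TruthRecord] = []

    for i in range(cfg.n_long_reads):
        rid = f"lr{i:05d}"
        promoter = prom_names[rng.choice(len(prom_names), p=prom_p)]
        iso = iso_names[rng.choice(len(iso_names), p=iso_p)]
        template = layout.chain(rid, promoter, iso)
        truncated = bool(rng.random() < cfg.truncation_rate)
        is_artifact = bool(rng.random() < cfg.artifact_rate)
        duplicated = bool(rng.random() < cfg.dup_rate)

        for attempt in range(1000):
            d5 = int(rng.integers(0, FIVE_PRIME_JITTER))
            d3 = int(rng.integers(0, THREE_PRIME_JITTER))
            chain = _jittered(template, d5, d3)
            if truncated:
                lo, hi = 1, chain.spliced_length() - 50
                chain = _clip_five_prime(chain, int(rng.integers(lo, hi)))
            key = tuple((ex.start, ex.end) for ex in chain.exons)
            if key not in seen:
                break
        else:  # pragma: no cover - jitter space far exceeds read counts
            raise RuntimeError("could not draw a unique read coordinate")

        applied_artifact = False
        if is_artifact:
            # only applicable while the exon-3 core is still part of the read
            if any(ex.start <= art_lo and ex.end >= art_hi for ex in chain.exons):
                pos = int(rng.integers(art_lo, art_hi))
                chain = _apply_deletion(chain, pos)
                applied_artifact = True

        seen.add(tuple((ex.start, ex.end) for ex in chain.exons))
        reads.append(chain)
        seqs[rid] = spliced_sequence(genome, chain)
        truth.append(TruthRecord(rid, iso, promoter, False, truncated, applied_artifact))
        if duplicated:
            dup_id = rid + "d"
            dup = replace(chain, read_id=dup_id)
            reads.append(dup)
            seqs[dup_id] = seqs[rid]
            truth.append(TruthRecord(dup_id, iso, promoter, True, truncated, applied_artifact))

    return reads, seqs, SimTruth(truth)


# ---------------------------------------------------------------------------
# Short-read simulation
# ---------------------------------------------------------------------------

def _window_chain(chain: TranscriptAlignment, rid: str, offset: int, length: int) -> TranscriptAlignment:
    """Lift a spliced-coordinate window back to genomic exon blocks."""
    clipped = _clip_five_prime(chain, offset)
    exons = list(clipped.exons) if chain.strand == "+" else list(reversed(clipped.exons))
    out, remaining = [], length
    for ex in exons:
        take = min(len(ex), remaining)
        if chain.strand == "+":
            out.append(GenomicInterval(ex.contig, ex.start, ex.start + take, ex.strand))
        else:
            out.append(GenomicInterval(ex.contig, ex.end - take, ex.end, ex.strand))
        remaining -= take
        if remaining == 0:
            break
    if chain.strand == "-":
        out.reverse()
    return TranscriptAlignment(rid, chain.contig, chain.strand, tuple(out))


def simulate_short_reads(
    locus: LocusAnnotation,
    genome: GenomeSeq,
    cfg: SimConfig,
) -> list[TranscriptAlignment]:
    """Simulate single-end spliced short reads as exon-block alignments.

    Each read is a uniform window over one isoform's spliced coordinates;
    windows that straddle an exon-exon boundary become multi-block
    junction-spanning alignments.
    """
    catalog = toy_isoform_catalog(locus)
    for name in cfg.isoform_mixture:
        if name not in catalog:
            raise ConfigError(f"unknown isoform {name!r} in mixture")
    layout = ToyLayout(strand=locus.strand)
    rng = np.random.default_rng(cfg.seed + 1)
    iso_names = sorted(cfg.isoform_mixture)
    iso_p = np.array([cfg.isoform_mixture[n] for n in iso_names])
    prom_names = sorted(cfg.promoter_mixture)
    prom_p = np.array([cfg.promoter_mixture[n] for n in prom_names])

    chains = {(prom, iso): layout.chain(f"{prom}:{iso}", prom, iso)
              for prom in prom_names for iso in iso_names}
    min_len = min(c.spliced_length() for c in chains.values())
    if cfg.short_read_len >= min_len:
        raise ConfigError(
            f"short_read_len {cfg.short_read_len} >= shortest isoform ({min_len} nt)")

    reads = []
    for i in range(cfg.n_short_reads):
        promoter = prom_names[rng.choice(len(prom_names), p=prom_p)]
        iso = iso_names[rng.choice(len(iso_names), p=iso_p)]
        chain = chains[(promoter, iso)]
        offset = int(rng.integers(0, chain.spliced_length() - cfg.short_read_len + 1))
        reads.append(_window_chain(chain, f"sr{i:06d}", offset, cfg.short_read_len))
    return reads
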