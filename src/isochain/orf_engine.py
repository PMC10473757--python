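"""Reading-frame prediction, frame filtering, frameshift consequences, masses.

Frame logic is spliced-coordinate arithmetic over the standard nuclear code
(stops TAA/TAG/TGA).  A read is *in frame* when, walking codons from the
promoter-appropriate start codon along its spliced sequence, the first stop
encountered is exactly the locus's shared stop triplet.  Premature stops,
frame misalignment relative to the shared stop, and reads that never reach a
stop are all rejected, each under its own status for auditability.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

from .locus_model import (
    BoundsError,
    ConfigError,
    GenomeSeq,
    LocusAnnotation,
    TranscriptAlignment,
    genomic_to_spliced,
    spliced_sequence,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

FrameStatus = Literal[
    "in_frame", "out_of_frame", "premature_stop", "no_stop_reached", "start_absent"
]


def _is_stop(codon: str) -> bool:
    # codons containing N are conservatively treated as non-stop
    return codon in STOP_CODONS


@dataclass(frozen=True)
class OrfResult:
    """Frame status of one read's predicted CDS."""

    read_id: str
    start_label: str
    frame_status: FrameStatus
    cds_length: int | None = None
    premature_stop_offset: int | None = None  # codons from the start codon
    contains_n: bool = False


@dataclass(frozen=True)
class FrameshiftEdit:
    """A small indel in spliced transcript coordinates.

    ``position`` is 1-based within the transcript.  For a deletion it is the
    first deleted base; for an insertion, the inserted sequence begins at that
    position.
    """

    kind: Literal["deletion", "insertion"]
    position: int
    length: int = 1
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind == "insertion" and not self.sequence:
            raise ConfigError("insertion edit requires a sequence")
        if self.kind == "deletion" and self.length < 1:
            raise ConfigError("deletion length must be >= 1")
        if self.position < 1:
            raise ConfigError("edit position is 1-based")


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def predict_orf(
    read: TranscriptAlignment,
    locus: LocusAnnotation,
    genome: GenomeSeq,
    promoter_label: str,
) -> OrfResult:
    """Predict the reading frame of ``read`` from one promoter's start codon.

    The start codon's genomic position must be exonic in the read
    (``start_absent`` otherwise).  Codons are then walked along the spliced
    sequence; the first stop decides the status: at the shared stop ->
    ``in_frame``; before it -> ``premature_stop`` (with its codon offset);
    past it -> ``out_of_frame``; never -> ``out_of_frame`` when the spliced
    start-to-shared-stop distance is not a multiple of three, else
    ``no_stop_reached``.
    """
    if promoter_label not in locus.start_codons:
        raise ConfigError(f"unknown promoter label {promoter_label!r}")
    start_pos = locus.start_codons[promoter_label]
    try:
        s = genomic_to_spliced(read, start_pos)
    except BoundsError:
        return OrfResult(read.read_id, promoter_label, "start_absent")

    seq = spliced_sequence(genome, read)
    contains_n = "N" in seq
    stop_last = locus.stop_last_base()
    try:
        t = genomic_to_spliced(read, stop_last)  # spliced offset of stop's 3' base
    except BoundsError:
        t = None

    for k in range(s, len(seq) - 2, 3):
        if _is_stop(seq[k:k + 3]):
            if t is not None and k + 2 == t:
                return OrfResult(read.read_id, promoter_label, "in_frame",
                                 cds_length=k + 3 - s, contains_n=contains_n)
            if t is None or k + 2 < t:
                return OrfResult(read.read_id, promoter_label, "premature_stop",
                                 cds_length=k + 3 - s,
                                 premature_stop_offset=(k - s) // 3,
                                 contains_n=contains_n)
            return OrfResult(read.read_id, promoter_label, "out_of_frame",
                             contains_n=contains_n)
    if t is not None and (t + 1 - s) % 3 != 0:
        return OrfResult(read.read_id, promoter_label, "out_of_frame",
                         contains_n=contains_n)
    return OrfResult(read.read_id, promoter_label, "no_stop_reached",
                     contains_n=contains_n)


def frame_filter(
    reads: list[TranscriptAlignment],
    results: Mapping[str, OrfResult],
) -> tuple[list[TranscriptAlignment], list[tuple[TranscriptAlignment, str]]]:
    """Keep only ``in_frame`` reads; rejections are labeled with their status."""
    kept, rejected = [], []
    for r in reads:
        res = results[r.read_id]
        if res.frame_status == "in_frame":
            kept.append(r)
        else:
            rejected.append((r, res.frame_status))
    return kept, rejected


# ---------------------------------------------------------------------------
# Frameshift consequences
# ---------------------------------------------------------------------------

def apply_edit(seq: str, edit: FrameshiftEdit) -> str:
    p = edit.position - 1
    if p >= len(seq):
        raise BoundsError(f"edit position {edit.position} outside transcript "
                          f"of length {len(seq)}")
    if edit.kind == "deletion":
        if p + edit.length > len(seq):
            raise BoundsError("deletion runs past transcript end")
        return seq[:p] + seq[p + edit.length:]
    return seq[:p] + edit.sequence.upper() + seq[p:]


def _first_stop_codon(seq: str, cds_start: int, from_codon: int = 0) -> int | None:
    """Index (codons from cds_start) of the first stop at/after ``from_codon``."""
    for idx in range(from_codon, (len(seq) - cds_start) // 3):
        k = cds_start + 3 * idx
        if _is_stop(seq[k:k + 3]):
            return idx
    return None


def frameshift_consequence(
    transcript_seq: str,
    cds_start: int,
    edit: FrameshiftEdit,
    convention: Literal["exclusive", "inclusive"] = "exclusive",
) -> tuple[bool, int | None]:
    """Re-translate after an indel and locate the resulting stop codon.

    ``cds_start`` is the 0-based spliced offset of the reading frame's first
    base.  Returns ``(new_premature_stop, distance)`` where ``distance``
    counts codons from the codon containing the edit to the first stop at or
    after it in the edited sequence.  Under the default ``"exclusive"``
    convention the distance is the stop codon's index minus the edited
    codon's index (the edited codon itself not counted, the stop counted);
    ``"inclusive"`` adds one.

    ``new_premature_stop`` is False when that first stop is the original
    terminating stop, merely shifted by the edit's net length change (as for
    an in-frame insertion of whole non-stop codons).
    """
    transcript_seq = transcript_seq.upper()
    edited = apply_edit(transcript_seq, edit)
    p = edit.position - 1
    if p < cds_start:
        raise ConfigError("edit upstream of the CDS has no frame consequence")
    edit_codon = (p - cds_start) // 3

    stop_idx = _first_stop_codon(edited, cds_start, from_codon=edit_codon)
    if stop_idx is None:
        return False, None

    delta = len(edited) - len(transcript_seq)
    orig_idx = _first_stop_codon(transcript_seq, cds_start, from_codon=edit_codon)
    same_stop = (
        orig_idx is not None
        and (cds_start + 3 * stop_idx) == (cds_start + 3 * orig_idx) + delta
    )
    distance = stop_idx - edit_codon
    if convention == "inclusive":
        distance += 1
    return (not same_stop), distance


# ---------------------------------------------------------------------------
# Protein mass
# ---------------------------------------------------------------------------

# average (isotope-abundance-weighted) residue masses, Da
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.01524


def predict_protein_mass(aa_sequence: str) -> float:
    """Average molecular mass of a polypeptide in kilodaltons.

    Sum of average residue masses plus one water; report to one decimal when
    quoting sizes (e.g. 104.8 kDa).
    """
    aa_sequence = aa_sequence.strip().upper()
    unknown = set(aa_sequence) - set(_RESIDUE_MASS)
    if unknown:
        raise ValueError(f"unknown residues: {sorted(unknown)}")
    return (sum(_RESIDUE_MASS[a] for a in aa_sequence) + _WATER) / 1000.0
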