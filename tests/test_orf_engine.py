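"""Frame prediction against an independent translate-and-scan oracle."""
import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from isochain import (
    ConfigError,
    FrameshiftEdit,
    GenomicInterval,
    SimConfig,
    TranscriptAlignment,
    frame_filter,
    frameshift_consequence,
    predict_orf,
    predict_protein_mass,
    simulate_long_reads,
    spliced_sequence,
)
from isochain.locus_model import BoundsError, genomic_to_spliced
from isochain.orf_engine import apply_edit


# ---------------------------------------------------------------------------
# independent oracle: translate from the start codon, scan for the first stop
# ---------------------------------------------------------------------------

def oracle_status(read, locus, genome, label):
    try:
        s = genomic_to_spliced(read, locus.start_codons[label])
    except BoundsError:
        return "start_absent"
    seq = spliced_sequence(genome, read)
    try:
        t = genomic_to_spliced(read, locus.stop_last_base())
    except BoundsError:
        t = None
    tail = seq[s:]
    prot = str(Seq(tail[: len(tail) - len(tail) % 3]).translate())
    first = prot.find("*")
    if first == -1:
        if t is not None and (t + 1 - s) % 3 != 0:
            return "out_of_frame"
        return "no_stop_reached"
    stop_end_offset = s + 3 * first + 2
    if t is not None and stop_end_offset == t:
        return "in_frame"
    if t is None or stop_end_offset < t:
        return "premature_stop"
    return "out_of_frame"


def random_toy_reads(genome, locus, n, seed):
    """Noisy simulated reads plus hand-mangled variants for frame diversity."""
    cfg = SimConfig(n_long_reads=n, dup_rate=0.0, truncation_rate=0.3,
                    artifact_rate=0.3, seed=seed)
    reads, _, truth = simulate_long_reads(locus, genome, cfg)
    return reads, truth


def test_reference_isoforms_in_frame(toy):
    genome, locus = toy
    for name, label in (("RA", "B"), ("RC", "B"), ("A-ext", "A")):
        res = predict_orf(locus.reference_isoforms[name], locus, genome, label)
        assert res.frame_status == "in_frame", name
        assert res.cds_length % 3 == 0


def test_predict_orf_matches_oracle_on_random_reads(toy):
    genome, locus = toy
    reads, truth = random_toy_reads(genome, locus, 1000, seed=21)
    by_read = truth.by_read()
    mismatches = []
    for r in reads:
        label = by_read[r.read_id].promoter
        got = predict_orf(r, locus, genome, label).frame_status
        want = oracle_status(r, locus, genome, label)
        if got != want:
            mismatches.append((r.read_id, got, want))
    assert not mismatches, mismatches[:5]


def test_predict_orf_matches_oracle_minus_strand(toy_minus):
    genome, locus = toy_minus
    reads, truth = random_toy_reads(genome, locus, 300, seed=22)
    by_read = truth.by_read()
    for r in reads:
        label = by_read[r.read_id].promoter
        assert predict_orf(r, locus, genome, label).frame_status == \
            oracle_status(r, locus, genome, label)


def test_shortened_exon_breaks_frame(toy):
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    exons = list(ra.exons)
    e3 = exons[3]  # extended exon 3, upstream of the zinc-finger exons
    exons[3] = GenomicInterval(e3.contig, e3.start, e3.end - 1, e3.strand)
    mangled = TranscriptAlignment("mangled", ra.contig, ra.strand, tuple(exons))
    got = predict_orf(mangled, locus, genome, "B").frame_status
    assert got == oracle_status(mangled, locus, genome, "B")
    assert got in ("out_of_frame", "premature_stop")


def test_mono_exon_read_cannot_reach_stop(toy):
    genome, locus = toy
    exon2 = TranscriptAlignment(
        "e2", locus.contig, locus.strand,
        (GenomicInterval(locus.contig, 2860, 3600, locus.strand),))
    res = predict_orf(exon2, locus, genome, "B")
    assert res.frame_status in ("no_stop_reached", "start_absent")
    res_a = predict_orf(exon2, locus, genome, "A")
    assert res_a.frame_status == "start_absent"
    with pytest.raises(ConfigError):
        predict_orf(exon2, locus, genome, "Z")


def test_utr_variation_does_not_change_b_frame(toy):
    """In-frame status under the B start is invariant to 5' UTR changes."""
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    trimmed_first = GenomicInterval(ra.contig, ra.exons[0].start + 120,
                                    ra.exons[0].end, ra.strand)
    shorter = TranscriptAlignment("s", ra.contig, ra.strand,
                                  (trimmed_first,) + ra.exons[1:])
    no_first = TranscriptAlignment("n", ra.contig, ra.strand, ra.exons[1:])
    for read in (ra, shorter, no_first):
        assert predict_orf(read, locus, genome, "B").frame_status == "in_frame"


def test_frame_filter_partitions_by_status(toy):
    genome, locus = toy
    reads, truth = random_toy_reads(genome, locus, 200, seed=23)
    by_read = truth.by_read()
    results = {r.read_id: predict_orf(r, locus, genome, by_read[r.read_id].promoter)
               for r in reads}
    kept, rejected = frame_filter(reads, results)
    assert len(kept) + len(rejected) == len(reads)
    assert all(results[r.read_id].frame_status == "in_frame" for r in kept)
    assert all(reason != "in_frame" for _, reason in rejected)
    # every artifact read that reaches the frame filter is rejected
    kept_ids = {r.read_id for r in kept}
    assert not any(by_read[rid].is_artifact for rid in kept_ids)


# ---------------------------------------------------------------------------
# frameshift consequences
# ---------------------------------------------------------------------------

def oracle_frameshift(seq, cds_start, edit):
    edited = apply_edit(seq, edit)
    prot = str(Seq(edited[cds_start:len(edited) - (len(edited) - cds_start) % 3]
                   ).translate())
    edit_codon = (edit.position - 1 - cds_start) // 3
    idx = prot.find("*", edit_codon)
    return None if idx == -1 else idx - edit_codon


def test_inframe_insertion_adds_no_premature_stop(toy):
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    seq = spliced_sequence(genome, ra)
    s = genomic_to_spliced(ra, locus.start_codons["B"])
    edit = FrameshiftEdit("insertion", position=s + 1 + 30, sequence="GCTGCAGCG")
    new_stop, dist = frameshift_consequence(seq, s, edit)
    assert new_stop is False


def test_single_base_deletions_match_retranslation_oracle(toy):
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    seq = spliced_sequence(genome, ra)
    s = genomic_to_spliced(ra, locus.start_codons["B"])
    cds_len = 1800
    rng = np.random.default_rng(31)
    for pos in rng.integers(s + 4, s + cds_len - 3, size=100):
        edit = FrameshiftEdit("deletion", position=int(pos) + 1)
        got_new, got_dist = frameshift_consequence(seq, s, edit)
        assert got_dist == oracle_frameshift(seq, s, edit)
        if got_new:
            assert got_dist is not None


def test_codon_aligned_3nt_deletion_preserves_frame(toy):
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    seq = spliced_sequence(genome, ra)
    s = genomic_to_spliced(ra, locus.start_codons["B"])
    for codon_idx in (5, 50, 200):
        edit = FrameshiftEdit("deletion", position=s + 3 * codon_idx + 1, length=3)
        new_stop, _ = frameshift_consequence(seq, s, edit)
        assert new_stop is False  # frame unchanged downstream


def test_frameshift_edit_validation(toy):
    genome, locus = toy
    seq = spliced_sequence(genome, locus.reference_isoforms["RA"])
    with pytest.raises(BoundsError):
        frameshift_consequence(seq, 0, FrameshiftEdit("deletion",
                                                      position=len(seq) + 5))
    with pytest.raises(ConfigError):
        FrameshiftEdit("insertion", position=3)
    with pytest.raises(ConfigError):
        FrameshiftEdit("deletion", position=0)


def test_convention_difference_is_one_codon(toy):
    genome, locus = toy
    ra = locus.reference_isoforms["RA"]
    seq = spliced_sequence(genome, ra)
    s = genomic_to_spliced(ra, locus.start_codons["B"])
    edit = FrameshiftEdit("deletion", position=s + 100)
    _, excl = frameshift_consequence(seq, s, edit, convention="exclusive")
    _, incl = frameshift_consequence(seq, s, edit, convention="inclusive")
    if excl is not None:
        assert incl == excl + 1


# ---------------------------------------------------------------------------
# protein mass
# ---------------------------------------------------------------------------

def test_protein_mass_against_residue_table_oracle():
    assert predict_protein_mass("") == pytest.approx(0.018, abs=5e-4)
    # glycine free amino acid: residue + water
    assert predict_protein_mass("G") * 1000 == pytest.approx(75.07, abs=0.01)
    for seq in ("MKTAYIAKQR", "ACDEFGHIKLMNPQRSTVWY"):
        expected = ProteinAnalysis(seq).molecular_weight() / 1000
        assert predict_protein_mass(seq) == pytest.approx(expected, rel=1e-4)
    with pytest.raises(ValueError):
        predict_protein_mass("MKX")
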