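"""The toy locus generator and the long/short read simulators."""
import io

import pytest
from Bio.Seq import Seq
from scipy.stats import binomtest

from isochain import (
    ConfigError,
    SimConfig,
    build_toy_locus,
    collapse_duplicates,
    junction_chain,
    simulate_long_reads,
    simulate_short_reads,
    spliced_sequence,
    toy_isoform_catalog,
    write_gtf,
)
from isochain.locus_model import genomic_to_spliced
from isochain.longread_filter import span_filter
from isochain.synthetic_locus import ToyLayout


def brute_force_orf_ok(genome, locus, chain, label):
    """Independent translate-and-scan: clean ORF from start to shared stop."""
    seq = spliced_sequence(genome, chain)
    s = genomic_to_spliced(chain, locus.start_codons[label])
    t = genomic_to_spliced(chain, locus.stop_last_base())
    cds = seq[s:t + 1]
    if len(cds) % 3:
        return False
    prot = str(Seq(cds).translate())
    return prot.endswith("*") and "*" not in prot[:-1] and prot.startswith("M")


def test_reference_isoforms_have_clean_orfs(toy):
    genome, locus = toy
    assert brute_force_orf_ok(genome, locus, locus.reference_isoforms["RA"], "B")
    assert brute_force_orf_ok(genome, locus, locus.reference_isoforms["RC"], "B")
    assert brute_force_orf_ok(genome, locus, locus.reference_isoforms["A-ext"], "A")


def test_frame_incompatible_extension_breaks_short_acceptor_frame():
    genome, locus = build_toy_locus(1, frame_incompatible_extension=True)
    assert brute_force_orf_ok(genome, locus, locus.reference_isoforms["RA"], "B")
    assert not brute_force_orf_ok(genome, locus, locus.reference_isoforms["RC"], "B")


def test_build_is_deterministic():
    g1, l1 = build_toy_locus(1)
    g2, l2 = build_toy_locus(1)
    assert g1.contigs == g2.contigs
    b1, b2 = io.StringIO(), io.StringIO()
    write_gtf(l1.reference_isoforms, b1)
    write_gtf(l2.reference_isoforms, b2)
    assert b1.getvalue() == b2.getvalue()
    g3, _ = build_toy_locus(2)
    assert g3.contigs != g1.contigs


def test_minus_strand_build_mirrors_plus(toy, toy_minus):
    gp, lp = toy
    gm, lm = toy_minus
    for name in lp.reference_isoforms:
        assert spliced_sequence(gp, lp.reference_isoforms[name]) == \
            spliced_sequence(gm, lm.reference_isoforms[name])
    assert brute_force_orf_ok(gm, lm, lm.reference_isoforms["RA"], "B")


def test_simconfig_validation():
    with pytest.raises(ConfigError):
        SimConfig(isoform_mixture={"RA": 0.5})
    with pytest.raises(ConfigError):
        SimConfig(dup_rate=1.5)
    with pytest.raises(ConfigError):
        SimConfig(n_long_reads=-1)


def test_unknown_mixture_isoform_rejected(toy):
    genome, locus = toy
    cfg = SimConfig(isoform_mixture={"nope": 1.0}, n_long_reads=5, seed=0)
    with pytest.raises(ConfigError):
        simulate_long_reads(locus, genome, cfg)


def test_no_noise_simulation_all_full_length(toy):
    genome, locus = toy
    cfg = SimConfig(n_long_reads=100, dup_rate=0.0, truncation_rate=0.0,
                    artifact_rate=0.0, seed=3)
    reads, seqs, truth = simulate_long_reads(locus, genome, cfg)
    assert len(reads) == 100 and len(truth.records) == 100
    kept, removed, skipped = span_filter(reads, locus)
    assert (len(kept), len(removed), len(skipped)) == (100, 0, 0)
    assert all(seqs[r.read_id] == spliced_sequence(genome, r) for r in reads)


def test_duplicate_counts_match_truth(toy):
    genome, locus = toy
    cfg = SimConfig(n_long_reads=1000, dup_rate=0.5, truncation_rate=0.0,
                    artifact_rate=0.0, seed=9)
    reads, _, truth = simulate_long_reads(locus, genome, cfg)
    n_dups = sum(r.is_duplicate for r in truth.records)
    assert len(reads) == 1000 + n_dups
    deduped, removed = collapse_duplicates(reads)
    assert len(deduped) == 1000 and removed == n_dups


def test_degenerate_mixture_single_isoform(toy):
    genome, locus = toy
    cfg = SimConfig(isoform_mixture={"RA": 1.0}, n_long_reads=50, dup_rate=0.0,
                    truncation_rate=0.0, artifact_rate=0.0, seed=4)
    reads, _, truth = simulate_long_reads(locus, genome, cfg)
    ref_sig = junction_chain(locus.reference_isoforms["RA"])
    b_reads = [r for r in reads
               if truth.by_read()[r.read_id].promoter == "B"]
    assert b_reads
    for r in b_reads:
        assert junction_chain(r) == ref_sig


def test_simulation_is_deterministic(toy):
    genome, locus = toy
    cfg = SimConfig(n_long_reads=200, seed=11)
    r1, s1, t1 = simulate_long_reads(locus, genome, cfg)
    r2, s2, t2 = simulate_long_reads(locus, genome, cfg)
    assert r1 == r2 and s1 == s2 and t1.records == t2.records
    assert simulate_short_reads(locus, genome, cfg) == \
        simulate_short_reads(locus, genome, cfg)


def test_mixture_recovery_among_clean_reads(toy):
    """Clean-read class frequencies sit inside exact binomial 95% CIs."""
    genome, locus = toy
    cfg = SimConfig(n_long_reads=5000, seed=1)
    reads, _, truth = simulate_long_reads(locus, genome, cfg)
    by_read = truth.by_read()
    clean = [r for r in truth.records
             if not (r.is_duplicate or r.is_truncated or r.is_artifact)]
    n = len(clean)
    for body, p in cfg.isoform_mixture.items():
        k = sum(r.isoform == body for r in clean)
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        assert ci.low <= p <= ci.high, (body, k / n, p)


def test_artifact_and_truncation_structure(toy):
    genome, locus = toy
    cfg = SimConfig(n_long_reads=400, dup_rate=0.0, truncation_rate=0.3,
                    artifact_rate=0.3, seed=13)
    reads, _, truth = simulate_long_reads(locus, genome, cfg)
    by_read = truth.by_read()
    for r in reads:
        if by_read[r.read_id].is_artifact:
            # the single-base deletion appears as a 1-nt gap in the chain
            assert any(j.end - j.start == 1 for j in junction_chain(r))
    # truncated reads starting at/past the exon-2 acceptor never pass the span filter
    kept, removed, _ = span_filter(reads, locus)
    for r in kept:
        assert locus.is_upstream(r.five_prime, locus.exon2_acceptor)


def test_short_reads_window_structure(toy):
    genome, locus = toy
    cfg = SimConfig(n_short_reads=500, seed=2)
    reads = simulate_short_reads(locus, genome, cfg)
    assert len(reads) == 500
    for r in reads:
        assert r.spliced_length() == cfg.short_read_len

    assert simulate_short_reads(
        locus, genome, SimConfig(n_short_reads=0, seed=2)) == []
    with pytest.raises(ConfigError):
        simulate_short_reads(locus, genome,
                             SimConfig(n_short_reads=1, short_read_len=5000, seed=2))


def test_short_read_junction_gap_matches_intron(toy):
    genome, locus = toy
    cfg = SimConfig(n_short_reads=2000, seed=6)
    reads = simulate_short_reads(locus, genome, cfg)
    multi = [r for r in reads if len(r.exons) > 1]
    assert multi, "expected junction-spanning short reads"
    valid_introns = set()
    layout = ToyLayout(strand=locus.strand)
    for prom in "AB":
        for body in toy_isoform_catalog(locus):
            for j in junction_chain(layout.chain("x", prom, body)):
                valid_introns.add((j.start, j.end))
    for r in multi:
        for j in junction_chain(r):
            assert (j.start, j.end) in valid_introns
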