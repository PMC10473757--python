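# Methods

## The analysis model

The pipeline treats a multi-promoter locus as: an ordered set of promoter
first exons, a shared exon scaffold beginning at the exon-2 splice acceptor,
one start codon per promoter, and a single shared stop codon used by every
productive isoform. A full-length cDNA read is interpretable when it carries
promoter evidence (5′ terminus strictly upstream of the exon-2 acceptor — a
read starting *at* the acceptor cannot contain promoter evidence, so boundary
equality is excluded) and covers the complete reading frame (3′ terminus at
or beyond the last stop base). All coordinates are internally 0-based
half-open; GTF I/O converts to 1-based inclusive; BED12 is native. Strand is
carried everywhere: 5′/3′ termini, upstream/downstream tests, and codon walks
are all transcription-direction aware, and nothing assumes a plus-strand
locus.

**Duplicate model.** "PCR duplicate" is operationalized as coordinate
identity: same strand, identical junction chain, and both read ends within
`end_tolerance` nt (default 0). Published pipelines rarely state their slop,
so the tolerance is a parameter rather than a guess; exact collapse is the
most conservative reproducible rule. Collapse keeps the first-seen
representative and is idempotent.

**Frame prediction.** For a read assigned promoter *P*, the engine locates
*P*'s start codon inside the read's exon chain (`start_absent` if the read
does not cover it), then walks codons along the spliced sequence. The first
stop decides the call: exactly at the shared stop → `in_frame`; earlier →
`premature_stop` (with its codon offset); past the shared stop →
`out_of_frame`; no stop, with a start-to-stop spliced distance not divisible
by three → `out_of_frame`; otherwise `no_stop_reached`. Only `in_frame` reads
survive, so premature-stop reads are rejected along with frame-shifted ones —
they do not use the annotated shared stop — but are reported under their own
reason for auditability. Codons containing N are conservatively treated as
non-stop and the result flagged. Reads whose 5′ terminus sits in no promoter
exon are tried under every start codon and kept if any yields `in_frame`
(the downstream start preferred when several do); they are excluded from
promoter-scoped denominators.

**Classification window.** Isoform classes are equivalence classes of the
*windowed junction signature*: the ordered introns lying between the exon-2
acceptor and the last stop base. This window deliberately ignores 5′
(promoter/UTR) and 3′ end variability, so a promoter-A read with the same
ORF-region splicing as a B reference falls in the same class and is counted
in its own promoter scope. Signatures use exact junction coordinates —
integer-identical introns — because counting splice usage presumes exact
junction identity; fuzzy matching for noisy real alignments is deliberately
not a default. Novel classes are named `<scope>-Alt-k` by descending count;
exact count ties go to the class whose earliest distinguishing junction is
more upstream in transcription direction (lexicographic comparison of
signatures in transcription order).

**Percent convention.** All printed percentages are integer round-half-up
(`floor(100·k/n + 0.5)`). This convention reproduces every count-consistent
published fraction in the locus survey this pipeline mirrors (41, 13, 10, 5,
86, 1, 86, 47); the two published values that contradict their own counts
(printed 94% for 4,913/5,079 = 96.7% and 99% for 5,070/5,079 = 99.8%) are
recomputed and flagged as inconsistent rather than reconciled.

**Frameshift consequences.** `frameshift_consequence` applies an indel in
spliced transcript coordinates (1-based positions, matching how such lesions
are quoted) and re-walks codons. The reported distance counts codons from the
codon containing the edit to the first stop at or after it — exclusive of the
edit codon, inclusive of the stop — which is the convention under which a
known 1-nt deletion lesion in this locus family yields its quoted "15 codons"
distance; an inclusive variant is available via a flag. A stop is "new" when
it is not the original terminator merely shifted by the edit's net length.

**Protein mass** is the sum of average (isotope-weighted) residue masses plus
one water, reported in kDa; it is cross-checked against Biopython's
ProtParam table in the tests.

**BPM coverage.** Bins-per-million divides per-bin read counts by
(total mapped reads / 10⁶). A read overlaps a bin when any exon block
intersects it and counts once per bin. Genome-size flags seen in coverage
tools are inert for BPM and intentionally not parameters here. Default bin
size 5 nt; output is sparse bedGraph. Coverage is unstranded by default.
"Short-read support" for a class means every junction in its signature is
spanned by at least `min_reads` short reads; published usage of the concept
sets no threshold, so the default is 1 and the parameter is explicit.

## The synthetic locus

`build_toy_locus(seed)` writes a 10 kb contig: promoter-A first exon
(500–800, start codon at 699), promoter-B first exon (1500–1800), shared
exon 2 (2500–3600) with an optional 160-nt internal intron (2700–2860) lying
in the B 5′ UTR, the B start codon at 3000, exon 3 with an extended acceptor
at 4300 and a short acceptor at 4450 plus an optional 60-nt internal intron
(4600–4660), two zinc-finger exons (5600–5900, 6600–7200), and the shared
stop at 6897–6900. Frame safety is by construction rather than by luck:
every optional splice difference is a multiple of three and codon-aligned in
the shared frame, all CDS codon slots are drawn from non-stop codons, and
build-time assertions re-translate each reference isoform. A
`frame_incompatible_extension` flag shifts the short acceptor by 1 nt for
negative tests. The minus-strand build is the exact mirror (reflected
coordinates over the reverse-complemented contig), yielding identical spliced
sequences.

Six body splice patterns are simulated: `RA` (extended acceptor, exon-2
intron spliced), `Alt1` (adds the exon-3 internal intron), `RC` (short
acceptor), `RD` (retains the exon-2 intron), and the combinations `RC-Alt1`
and `RD-Alt1`. The default mixture {0.41, 0.13, 0.10, 0.05, 0.155, 0.155}
mirrors the class spectrum reported for this kind of locus, promoter use
defaults to 1% A / 99% B, and the default noise rates are 20% PCR
duplication, 10% 5′ truncation, and 5% artifact — these defaults are the
reference study conditions used by the acceptance checks.

Simulator details that matter for interpretation:

- Distinct original molecules always receive distinct (5′, 3′) end-jitter
  pairs (5′ drawn on a 30-nt grid inside the first exon, 3′ on a 300-nt grid
  in the terminal UTR; collisions redrawn). PCR duplicates are exact copies.
  Coordinate identity is therefore *equivalent* to duplication, which makes
  duplicate-collapse counts exactly checkable against truth.
- Truncations remove a uniform 5′ prefix of the spliced sequence (leaving at
  least 50 nt); a truncated read surviving the span filter is genuinely
  promoter-assignable from its remaining 5′ terminus.
- Artifacts are 1-nt deletions at a uniform position in the exon-3 core
  shared by all patterns, realized as a 1-nt gap in the chain; they shift the
  downstream frame and are guaranteed frame-filter rejections. When a read's
  truncation has already removed the exon-3 core the artifact cannot be
  placed and the truth record says so.
- One RNG per simulate call, draws in fixed per-read order (promoter,
  isoform, jitter, truncation, artifact, duplication), so output is
  byte-reproducible for a given seed.

What the generator does **not** model: sequencing errors within exons,
quality scores, soft-clips or alignment ambiguity, fuzzy splice boundaries,
polyA artifacts, expression-dependent length biases, or strand-mixed
libraries. Passing tests therefore demonstrate the correctness of the
filtering/classification logic under clean alignment structure, not
robustness to aligner noise on real data — for real alignments the
`end_tolerance` and (off-by-default) fuzzy-junction options exist precisely
because those effects appear there.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at 5,000 long
reads and 20,000 short reads — the scale at which exact binomial 95%
confidence intervals (Clopper–Pearson, via `scipy.stats.binomtest`) are tight
enough (~±1.5% absolute) to be a meaningful mixture-recovery check while the
whole run stays in seconds. Mixture-recovery checks test that each recovered
class frequency's exact CI covers its generating probability. Stochastic
tests fix their seeds; hypothesis property tests run derandomized.

Degenerate inputs: an empty read set produces a zero-count report (not an
error); an empty scope raises on frequency-table construction; a zero-read
coverage request returns an all-zero track; mono-exon chains have empty
junction signatures and are trivially short-read "supported".

## Known limitations

- Real headline counts from the archived fly-ovary libraries (thousands of
  in-frame full-length reads) require SRA downloads and upstream mapping and
  are outside the desk scale of this package; the synthetic conditions stand
  in for them.
- SAM/BAM ingestion is not implemented; alignments enter as BED12 exon
  chains (the upstream aligner's export format).
- Classification is promoter-scoped but not expression-quantifying: no
  TPM/EM, no length or positional bias correction.
- The duplicate key cannot distinguish a true PCR duplicate from two
  independent molecules with identical ends; on real data a nonzero
  `end_tolerance` makes the collapse strictly more aggressive, never less.
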