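# Methods

This note documents the models, algorithms and numerical choices behind
`eccpipe`, and what the synthetic data generator does and does not
emulate.

## Synthetic study design (`simdata`)

The generator builds the study conditions the pipeline targets rather
than arbitrary toy data.

**Genome.** Chromosomes are uniform-random nucleotide sequences with a
single centromere interval (default 10% of the chromosome, centered).
TE copies are mutated descendants of per-family consensus sequences
(default two families per superfamily across RC/Helitron, LTR/Copia,
LTR/Gypsy, DNA/MuDR, DNA/En-Spm and LINE/L1, with helitron-heavy default
weights mirroring a small crucifer genome). Per-bp placement probability
inside the centromere is a configurable multiple (default 5×) of the
outside probability, emulating the centromeric/pericentromeric TE and
eccDNA enrichment of repeat-rich plant genomes. Consensus divergence is
3% substitutions plus rare indels; copies never overlap other features,
and genes (CDS intervals, 0.3–3 kb) are placed on the arms only.

**Circles.** The default circle population mixes full-TE (30%),
partial-TE (25%), genic (20%) and intergenic (25%) origins, with 5%
chimeric circles joining two loci at least 10 kb apart. Full-TE circles
carry up to 500 bp of flanking sequence; partial-TE circles truncate
their source element (30–90% of its length, strictly shorter). Genic and
intergenic circle lengths are drawn from a lognormal model
parameterized by its arithmetic mean (3,681 nt) and median (3,347 nt) and
clipped to 0.5–22.4 kb — the molecule-size scale the pipeline is meant
for. Sampling is rejection-based so that truth labels are unambiguous
under the annotation module's TE > CDS > intergenic priority: genic and
intergenic circles avoid TEs, and TE flanks avoid other features.

**Reads.** A read is the circle rotated by a uniform random phase,
repeated `rounds` times (real-valued; the trailing repeat is fractional,
because RCA does not stop at integer multiples), then corrupted by
i.i.d. errors with a substitution:insertion:deletion mix of 8:1:1 —
high-accuracy consensus long reads are substitution-dominated. Base
qualities are informative: correct bases draw Phred ≈ N(37, 2) clipped
to [33, 41], error bases ≈ N(15, 4) clipped to [3, 25], emulating
calibrated consensus quality strings. Linear contaminants are genome
fragments 1.2–3× a typical circle length with `true_rounds` 1. Reads
shorter than `min_read_length` are dropped but logged, so truth records
always equal emitted + dropped reads. The default minimum read length is
3,000 bp, matching the instrument-side insert filter the pipeline
emulates; small-genome fixtures override it to 200 bp.

**What is not modeled:** polymerase kinetics, chimeric adapter
artifacts, barcode demultiplexing, organellar contamination (off by
default), and sequence-context-dependent error rates. Passing tests
therefore demonstrate algorithmic correctness under a realistic error
budget, not robustness to every instrument artifact.

## Circularity calling (`circcall`)

**Read filter.** Length and mean-base-quality thresholds stand in for
the instrument's insert-length and predicted-accuracy filters (the
accuracy statistic itself is instrument-specific); defaults 3,000 bp and
Phred 30.

**Period estimation.** Candidate periods are the modes of distances
between successive occurrences of identical k-mers (k = 13, reduced for
very short fixtures), restricted to [min_monomer, read/2] and binned ±3
bp to pool indel jitter. Each candidate is screened with a single
segment-vs-segment alignment, then refined over ±3 bp by maximizing the
mean identity of successive period-length segments against the first
(edlib global alignments, at most 6 comparisons). A verified period must
reach the identity floor (default 0.90 — tolerant to 1% error plus
alignment slack, strict enough to reject chance periodicity). A divisor
guard re-tests p/2, p/3, … down to `min_monomer` so a doubled monomer is
never reported; the smallest verifying period wins. `min_monomer`
defaults to 50 bp, which together with the search floor excludes
homopolymer and microsatellite pseudo-periods. Rounds are read length /
period; reads are retained only when rounds exceed 1 (strictly; the
threshold is exposed because the treatment of, say, 1.4 rounds is a
policy choice).

**Consensus.** The first period-length segment is the initial backbone.
Its length is first sharpened to base resolution by locating the
recurrence of the read's 64-bp prefix near the estimated period — a
k-mer spectrum brackets the period only to a few bp, and a biased
backbone otherwise loses the junction bases. Subsequent segment
boundaries are re-anchored by alignment (prefix-mode edlib), so ±1–2 bp
period error cannot accumulate into a frame shift across rounds. Every
segment (including the fractional tail, if ≥ max(20 bp, p/10)) is
aligned to the backbone; per-column majority voting with documented tie
rules (higher base quality first, then first-segment precedence)
produces the consensus. Insertions relative to the backbone are
left-normalized (indel placement inside repeats is ambiguous), pooled
across adjacent columns, and accepted by majority among non-backbone
voters — the backbone cannot witness an insertion relative to itself —
with a quality gate (≥ Phred 30) for single-voter junctions. A second
voting pass against the first-pass consensus polishes residual backbone
errors. A full segment failing the identity floor rejects the whole
call.

**Canonical form.** Circular molecules are compared via the
lexicographically least rotation of the sequence and of its reverse
complement (Booth's linear-time least-rotation algorithm), which is
rotation- and strand-invariant and idempotent.

## Annotation (`annotate`)

Two mapping backends share the 12-column tabular-hit contract
(1-based inclusive subject coordinates, `s_start > s_end` for minus
strand). The reader for external tabular hits applies the e-value ≤
1e-50 filter and one HSP per subject verbatim. The built-in mapper
(exact 13-mer seeds, diagonal chaining with a 25-bp band and 2-kb gap
split, edlib verification with 30 bp padding) filters on identity ≥ 90%
and alignment length ≥ 100 bp as its e-value surrogate; surrogate
bit scores are 2·matches − 3·(mismatches+gaps), sufficient for best-hit
ranking. Karlin–Altschul statistics are deliberately not reimplemented.

Monomers are mapped as their **doubled sequence** so the arbitrary
rotation phase of a circular consensus cannot split its locus into two
HSPs at the junction; coordinates are interpreted on the subject only,
and duplicate HSPs from the two copies are removed by containment
dedup.

Classification rules: origin priority TE > CDS > intergenic (the
databases overlap, so a deterministic precedence is required and
configurable); best hit by bit score with documented tie-breaks;
full-TE calls require eccDNA length ≥ TE length **and** ≥95% coverage of
the TE by the alignment (the guard prevents a long eccDNA merely longer
than an unrelated TE from being called full); single-event means one
merged genomic locus (merge gap 100 bp) covers ≥90% of the monomer;
windows are assigned by best-locus midpoint with floor(mid /
window_size), default 100 kb.

## Quantification (`quantify`)

Two denominators exist and are never mixed: window profiles divide by
the replicate's total eccDNA reads, TE abundance divides by the sample's
total CCS reads, each ×100; every output row names its denominator.
Zero manifest totals are errors (corrupt input); zero fold-change
denominators yield explicit NA (legitimate biology), with an optional
pseudocount. Replicate error bars use the n−1 standard deviation.

## Clustering (`cluster`)

Greedy incremental clustering in length-descending order (id as
tie-break, so results are deterministic and order-robust by
construction): a sequence joins the first cluster whose representative
reaches the identity threshold (default 0.9, the wrapped tool's default)
computed over the shorter sequence, aligning the canonical form against
the doubled representative on both strands. Operating on canonical
sequences is a deliberate improvement over naive linear clustering of
circular molecules: rotation phase can never split a cluster.

## Statistics (`stats`)

Exact two-sided binomial p-values are computed by direct pmf summation
over outcomes whose pmf does not exceed the observed outcome's (with a
1e-12 relative slack for floating-point ties); this matches brute-force
rational-arithmetic summation to 1e-12 for n ≤ 500 and is cross-checked
against an independent library implementation in the tests. Enrichment
defaults to element-count composition fractions (bp-based selectable);
multiple testing defaults to Benjamini–Hochberg with a "none" mode for
analyses that report bare p < 0.05. Group comparisons use Welch's
unequal-variance t-test for two groups (robust at n = 3) and one-way
ANOVA for three or more, significance at p < 0.05. Window correlations
are Pearson on the inner join of window keys; exactly affine data is
snapped to r = ±1 (library routines leave ~1e-16 rounding residue);
zero variance yields explicit NA. LIR membership is ≥1 bp overlap of the
best locus (minimum overlap configurable). The centromeric partition
test is an exact binomial of a family's centromeric eccDNA share against
its genomic centromeric copy fraction, midpoint rule for membership.

## Problem sizes and determinism

The packaged test suite and the acceptance script run the standard
synthetic study at desk scale: 2 × 120–200 kb chromosomes, 100–200
circles, 1% read error, 2–8 rounds, 1,000 Monte-Carlo replicates for
calibration checks — sizes chosen so the full suite completes in a few
minutes on one CPU while keeping every estimate's sampling error well
inside the asserted tolerances. All randomness flows from explicit
seeds; identical seeds give byte-identical FASTA/FASTQ/TSV outputs.

## Known limitations

* The built-in mapper is designed for desk-scale databases (its k-mer
  index is an in-memory Python dict); genome-scale mapping should use an
  external aligner and the tabular-hit reader.
* Consensus accuracy degrades gracefully at exactly 2 rounds, where ties
  must be resolved by base quality alone; reads with informative quality
  strings are assumed.
* Greedy clustering is inherently order-dependent; determinism is
  guaranteed by fixing the order, not by proving order-invariance.
* The enrichment test treats reads as independent draws; RCA duplicates
  of the same molecule violate this if clustering is skipped.
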