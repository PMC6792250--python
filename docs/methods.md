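# Methods

This note documents the models, conventions and numerical choices behind
`nonbcov`, in the order the pipeline runs them.

## Scope and model

The package treats a single phenomenon: sequence capable of adopting non-B
DNA structures (G-quadruplexes, tandem-repeat tracts, dyads/inverted
repeats) is under-sampled by sequencing and, when sampled, read with
elevated error. Everything else — recruitment, coverage arithmetic,
consensus building — is the machinery needed to measure that phenomenon on
a query gene against a read set, and to rebuild a usable gene model from
the reads that survive.

## Non-B motif scanning (`nonbcov.motifs`)

**G-quadruplex.** The scanner implements the strict, degeneracy-free motif
G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊. Conventions, chosen for deterministic
counts in the style of quadparser-like tools:

* G-runs are always maximal — a run of five Gs is one run of length 5,
  never split to start a motif one base earlier.
* Loops are 1–12 characters from {A,C,G,T}; G is allowed in loops. A
  literal N (unknown base) breaks both runs and loops, since an unknown
  base cannot be asserted to satisfy the motif.
* Matches are taken leftmost and non-overlapping; among chains starting at
  the same run the earliest subsequent runs win.
* With `both_strands`, the reverse complement is scanned identically and
  hits are mapped back to forward coordinates with strand "−".

**Tandem repeats.** Exact mode (the default, and the only mode the oracle
tests cover) reports, for each period p ≤ 20, maximal runs where
`seq[i] == seq[i−p]`, kept when they hold ≥3 full copies and span ≥12 bp;
a run already described by a smaller period is suppressed. An approximate
mode tolerating a bounded fraction of internal mismatches exists for
exploratory use. The defaults (period ≤ 20, ≥3 copies, ≥12 bp) are sized
to the short units — "TTGGGGGGG" / "CCCCCCCA"-type motifs — that make up
the introns modelled here; note that the ≥12 bp floor excludes very short
runs such as five copies of a dinucleotide (10 bp) unless loosened.

**Dyads.** For every loop placement (loop ≤ 50 bp) arms grow outward,
pairing left-arm base i with right-arm base i by reverse complement
(Hamming matching only, no gaps), tolerating at most one strictly internal
mismatch: arms never start or end on a mismatch — a mismatch adjacent to
the loop is loop, not arm — and N never pairs. Overlapping candidates are
reduced to local maxima: longest arm first, ties to the smaller loop, then
the leftmost start, accepted greedily without overlap. The arm-extension
loop is JIT-compiled with numba when available; a pure-Python fallback
gives identical results.

**GC content** is computed over unambiguous bases only (N excluded from
numerator and denominator; a sequence with no unambiguous base has
undefined GC, returned as `None`). Batch summaries report median and
quartiles with linear interpolation.

All coordinates throughout are 0-based, half-open, forward strand.

## Synthetic data (`nonbcov.simulate`)

The generator emulates the data situation under study, not an instrument:

* **Genes** are `n_exons` random exon sequences with an *exact* base count
  at the requested GC percent (so the realised exon GC is within half a
  base of target), separated by introns that are pure tandem tracts —
  the architecture of the GC-rich genes this analysis concerns. The non-B
  truth annotation is produced by running the scanners on the finished
  sequence, so truth and scanner agree by construction.
* **Flanks** of random 45%-GC sequence (default 2 kb each side) surround
  the gene so reads can span its boundaries.
* **Sampling.** Candidate long reads have log-normal lengths (configurable
  mean, σ = 0.15) and uniformly placed starts that may overhang either end
  of the flanked source (overhangs are clipped). The overhang convention
  makes the expected naive per-position depth uniform across the source —
  without it the interior runs ~2–4% hot relative to the nominal depth and
  depletion estimates inherit the bias. Candidates are drawn until their
  summed expected depth reaches the target (or exactly `n_reads` when
  requested).
* **Depletion** acts per read at acceptance: a candidate overlapping non-B
  truth intervals with fraction f survives with probability (1 − d)^f.
  The published observations constrain only net outcomes (net 5–11% of
  expected coverage, patchy alignments), not the mechanism — whether reads
  are lost at library construction or at sequencing is left open, and this
  acceptance model reproduces the net behaviour with one parameter.
* **Errors** are injected per position at class-dependent total rates
  (defaults: 13% over routine sequence, 20% over non-B regions — the
  middle of the 11–15% and 15–25% bands), split substitution:insertion:
  deletion = 2:3:1 as is typical of long reads. Realised edit counts and
  the non-B overlap fraction of every read are recorded as truth.
* Reads are reverse-complemented with probability 1/2. All randomness in
  a call flows from one integer seed.

Short reads are the same sampling scheme with fixed length, no errors, and
a dropout parameter playing the role of d.

What the generator does **not** model: chimeric reads,
homopolymer-length-dependent indels, quality values (FASTQ output uses a
constant), GC-dependent amplification curves, or any distinction between
library-construction and sequencing losses. Passing tests therefore
demonstrate that the pipeline recovers the parameters of *this* generative
model, not that it is calibrated for any particular instrument.

## Read recruitment (`nonbcov.recruit`)

Recruitment is seed-and-extend: exact k-mer seeds (k = 13; k-mers
containing N never match) against the query on both strands, clustered on
the diagonal with gaps up to 100, each cluster defining a query window —
the read span projected through the cluster's median diagonal, padded 15%
for indel drift plus 60 bp slack. Highly repetitive k-mers contribute at
most 50 query positions each, and at most 8 clusters per read/strand are
aligned; a tandem tract offers arbitrarily many equivalent placements and
one representative suffices for coverage accounting.

Each window is resolved by an exact local dynamic-programming alignment
(Biopython's PairwiseAligner) scored match +1, mismatch −2, gap open −2,
gap extend −1 — parameters tolerant of ~25% error. The window plays the
role of a band: tests verify the windowed score equals a full-matrix
Gotoh oracle on instances up to 2 kb. Identity is percent matches over
*all* alignment columns, gap columns included (the stricter convention).
Defaults mirror long-read search practice: reads <400 bp skipped,
alignments <400 columns or <70% identity discarded, identity <75% flagged
low-confidence (the regime where GC-rich reads stop aligning reliably).

One best alignment per read per locus is kept (highest score, then longer
alignment, then leftmost query start). Two candidates count as the same
locus when their query intervals overlap *or* when they spend the same
read segment (read intervals overlapping by more than half of the shorter)
— the second clause prevents a repetitive query from double-counting one
read segment at several placements, while genuine multi-locus hits, which
use disjoint read segments, are all reported.

Decision rules are implemented with the stated boundary semantics:
positive hit iff aligned query fraction > 0.90 **and** identity > 95.0
(both strict); contamination iff the aligned-read percentage is ≥ 2.5
("below 2.5%" is strict).

## Coverage statistics (`nonbcov.coverage`)

Expected aligned bases are `query_len × copy_number × dataset_depth`, with
`query_len` always the length of the supplied query sequence and
`dataset_depth` a user input (e.g. 60 or 180), never estimated internally.
The depletion percent is 100·observed/expected at full precision; rounding
is the caller's business. Observed bases sum the query-interval lengths of
the retained alignments (one per read per locus, see above). Patchiness is
the percent of query positions with zero alignment depth. The
per-position depth profile satisfies `depth.sum() == observed_bp` by
construction.

## Consensus models (`nonbcov.consensus`)

Reads are oriented to the query strand, then aligned one by one to the
current model with edlib (unit-cost edit distance, infix mode) — the
standard fast choice for noisy-long-read consensus; the affine scoring
used for recruitment buys nothing at the voting stage. Per column:

* the plurality character wins; ties go to bases over gaps, and between
  bases follow the fixed order A < C < G < T (a deterministic rule in
  place of manual curation);
* a gap majority deletes the column;
* a strict plurality (> half of the reads spanning the boundary) inserting
  the same base opens a new column, deliberately conservative so random
  insertions cannot inflate the model;
* align-and-call iterates (≤5 passes) until the sequence is stable.

Iteration operates on the unmasked majority-base model; the *reported*
sequence additionally renders every column with fewer than `min_depth`
(default 5) supporting reads as N — the representation for uncovered or
unalignable stretches. Masking only the report keeps later passes from
aligning reads against meaningless N-runs. With no reads at all the seed's
span is reported as all N.

**Gene structure.** A cDNA is mapped onto the genomic model by the
recruiter with the length threshold lowered to `min_exon` (20 bp) and
alignments split at deletions of ≥30 genomic bases (intron candidates);
blocks shorter than `min_exon` or below 80% identity are dropped, and the
mapping must explain ≥50% of the cDNA. Exon/intron junctions are slid by
up to 5 bp — legal only where the exchanged exon bases are identical, i.e.
where the alignment is genuinely ambiguous — to expose GT/AG first, then
CG/AG, before a junction is accepted as noncanonical; this mirrors
standard spliced-alignment practice, and the CG/AG tier exists because
that atypical donor is a documented reality in avian leptin genes.

## Pipeline and formats (`nonbcov.pipeline`, `nonbcov.cli`)

Subcommands simulate / scan / recruit / profile / reconstruct wire the
stages together from a YAML config plus flag overrides, writing FASTA,
FASTQ, BED6, bedGraph, GFF3 (1-based inclusive, converted from the
internal 0-based half-open convention), TSV and JSON, plus a
`manifest.json` recording version, seed and thresholds. Outputs contain no
timestamps, so a config+seed pair reproduces byte-identical artifacts.
Exit codes: 0 success, 2 invalid config, 3 missing input, 4 empty result
under `--strict`.

## Test design and problem sizes

Every scanner is checked against an independent brute-force enumerator on
200 random sequences (G4 and tandem up to 2 kb; dyad slices up to 300 bp,
where the quadratic brute force is affordable), with planted motifs so the
comparisons are never vacuous. The recruiter is checked against a
pure-Python full-matrix Gotoh aligner. Depletion recovery is exercised at
d ∈ {0, 0.5, 0.9, 0.95} on a ~6 kb tandem tract at 60X with ~300 bp reads
— sized so that reads partially overlapping the tract edge (which survive
at (1−d)^f > 1−d) perturb the tract-wide estimate by under 3 percentage
points — and the estimate is required within 3 points of 100·(1−d).
Consensus accuracy uses the canonical 15-read / 12%-error / 5 kb setting
and requires ≥99% identity to truth. The full suite runs in a couple of
minutes on one CPU.

## Known limitations

* The G4 scanner is the strict text motif only — no G4Hunter-style
  thermodynamic scoring, and no non-B classes beyond G4/tandem/dyad
  (no Z-DNA, triplex or A-phased repeats).
* The recruiter's exact 13-mer seeding is less sensitive than a
  word-size-5 blastn search; above ~25% error recruitment depends on
  chance seed survival, matching the observation that such reads are
  effectively unalignable.
* Consensus is column voting, not a partial-order-alignment graph; there
  is no quality-aware polishing and no ORF annotation.
* E-values and alignment statistics are out of scope; thresholds are the
  decision rules above.
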