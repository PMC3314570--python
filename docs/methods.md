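# Methods

## The detection model

NumtS detection is cast as local alignment of a mitochondrial reference
(query, treated linearly) against nuclear chromosomes (subjects). The scoring
scheme is BlastN-like: match +2, mismatch −3, gap open −5, gap extension −2.
The gap convention is NCBI's: a gap of length *L* scores `open + L·ext`
(so a 1 bp gap costs −7). `N` aligned to anything scores as a mismatch.

Significance uses the Karlin–Altschul statistic `E = K·m·n·e^(−λS)` with
*m* = mtDNA length and *n* = chromosome length (no edge-effect correction).
λ is solved by Brent root-finding on the moment equation
`Σ_s P(s)·e^(λs) = 1` over the per-column score distribution; K by the
standard lattice-case series approximation (convolutions of the score
distribution accumulating `σ = Σ_k (1/k)[E(e^{λS_k}; S_k<0) + P(S_k ≥ 0)]`,
then `K = δλe^{−2σ} / (H(1−e^{−λδ}))`). For +1/−3, +1/−2 and +1/−4 at
uniform composition this reproduces the published ungapped BLASTN constants
(λ = 1.374/1.332/1.383, K = 0.711/0.621/0.738) to three decimals. Gapped
alignments reuse the ungapped λ, K — a deliberate, documented approximation;
both constants can be overridden to match an external BLAST run. HSPs are
kept at E ≤ 10⁻³.

## Search strategy

Two paths share one affine-gap Smith–Waterman–Gotoh core (numba kernels with
full tracebacks):

* **Full DP** for problems up to `full_dp_max_cells` (default 10⁶ cells):
  exhaustive and exact.
* **Seed-and-extend** beyond that: exact k-mer seeds (default k = 12,
  chosen near BlastN's word size but one larger for desk-scale speed; seeds
  may not contain N, and k-mers occurring > 100 times in the query are
  skipped as uninformative). Seed hits are clustered by diagonal
  (±150 default) and subject proximity (≤ 1500 bp), triggered by a cheap
  ungapped maximum-subarray extension along the cluster's median diagonal
  (threshold 0.8 × the E-value score cutoff, floor 20 — the two-stage
  ungapped-then-gapped design mirrors BLAST), and extended by windowed
  Smith–Waterman with 500 bp pads.

Overlapping HSPs are resolved greedily by score, masking accepted subject
intervals, ties to the leftmost nuclear start. Both strands are searched by
reverse-complementing the query; all reported coordinates are on the forward
strands (0-based half-open), with the HSP strand recording orientation.

**Gap splitting.** An optimal alignment will bridge two strong matches
across an arbitrarily long gap whenever the flanks outscore the gap penalty
(~2 per bp); heuristic extension (BLAST's X-drop) terminates instead. To
match that behaviour the traceback is decomposed at gap runs of
≥ `gap_split_threshold` columns (default 50) and each piece reported as its
own HSP with its own score. This matters for split NumtS insertions: the
spacer between fragments must surface as two chainable HSPs, not one HSP
with a giant deletion. On random pairs ≤ 300 bp the threshold is
unreachable (a 50-column gap costs 105), so the scanner remains exactly
equal to the unconstrained DP there.

## Assembly

HSPs sorted by (chromosome in natural order, nuclear start) are chained
greedily left-to-right: same chromosome, same strand, nuclear gap
strictly < 2000 bp, mitochondrial gap ≤ 2000 bp (the strict/inclusive
asymmetry follows the protocol wording), and mitochondrial order colinear
with nuclear order ('+' records: mito coordinates increase along the
chromosome; '−': decrease — the pattern a single inverted insertion
produces when fragmented). Gaps are `next.start − prev.end`; negative gaps
(overlaps) always chain when strand and colinearity hold. No optimal
chaining is attempted — the original protocol was simple adjacency
interpolation. The repeat-aware relaxation additionally joins a nuclear gap
≥ 2000 bp when ≥ 90% of its bases lie in annotated repeats each ≥ 500 bp
(both configurable; the original protocol left the exact rule unspecified),
flagging such records.

An assembled record's identity is the alignment-length-weighted mean of its
members'. IDs are assigned after sorting, `<prefix>_NumtS_<code>` with
three-digit codes (widening beyond 999 records); the `_b<k>` track-name
suffix carries the block count, with `_b1` also applied to single-HSP
records for uniformity.

## Tracks

BED tracks are 0-based half-open with the 0–1000 score convention; the
score mapping is `round(10 × percent identity)` capped at 1000. The source
catalogues never document their score column; this mapping is the simplest
rule consistent with the observed score range against the reported identity
range (~64–100% vs scores ~708–983) and is override-friendly.

The mismatch track realigns each NumtS to its hinted mtDNA window
(hint ± 500 bp) with a fit alignment (whole NumtS aligned, free end-gaps on
the window); minus-strand records are realigned as reverse complements with
SAM flag 16 and stored in reference orientation. CIGAR, NM and MD follow
the SAM format definition (NM = mismatches + inserted + deleted bases; verified
byte-identical to `samtools calmd`). Assembled records are realigned
fragment by fragment (lines `<track name>.<i>`) because the inter-fragment
spacer is nuclear sequence with no mitochondrial counterpart. Realignments
scoring below a configurable floor raise a "suspect record" error. SAM text
is the contract; BAM conversion is delegated to samtools. For reference
builds lacking a mitochondrial chromosome the mitochondrion tracks are
skipped with a warning.

## Statistics

Repeat-element content counts an element as "within NumtS" on ≥ 1 bp
overlap; base-pair figures use merged-union intersections so no base is
double-counted; flanks (default 1000 bp each side) are clipped at
chromosome ends, which is why genome sizes are a required input. The
Pearson matrix is computed over per-species feature tables (pandas);
zero-variance columns yield missing entries, never 0. Compilation joins
pair records one-to-one by maximal overlap (≥ 1 bp default), ties to the
leftmost; cross-build coordinate conversion is out of scope — inputs must
share a build.

## Synthetic genomes

The generator emulates the observed properties of real NumtS catalogues:
fragment lengths 28–8984 bp and divergence 0–0.36 (identity 64–100%) by
default, strand chosen at 1/2, split insertions (default rate 0.15, spacer
100–1900 bp), duplicated insertions (default rate 0.1, exact copies of an
earlier implant), uniform base composition, substitutions with 10% of
divergence events realized as 1 bp indels (the mutational model is not
specified by any source; this is a single fixed choice). Implants are
placed with ≥ 2001 bp of background between them so that independent
implants can never be chained by the 2000 bp rule — keeping truth
bookkeeping unambiguous. All randomness flows from one seed;
identical seeds give byte-identical output.

What the generator does **not** emulate: realistic base composition or
repeat landscapes, heteroplasmy, assembly gaps, or the clustered insertion
hotspots of real genomes. Passing the recovery suite therefore demonstrates
correctness of the algorithmic pipeline under the stated conditions, not
performance on real assemblies.

Detection scoring assigns each detected record to the truth implant of
maximal span overlap; a truth locus counts as recalled when assigned
records cover ≥ 50% of its fragment bases (so a split implant assembled
into one record is one matched locus), and a record is correct when ≥ 50%
of its bases fall in its implant's span. Base-level recall trims truth
fragments by 20 bp per end — terminal bases an exact-scoring local aligner
may legitimately exclude.

## Problem sizes and numerical choices

The validation suite runs at desk scale: the recovery experiment uses
20 seeded replicates of 1 Mb genomes with 30 implants (lengths
300–5000 bp, divergence ≤ 0.05), the oracle-equivalence suite 200 random
pairs ≤ 300 bp against a textbook row-by-row DP, and repeat statistics are
checked against per-base bitmaps on ≤ 600 kb fixtures. Genome-scale counts
from real assemblies (hundreds of HSPs per species) require the actual
panTro2/rheMac2/mm9 builds and are outside the test scope.

Tie-breaks are deterministic everywhere: HSP acceptance by (score desc,
nuclear start asc, strand), region queries by (score desc, start asc,
name), join pairing by (overlap desc, leftmost). Degenerate inputs are
errors, not silent results: empty sequences, non-IUPAC characters,
inverted gap costs, zero-length intervals, empty compilations for
summaries, regions outside the mtDNA.

## Known limitations

* E-values for gapped alignments use ungapped λ, K (documented above);
  absolute E-values therefore differ from BLAST's gapped statistics,
  though the ranking is preserved.
* The greedy per-round extraction recomputes the DP after masking; for
  subjects with very many overlapping HSPs this is quadratic in the number
  of HSPs per window.
* The primer screen is positional (Hamming sites with an exact 5-base
  3' anchor, both template orientations); it does not model melting
  temperature or secondary structure.
* The seed-and-extend path can miss alignments with no exact 12-mer — at
  the divergence range of interest (≤ 36%, and ≤ 5% in the recovery
  conditions) seeds are abundant, and the full-DP path covers small inputs.
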