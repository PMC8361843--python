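# Methods

This note documents the models, algorithms and numerical choices behind
`trscout`, and what the simulation-based tests do and do not establish.

## Coordinates and data model

All internal coordinates are 0-based half-open (BED convention); SAM's
1-based `POS` is converted at the I/O boundary in `alignio`. An
`AlignmentRecord` stores the CIGAR, clip lengths and the read sequence
as aligned to the reference strand. Hard-clipped supplementary records
without `SEQ` are kept for split-alignment geometry but excluded from
sequence extraction. Secondary alignments (flag 0x100) are ignored by
default: insertion evidence should be counted once per read.

## Tandem-repeat detection (`trfind`)

Detection is a two-step procedure in the tradition of classic
tandem-repeat finders, but fully specified and deterministic:

1. **Candidate motifs.** For sequences ≤ 64 bp, every rotation class of
   2–6 bp motifs is enumerated and scored in a single vectorized batch;
   this makes the detector's best hit provably identical to an
   exhaustive motif/boundary search under the same scoring (a property
   the test suite checks against an independently written oracle). For
   longer sequences, candidate periods come from the self-match profile
   `s(p) = mean(seq[i] == seq[i+p])`: the smallest short period within
   0.02 of the short-period maximum when one dominates (profile ≥ 0.5),
   every short period otherwise (a short tract inside a long window
   leaves the profile mean uninformative), plus the smallest long
   period with `s(p) ≥ 0.55`. Seed motifs are drawn from the up to
   three strongest non-overlapping self-match windows per period
   (window length ≥ 12 bp, so genuine short tracts outrank accidental
   perfect matches of tiny windows).

2. **Wraparound alignment.** Each candidate is aligned to the sequence
   with local (Smith–Waterman-style) dynamic programming over circular
   motif columns: match +1, mismatch −1, indel −2, zero floor. The
   cyclic within-row dependency is resolved exactly with a decayed
   prefix-maximum over a doubled column array, giving O(n·m) per
   candidate with vectorized rows. Tracts are reported when the raw
   score reaches 8 and span at least two motif copies; purity is
   matches / aligned columns; copy number is span / motif length.

**Ranking and parsimony.** Candidates are ranked by *adjusted score* =
score − motif length. Any motif matches one copy of itself for free;
without this charge a long quasi-concatemer motif (with sequencing
errors absorbed into its unit) outranks the true short unit on short
tracts. Ties break toward the shorter motif, then the lexicographically
smallest strand-invariant canonical form, then the leftmost start. When
a motif longer than 6 bp still wins, its own cyclic self-similarity is
probed for a primitive sub-unit (deletion-biased noise can make a
quasi-doubled motif fit marginally better), and the sub-unit competes
under the same rules. After a tract is accepted, the flanking segments
are scanned recursively, so multiple tracts (including different
motifs) are reported per sequence.

**Consensus refinement.** On the long-sequence path, the winning seed is
refined up to twice by taking the per-column majority of the aligned
bases and re-aligning; the refined motif is kept only when it ranks
better. Refinement is skipped on the exhaustive short path, where the
candidate set already contains every short motif.

**Canonical motifs and matching.** `canonical_motif` returns the
lexicographically smallest rotation (by default also considering the
reverse complement, since reads align to either strand). `motifs_match`
is exact canonical equality for short motifs; for long motifs (> 6 bp,
where sequencing noise makes exact identity unrealistic) the shorter
motif must align end-to-end inside a concatemer of the other at ≤ 20%
edit distance, and for mixed lengths the *long* motif must be an
approximate concatemer of the short one — requiring the long motif to
be explained prevents a trivial shared substring from matching.
Whole-query edit distance (edlib) is used rather than local alignment
because score-optimal local alignments truncate at the first
error-dense stretch and under-report coverage.

## Genome scan (`scan`)

Insertions ≥ 100 bp are taken from CIGAR `I` operations and from
adjacent split-alignment pairs on the same chromosome and strand whose
reference gap is ≤ 50 bp while the read gap exceeds it by ≥ 100 bp
(event length = read gap − max(reference gap, 0), anchored at the
earlier alignment's reference end). Events are merged by single-linkage
clustering with a 50 bp window, one (largest) event per read; clusters
need ≥ 2 reads. A cluster survives the purity filter when ≥ 2 of its
insertions are ≥ 70% covered by tracts of one canonical motif and those
motifs agree; the majority motif is carried forward. The locus is then
delineated by screening the reference ± 1 kb around the anchor and
taking the concordant tract nearest the anchor; if de-novo screening
misses a short or low-complexity reference tract, the known insertion
motif is aligned directly over the window as a targeted fallback.
Clusters without any concordant reference tract are discarded
(insertion and genomic motifs must agree). Overlapping loci are
deduplicated toward higher support, ties leftmost, making scan output
independent of input read order.

## Genotyping (`genotype`)

For each read overlapping a target locus, the repeat tract is the read
interval between the last aligned base left of the locus and the first
aligned base at or beyond its end. Flank anchoring is measured in
*reference* bases covered by the alignment outside each boundary
(default ≥ 100 bp per side): reference extent is invariant to read
indel errors, whereas counting aligned read bases would silently fail
reads whose flank margin sits near the threshold. Reads clipped inside
the locus are rescued by aligning the 80 bp reference flank beyond the
missing boundary into the clipped sequence (edlib infix mode); success
requires edit distance ≤ 15% of the flank and a unique placement
(optimal locations > 10 bp apart count as ambiguous). Split-aligned
reads contribute through whichever record rescues; one call per read.

The extracted sequence is screened with `find_repeats`; tracts whose
motif matches a target motif define the call, with repeat size = total
bases covered by matching tracts and copy number = size / length of the
best-matching target motif. Two guards handle pathological sequences:
a call whose matching tracts cover < 50% of the extracted sequence is
not accepted from de-novo detection (an insertion that does not
resemble the target repeat is no evidence), and when de-novo detection
fails on very short or noisy tracts the target motif itself is aligned
directly — the call stands only if that alignment clears the usual
score threshold *and* explains ≥ 50% of the sequence.

Per-locus sizes are clustered with 1-D Gaussian mixtures
(scikit-learn), k = 1..`max_alleles` (default 2), full per-component
variances, 5 initializations, fixed seed, `reg_covar` = 1e-2 so
identical sizes stay numerically benign. The k with the smallest AIC
wins, ties toward fewer alleles. Reads go to their
maximum-responsibility component; components with support < 2 are
dropped and components whose means lie within 2 bp are merged (the
mixture can split a tight cluster into near-duplicates). Allele size
and copy number are exact medians over member reads. Clustering
operates on bp sizes, not copy numbers: sizes are what reads measure,
and dividing by motif length adds no information.

## Simulator (`simulate`)

Toy references place each disease locus on its own synthetic contig:
20 kb uniform-random flanks around a pure repeat tract of the real
locus' motif and reference length (e.g. 20 CGG copies for FMR1).
Alleles are planted by replacing the tract with the desired number of
motif copies. Reads have log-normal lengths (5 kb median, σ = 0.35 —
scaled to the toy contigs), uniform starts, and i.i.d. errors:
substitution 3%, insertion 4%, deletion 5% (12% total, indel-dominated,
deletion-biased, as for raw long reads; the exact composition is
configurable). Every error is logged per read, so the exact alignment
to the *reference* is known and written as a truth SAM: reads crossing
an expanded tract carry an `I` operation of the expansion size adjusted
by local indels, and when the insertion exceeds 1 kb the read is
emitted as a soft-clipped primary/supplementary pair instead, mimicking
how aligners fragment reads around long repeat insertions (and
exercising the split and rescue paths). Read names encode contig,
start, mappability, haplotype, allele size and aligned span, so truth
sets are recoverable from names alone.

Experiment designs:

* `het17` — all 17 disease loci, reference + expanded allele (default
  500 bp tract) at 15X per haplotype.
* `resolve_grid` — bi-/tri-allelic samples over base sizes
  {100, 500, 1000, 2000} × separations {100, 200} bp, 10X per allele,
  with 8 kb flanks (locus-targeted simulation keeps this grid at desk
  scale).
* `mosaic_series` — a toy FMR1 contig; eleven 30-read samples from 100%
  premutation (150 CGG copies) to 100% full mutation (500 copies) in
  10% steps, ten replicates each, every read guaranteed to span the
  tract with ≥ 1 kb flanks.

What the simulator does **not** model: sequence-context-dependent
errors (homopolymer bias), quality scores, chimeras, coverage bias, or
alignment artifacts of a real aligner. Passing tests therefore
establish the correctness of the extraction/clustering machinery under
a realistic error *rate*, not performance on any particular instrument.

## Benchmarking (`bench`)

Ground-truth spanning reads are those covering the expanded locus
footprint with ≥ 50 bp margin on both sides; sensitivity is
TP/(TP+FN) over these reads, false positives are supporting reads
outside the truth set. Assembly repeat sizes are measured by placing
500 bp reference flank probes in each scaffold (edlib infix alignment;
end-to-end, unique within the scaffold, ≤ 20% divergence) and taking
the gap between the probes, reported only when the enclosed sequence is
≥ 80% a single repeat. Called and truth alleles are compared after
sorting, rank for rank; a pair matches when it differs by ≤ 20 bp or by
≤ 10% of the *truth* allele (the relative rule is deliberately
asymmetric, anchored on the truth side). A mono-allelic call against
bi-allelic truth classifies as `one_match` at best. Distribution
comparisons use the two-sample Kolmogorov–Smirnov test (scipy) at
α = 0.05.

## Experiment-design choices in the acceptance runs

The read-level sensitivity experiment genotypes with
`min_flank_anchor = 50` bp, equal to the ground-truth overlap margin,
so the support-read and truth-read definitions coincide; with the
default 100 bp anchor, truth reads with 50–100 bp margins would be
rejected by construction, capping measurable sensitivity regardless of
algorithmic quality. The default anchor remains 100 bp for general
use, where firmer anchoring is worth a small loss of marginal reads.

Problem sizes: the heterozygous experiment simulates ~20 Mb of reads
(17 contigs × ~40 kb × 30X); the mosaic series 110 samples × 30 reads;
the resolution grid seven samples at 20X over 17 contigs with 8 kb
flanks. These sizes give a few hundred truth reads per experiment —
enough for the percent-level claims being checked — while keeping each
experiment in the minutes range on one CPU.

## Known limitations

* No SNV-based phasing; allele count is bounded by `max_alleles`, so
  loci with more alleles than that are under-called by design.
* Contractions (alleles smaller than the reference) are not discovered
  in scan mode (only insertions are mined), though genotype mode sizes
  them correctly at given loci.
* Motif interruption structure is summarized only as purity; the
  interrupting motifs are not decomposed.
* Very short noisy tracts (a few copies of a short motif, e.g. the
  42 bp GGCCTG tract) can occasionally evade de-novo motif recognition;
  the known-motif fallback recovers most but not all such reads.
* The wraparound aligner's scoring (+1/−1/−2, threshold 8) is tuned for
  ~10–15% read error; substantially noisier data would need a more
  permissive scheme.
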