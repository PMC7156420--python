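# Methods

## Coordinate and strand conventions

All mutation bookkeeping is normalised to 1-based cDNA coordinates on the
coding (non-transcribed) strand; codon *i* spans positions 3i−2..3i, so the
Kras hotspots are G12 at 34–36 (GGT), G13 at 37–39 (GGC) and Q61 at 181–183
(CAA). An amplicon stores its sequence in read orientation plus the cDNA
coordinate of the read's first base; for transcribed-strand assays the read
runs 3'→5' along the coding strand and bases are complemented on mapping.
The mapping is a bijection and its own inverse, so assays of either strand
produce identical mutation-key spaces (verified by test), while the
originating read strand is kept on every record for strand-bias analyses.

Trinucleotide classes are reported in two anchored forms: the 5'-anchored
pattern (CAN>CTN: an A>T with a 5' C, any 3' base) and the 3'-anchored
pattern of the same key; the class a change carries on the opposite strand
is the 3'-anchored pattern of the reverse-complemented key (CAN>CTN ↔
NTG>NAG). This makes the complement relation an involution that tests can
check mechanically.

## Hotspot enumeration

All nine single-nucleotide substitutions of each hotspot codon are
translated with the standard genetic code; synonymous and nonsense changes
are excluded. Point mutations are counted per gene; distinct substitutions
collapse point mutations reaching the same (gene, codon, amino acid) — at
Q61 (CAA) both 182A>C (CAC) and 183A>T/C (CAT/CAC) encode histidine, which
is why 19 missense point mutations per gene collapse to 18 distinct
substitutions, giving 57 and 54 over three genes.

## Library simulator

The generator models exactly the structure consensus calling exploits,
rather than a full branching PCR:

- each of `n_templates` templates receives one barcode drawn uniformly
  from the 4^14 space (collisions are kept, not deduplicated — at realistic
  scales they are rare and downstream code must tolerate them);
- spike-in templates carry 2–3 co-occurring engineered substitutions at a
  configured template frequency (the count is rounded; sub-Poisson designs
  warn);
- each template gets `Poisson(lambda_linear)` (truncated ≥1, default 10)
  linear copies; each copy acquires substitution errors at `p_linear_error`
  per base (default 10⁻⁵), inherited by exactly the reads descending from
  that copy — the one error process that *can* be family-consistent;
- each template yields `Poisson(lambda_reads)` sequenced reads (default 6,
  a realistic mean family size for a well-loaded run), each picking its
  ancestral copy uniformly and adding independent sequencing errors at
  `p_seq_error` per base (default 10⁻³);
- reads are emitted as `[index][barcode][primer][target]` with Phred+33
  qualities drawn from a clipped normal (mean 35, sd 5, clip 2–40) for the
  target and a fixed Q40 for the technical prefix. Qualities are
  thresholds for the filter, not error probabilities: error placement is
  independent of the emitted quality by design.

The linear-copy and sequencing rates are exposed configuration, not
measured values. Identical config + seed gives byte-identical FASTQ and
manifest. What the simulator deliberately omits: indels, chimeras, adapter
read-through, GC amplification bias, barcode-sequencing errors as a
distinct process, and duplex (two-strand) barcoding — so passing tests
demonstrate correctness of the consensus logic under the stated error
model, not robustness to every artifact of real libraries.

## Read processing

The quality filter passes a read iff ≥90% of bases have Phred ≥20,
boundary inclusive. Demultiplexing anchors on the known gene-specific
primer: a sample matches when its 0–7 nt index prefixes the read and the
primer aligns at `len(index) + 14` within 2 mismatches, longest index
first, so a zero-length index is only a fallback. Barcode and target are
excised and the target must match the expected length exactly, which
discards indel-containing reads. The pair merger picks the overlap (≥10 nt,
mismatch fraction ≤0.1) maximising matches−mismatches, resolving
disagreements to the higher-quality base (tie → read 1) with the lower
quality retained; it is a minimal merger, not a re-implementation of any
particular published tool.

## Consensus calling

"Unique consensus" is operationalised as a per-position supermajority:
at every position one base must be carried by ≥90% of members. For family
sizes ≤9 this equals unanimity, which makes the rule conservative against
PCR jackpots and barcode collisions; families failing it are dropped
(NO_CONSENSUS), never guessed. The consensus sequence is exact-matched
against the reference and its complete single-substitution library: WT,
SINGLE (with the matched key), or OTHER for multi-substitution consensi.
OTHER families stay in the frequency denominator — the frequency of a
mutation is mutant families over *all* families — but are reported
separately. Spike-in mode checks only the engineered positions and accepts
families of ≥2 reads. The sample-level QC excludes samples with fewer than
1.5×10⁵ recovered families (strict less-than).

A deliberately simple per-family reference implementation and a vectorised
bulk caller coexist; the test suite asserts their equality on a thousand
randomized families.

## Frequencies, correction, fold change

Every key of the 3L-key library gets an explicit row; unobserved keys have
frequency zero. Before any log transform, frequencies are corrected by
adding the detection limit at the QC floor, 1/1.5×10⁵ ≈ 6.67×10⁻⁶ — one
fixed constant for all samples (a per-sample 1/total variant is available
but not the default). Heatmap matrices follow correct → sum within group →
fold change over the arithmetic mean of PBS samples → log10; an
unnormalised log10 mode serves per-key views. Because the correction is a
constant shift, frequency ordering is preserved and no entry is −∞.

C>T and G>T substitutions *as read* are inflated by cytosine deamination
and guanine oxidation during library preparation; the merged coding-strand
table therefore takes those keys from the assay of the opposite strand,
where the same change reads as G>A or C>A, recording provenance per key.
With only one strand assayed the affected keys are flagged masked.

## Tropism analyses

Strand-bias summaries average corrected frequencies over the positions
belonging to a class (e.g. CAN>CTN) and its reverse-complement class as
read in the same assay, then report mean ± SEM across samples (SEM 0 with
one sample). The expression-quartile analysis sorts genes by mean FPKM
with a stable (FPKM, gene id) key — determinism under row reordering —
splits them into four bins whose sizes differ by at most one (remainder to
the lower quartiles), sums class counts per tumor, per quartile and per
annotated strand, and reports the cohort mean ± SEM with n = number of
tumors. Mutations are counted per tumor occurrence, not once per gene.
Gene strand is an input column; the package does not compute gene
orientation from a genome.

The synthetic expression/WES generator draws log-normal FPKM (reps with
20% log-noise) and Poisson counts from per-strand rates as functions of
expression rank; the default rates rise (non-transcribed, 0.05→0.35) and
fall (transcribed, 0.35→0.05) linearly with rank, emulating
transcription-coupled asymmetry at per-gene-per-tumor counts of order 0.1.

## ddPCR quantification

Mmu = −ln(1 − nmu/n), MDNAconc = −ln(1 − nDNAconc/n), MAF = Mmu/MDNAconc,
where nDNAconc counts droplets positive for the mutant and/or wild-type
probe. Wells of one sample are pooled by summing droplet counts before the
transform (the maximum-likelihood combination for a shared concentration);
per-well estimates are also reported. Saturated wells (all droplets
positive) and empty wells are errors, not silent NaNs. No confidence
intervals are reported.

## Problem sizes used in tests

The acceptance-level suite runs the spike-in recovery at 2×10⁵ templates
(one mutant template at 5×10⁻⁶, recovered within 3-fold), the error
suppression property on >10⁵ size-≥3 families at sequencing error 10⁻³
with the linear-copy channel off (that channel is family-consistent by
construction, which is precisely the signal consensus calling is meant to
keep), and the dilution series 10⁻³..10⁻⁵ at 10⁵ templates per level. The
same machinery scales to 2×10⁶-template libraries (frequency 5×10⁻⁷) by
changing `n_templates`; memory stays bounded by the read matrix
(reads × length bytes).

## Known limitations

- Exact barcode matching only; no edit-distance clustering of barcodes.
- The merger is minimal (no quality-model rescoring of overlaps).
- The consensus is unweighted by base quality.
- Synthetic references carry only the documented codon/context features;
  positions outside them are arbitrary, so position-specific results other
  than the hotspot codons are not biologically meaningful.
- The simulator's defaults are plausible stand-ins where no measured value
  exists; conclusions about real libraries require re-estimating
  `lambda_linear`, `p_linear_error`, `lambda_reads` and `p_seq_error`.
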