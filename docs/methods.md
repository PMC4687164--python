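# Methods

`reseqaudit` audits a finished (closed) bacterial genome assembly against
short-read resequencing data. The scenario it targets: a genome closed
with early long-read technology carries a few hundred single-base
deletions concentrated in homopolymer runs; mapped short reads reveal
each one as a near-fixed insertion in the read consensus; applying the
corrections repairs annotated frameshifts and premature stop codons, and
a closely related genome can adjudicate every corrected allele. This
note records the model, the defaults, and the choices made where the
design was open.

## The audit model

A *discrepancy* is a site where the consensus of mapped reads differs
from the reference assembly. Because the sequenced isolate is clonal and
the question is assembly accuracy rather than polymorphism, calling is
consensus-level: an alternative allele is called only when it is carried
by at least `min_alt_fraction` (default 0.8) of the reads spanning the
site at depth ≥ `min_depth` (default 10). Fractions ≤ 0.5 are rejected
outright — a consensus caller needs a majority. At most one call is made
per site: the highest-fraction allele, ties going to the
lexicographically smallest.

Indels are reported *left-normalized*: an indel inside a homopolymer run
is shifted to its leftmost equivalent placement (rotating multi-base
alleles as in VCF left-alignment), so equivalent representations compare
equal. Normalization happens twice, deliberately: once per read when the
pileup counts an indel observation — an optimal aligner may anchor the
same gap at either end of a run, and the consensus would otherwise be
split across columns — and once more on the emitted call, where it is a
checked idempotent no-op. The leftmost representable anchor is column 0;
there is no "insertion before the genome".

Each discrepancy is annotated with its homopolymer context, measured on
the *uncorrected* reference (the sequence the discrepancy table
describes): for an insertion, the maximal run of the inserted base
immediately following the normalized anchor; for a deletion or
substitution, the maximal run containing the site. An inserted base
matching neither neighbour gets run length 1 by convention. Summaries
report both `n_run_ge5` and `n_run_ge6` so either reading of a
"greater than" threshold in prose is checkable.

## Mapping

The built-in mapper is a seed-and-extend design adequate for synthetic
data and small real datasets: non-overlapping read k-mers (k = 21) vote
for reference diagonals; the best few diagonal clusters are extended by
a banded edit-distance alignment (edlib, band 16) of the read against
the candidate window, both strands tried. Alignments with edit distance
above 10 % of the read length are unmapped; tied best scores at distinct
loci are discarded as multi-mapped rather than risk false alleles in
repeats. Ties within the rules break to the leftmost reference position,
then the + strand, so mapping is deterministic.

Reads crossing sequence absent from the reference cannot align end to
end under an edit-distance model, so a rescue path remaps the longest
mappable prefix or suffix, folds edit-dense terminal segments into the
soft clip, and then extends exact matches so the clip boundary lands on
the junction. This exists to feed the large-indel screen: a cluster of
soft clips marks an insertion in the sample, a stretch of depth below
10 % of the genome-wide median over ≥ 100 bp marks a deletion.

For full-scale real data the recommended entry point is a SAM file from
a production mapper, imported through `seqio.read_sam`; it feeds the
identical pileup machinery, and on error-free synthetic reads the two
routes produce byte-identical pileups (tested).

## Correction, liftover, and coding impact

Corrections are applied right-to-left so earlier coordinates stay valid,
with the exact invariant `len(corrected) = len(old) + Σ(len(alt) −
len(ref))` asserted on every run. A piecewise-offset coordinate map
lifts annotation boundaries; a feature whose boundary falls inside a
deleted stretch is clamped and logged, never dropped.

The coding consequence of each correction is classified by re-scanning
the corrected locus for open reading frames (translation table 11;
ATG/GTG/TTG starts; every start between two stops is a candidate ORF).
Among ORFs containing the corrected site and covering the annotated
span, the one whose boundaries best match the span is chosen — choosing
the *longest* instead would, in AT-rich sequence, frequently absorb a
chance upstream in-frame start codon and prepend spurious residues to
the product. Classification precedence for indels:

1. **gene_merge** — at least two same-strand annotated features are
   contained in the repaired ORF. Membership is decided by containment
   in the ORF, not by overlap with the site: in a split gene the
   discrepancy typically lies inside only one fragment.
2. **stop_removed** — the old annotated frame contains an internal stop
   absent from the repaired product.
3. **frameshift_repair** — a ±1 bp correction restores a single ORF
   covering the annotated region (and matching an expected ortholog
   length within ±5 %, when one is supplied).

Substitutions are synonymous/missense by codon comparison; sites outside
any CDS are intergenic.

Annotation transfer between proteomes is scored by *combined identity*:
alignment identity over the aligned reference span times the fraction of
the reference covered, from a glocal alignment (query global, reference
ends free; match +2, mismatch −1, gap open −5, extend −1). A hit is
accepted at combined identity ≥ 0.25 — i.e. 50 % identity over 50 % of
the length — and a significance proxy: a Karlin–Altschul-style e-value
computed from the alignment score (score/2 bits against the product of
the sequence lengths) must fall below 10⁻⁵. The proxy stands in for a
full extreme-value calibration, which is out of scope; it is calibrated
only to reject short spurious alignments. `perfect` means full-length
100 % identity; any other accepted hit is `length_mismatch`.

## Cross-validation against a related genome

For each discrepancy, two windows of ±250 bp around the site are framed
— one under the corrected allele, one under the reference allele — and
each is searched as an infix against both strands of the related genome
(edlib). If the better window aligns at under 70 % identity the region
is *not found*. Otherwise the verdict is decided by raw edit distance —
the windows differ only by the allele, so distances are directly
comparable, and an exact tie reads *neither* rather than a coin flip.
Because the search is an infix scan the whole window always participates;
the nominal coverage clause of the found/not-found rule therefore
reduces to the identity threshold. At the protein level the repaired
product is globally aligned to its related counterpart and reported as
"m/n": m identical columns over n alignment columns (gap columns
included, so a truncation counts against identity).

## Coverage

Depth at a position counts reads whose alignment spans it with M or D
(a read deleted at a column still spans it); soft clips never count.
The genome-wide mean and population SD over all positions, mean read
length, and per-CDS breadth — the fraction of a CDS's positions at depth
≥ 40 — are reported, including the two headline percentages (CDSs at
full breadth, CDSs at ≥ 60 % breadth). Breadth is non-increasing in the
threshold, and the depth-vector sum equals the total reference-consumed
bases of all alignments; both are tested invariants.

## The synthetic-data generator

The generator builds the complete study world so every stage runs with
no downloads:

* **True genome** — bases from a first-order Markov mixture: with
  probability `homopolymer_bias` (default 0.2) repeat the previous base,
  else draw i.i.d. from the target composition (GC 0.31). The repeat
  step leaves the marginal base composition unchanged — realized GC
  stays within ±2 points of target — while enriching long homopolymer
  runs the way real AT-rich genomes are enriched relative to i.i.d.
  sequence; bias 0 recovers exact i.i.d. sampling.
* **Planted CDSs** — by default one per 1250 bp (≈ 60 % coding, typical
  of a bacterial chromosome), each an ATG, an interior drawn from the
  same biased process with in-frame stops repaired by sense codons, and
  a stop codon, placed in disjoint slots on random strands. Drawing the
  interior from the biased process matters: i.i.d. codon sampling leaves
  coding regions almost devoid of long runs, and planted errors would
  then be ~90 % intergenic instead of the realistic ~60 % coding.
* **Corrupted assembly** — the published-reference analog: one base
  deleted from each of `n_planted_errors` homopolymer runs. Run-length
  demand is multinomial over `run_length_weights` (default mass
  {4: 0.08, 5: 0.07, 6: 0.35, 7: 0.30, 8: 0.20} over run lengths *as
  measured on the corrupted assembly*, so > 90 % of errors sit in runs
  ≥ 5 and ~85 % in runs ≥ 6); runs are drawn uniformly without
  replacement within each class, and a shortfall in any class is a
  configuration error reporting the available counts. Runs within one
  insert length of a linear genome's ends are ineligible — fragment
  sampling ramps depth down there, and a planted error below calling
  depth would test nothing. The truth table stores each planted deletion
  as the left-normalized *insertion* the audit should call, in
  corrupted-assembly coordinates, together with the CDS annotation
  lifted onto the corrupted assembly (as a real reference's annotation
  would be).
* **Reads** — 2×250 bp FR pairs, fragment length N(500, 50) sampled
  uniformly (wrapping on circular genomes), substitution errors only at
  `per_base_error`, constant quality at the Phred score implied by the
  rate. Read-indel errors are excluded by default to keep the consensus
  caller's null clean. Pair count is set so expected coverage equals
  `coverage_target`.

One integer seed drives everything; each stage derives an independent
stream via `SeedSequence` spawned with a fixed per-stage key, so stage
order cannot perturb reproducibility, and two runs with the same
configuration produce byte-identical reports (tested).

What the generator does **not** emulate: read-indel and quality-dependent
errors, GC-dependent coverage bias, adapter contamination, repeats and
mobile elements (so multi-mapping is essentially absent), operon
structure, and codon usage. Passing tests therefore demonstrate the
audit logic — detection, normalization, arithmetic, classification,
cross-validation — under clean Illumina-like conditions, not robustness
to every artifact of real libraries; for real data the SAM import path
plus a production mapper is the supported route.

## Problem sizes and numerical choices

The standard synthetic conditions used by the test suite and the
acceptance script are a 200 kb genome, 100 planted errors, 100× coverage
and a 0.2 % per-base error rate — large enough that every run-length
class is populated and depth fluctuations are representative, small
enough to run in seconds. The length-arithmetic check runs at full
chromosome scale (4,352,205 bp) because it is pure string/offset work.
The goodness-of-fit check of planted run lengths (χ², n = 500) also uses
a chromosome-scale genome so that the rarest weight class has a run pool
an order of magnitude larger than its demand, keeping draws effectively
multinomial.

Degenerate inputs are defined, not accidental: zero planted errors give
an identical assembly and an empty truth table; zero discrepancies give
an identity coordinate map and a summary of zeros; empty calls against
empty truth score precision = recall = 1.0, and empty calls against
non-empty truth score precision 1.0 (vacuous), recall 0.

## Known limitations

* The mapper is O(genome) per lookup in pure Python with a dict index;
  mapping a full 200× chromosome-scale dataset works but is not
  performance-engineered. SAM import is the intended path at that scale.
* The e-value proxy is not a calibrated extreme-value statistic; it is
  monotone in the alignment score and rejects short spurious hits, which
  is all the transfer rule needs.
* Diploid or population genotyping, base-quality-aware likelihoods, and
  somatic calling are out of scope by design; so are BAM/CRAM parsing
  (text SAM only) and GenBank flat-file writing.
* A correction landing in a feature annotated on the opposite strand of
  its true gene, or in overlapping genes on both strands, is classified
  conservatively as `other`.
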