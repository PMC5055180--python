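# Methods

## Problem setting

High-throughput sequencing of T-cell receptor beta-chain (TCRB) CDR3 regions
is dominated by two error sources: per-base sequencing errors (indel-heavy on
semiconductor platforms) and PCR resampling, which together inflate apparent
clonotype diversity and destroy absolute quantitation. The approach
implemented here attaches a 12-nt random molecular barcode (UMI) to each cDNA
molecule at reverse transcription, so that (i) reads can be grouped per
molecule and error-corrected by consensus, and (ii) the number of distinct
retained barcodes *is* the number of sequenced molecules. Absolute molecule
counts in turn justify species-richness machinery (ACE, rarefaction) on the
clonotype abundance table.

## Read architecture

Each single-end read is laid out 5'→3' as

    sample_index(5 nt) + barcode(12 nt) + spacer GTACATATTGTCGTT (15 nt)
    + C-region primer CTCTGCTTCTGATGGCTCAAAC (22 nt) + antisense TCRB

with the antisense part running from the constant-region primer site back
through J, the CDR3 junction, and into V. The simulator, demultiplexer and
annotator all share this contract; reads are re-oriented to the mRNA sense
strand only at annotation time.

## Pipeline stages and their rules

1. **Demultiplex** — first 5 nt matched exactly against the known sample
   indices (5-nt indices leave no useful edit slack); the spacer is located
   as the best ≤1-edit match starting at positions 15–20 of the read, so a
   single indel inside the barcode still anchors the tag boundary. Reads
   whose spacer+payload span is shorter than 150 nt are discarded.
2. **Tag-error monitoring** — indels dominate, so barcode errors surface as
   11- or 13-nt tags. Every 11/13-nt tag at exactly one indel from a 12-nt
   tag is marked as that tag's derivative (ties: most reads, then smallest
   tag). Per reads-per-tag bin *r*, the error-free fraction is
   n12/(n12+nderiv); the read-count threshold r\* is the smallest *r* such
   that every non-empty bin ≥ r\* has a fraction ≥ 0.90. Derivative reads
   are never pooled into the parent consensus — their tag identity is
   uncertain, and the conservative choice costs only coverage.
   Tags of the same length at Hamming distance 1 are *not* merged;
   substitution-born tags are handled by the read-count threshold instead.
3. **Counting** — retained molecules are the 12-nt, non-derivative tags with
   ≥ r\* reads; their number is the sample's absolute molecule count.
4. **Consensus** — per retained tag, at most the 50 longest reads (ties by
   input order) are aligned by a center-star scheme: the longest read is the
   center, every other read is globally aligned to it (match +1, mismatch
   −1, gap open −2, extension −1), and pairwise gaps are projected into a
   common frame ("once a gap, always a gap"). Within an insertion slot,
   reads inserting the same base at the same offset share a column while
   different bases get distinct columns, so independent single-read
   insertion errors cannot jointly defeat the gap majority. Each column
   takes the symbol carried by strictly more than 80% of the covering rows
   (leading/trailing gaps are non-coverage); a winning gap emits nothing,
   no winner emits N. Note that with ≤5 covering reads the strict >80% rule
   demands unanimity, so small tag groups carry N at any disputed column;
   N is a no-call, not a miscall, and molecules whose N lands inside the
   CDR3 are discarded at translation. A dedicated in-repo aligner (rather
   than an external MSA binary) keeps the pipeline hermetic; at the >99%
   within-tag identity typical of these groups, center-star and full MSA
   are effectively equivalent.
5. **Annotation** — consensus sequences are reverse-complemented to sense
   (the chemistry guarantees antisense; an auto-detect mode scores the best
   V seed on both strands and flags sequences with no seed ≥20 as
   unoriented). Each germline V and J is locally aligned with the same
   scoring; the best V (ties: identity, then name) must score ≥20 and the
   best J ≥15, thresholds chosen so that random 250-nt sequences (chance
   local scores ≤ ~18 against this reference) are rejected. The J hit must
   end 3' of the V anchor codon mapped onto the consensus — the anchor, not
   the raw V alignment end, defines "past the V", because local V
   alignments can drift a few bases into the junction when the junction is
   short. The CDR3 runs from the first base of the V Cys codon to the last
   base of the J Phe codon, both mapped through the alignment blocks
   (inclusive convention, so reported peptides start with C and end with F;
   an exclusive mode is available). Records with a frame shift, stop codon
   or ambiguous base are discarded with a reason code; no CDR3 length
   bounds are imposed.
6. **Clonotypes** — nucleotide-level clonotypes are (V, J, cdr3_nt) groups;
   amino-acid-level clonotypes pool nt clonotypes on cdr3_aa alone, since
   convergent recombination produces the same peptide from different
   rearrangements with inconsistent V usage.

## Repertoire statistics

With clonotype abundances n_1..n_S (Σ n_j = N molecules):

* **ACE** (Chao–Lee), rare cutoff k = 10: with S_rare, S_abund the rare/
  abundant clonotype counts, F_i the number seen i times, N_rare = Σ_{i≤k}
  i·F_i, coverage Ĉ = 1 − F₁/N_rare and
  γ̂² = max{ (S_rare/Ĉ)·Σ_{i≤k} i(i−1)F_i / [N_rare(N_rare−1)] − 1, 0 },

      Ŝ_ACE = S_abund + S_rare/Ĉ + (F₁/Ĉ)·γ̂².

  Degenerate cases: an empty rare group returns S_abund; an all-singleton
  rare group (Ĉ = 0) falls back to Chao1 = S_obs + F₁(F₁−1)/2 with a
  warning; a rare group holding ≤1 molecule is an error.
* **Rarefaction** — E[S_m] = Σ_j [1 − C(N−n_j, m)/C(N, m)], evaluated with
  log-gamma binomials; the default grid is 20 log-spaced sizes.
* **Subsampling** — fixed-size comparisons (default 100,000 molecules) use
  a seeded multivariate hypergeometric draw.
* **Abundance classes** — by molecule frequency: low < 0.01%,
  middle 0.01–0.1% (left-closed), high ≥ 0.1%.
* **Sharing** — for a clonotype present in exactly m ≥ 2 samples, its class
  is computed per sample; the "all" category rule assigns the minimum class
  across those samples, the "any" rule the maximum.

## The simulator as study-condition generator

The simulator produces ground-truthed runs: a clone repertoire (uniform or
power-law rank frequencies), V(D)J junctions (0–6 nt trimmed from the V tail
after the Cys codon and from the J head before the Phe codon, 0–15 random
inserted nt, insert length adjusted to keep the CDR3 in frame, stop-bearing
junctions redrawn — i.e. productive rearrangements by construction),
molecules sampled from clone frequencies with independent uniform 12-mer
barcodes (a distinct-barcode switch exists for exactness tests), reads per
molecule as 1 + negative binomial (default mean 10, size 20 — mildly
overdispersed PCR resampling), and per-base errors at sub/ins/del =
0.001/0.004/0.004. The platform's error rates are not published as numbers;
these defaults encode the indel-dominant regime at a realistic overall
magnitude (~0.9%/base). Reads default to 250 nt total so the 150-nt length
filter passes untruncated reads; shorter read lengths can be configured to
exercise the filter. All randomness derives from one seed through named
substreams (repertoire / barcodes / sampling / errors), so changing, e.g.,
error rates does not change which clones are sampled.

What the simulator does *not* model: quality scores (constant Phred 40),
flow-space homopolymer error structure, PCR chimeras, amplification bias
between protocols, and sequence-dependent error hotspots. Passing tests
therefore demonstrate the pipeline's correctness under independent-error,
unbiased-resampling assumptions, not performance on any particular
instrument run.

## Problem sizes used in tests and the acceptance script

Round-trip and counting checks run at 10⁴ molecules from 10³ clones (mean
10 reads/molecule, ~10⁵ reads); estimator recoveries sample 30–40×10³
molecules from repertoires of 2,000–50,000 clones across 10 seeds. These
sizes give stable statistics (binomial SEs well below the asserted margins)
while keeping a full run in minutes on one core. Estimator-level checks
(ACE recovery, skewed-vs-flat contrast) draw molecule counts directly from
clone frequency vectors — the read-level stages are exercised separately —
since the statistics consume only the abundance table.

## Known limitations

* Center-star consensus with the strict >80% rule is conservative at low
  read counts: tag groups of 3–5 reads yield N wherever any read disagrees,
  and those molecules are dropped if the N falls inside the CDR3 (~10–15%
  of molecules at default error rates). Molecule *counting* is unaffected.
* The 90% error-free cut is applied per sample; with very low error rates
  the lowest reads-per-tag bins can be sparsely populated and the threshold
  is then driven by few tags.
* Sample indices are matched exactly; reads with an index error are
  rejected rather than rescued.
* The annotator assumes a small germline reference (tens of segments); the
  exhaustive local-alignment search is quadratic in reference size and
  would need a seeded search to scale to full allele catalogues.
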