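# Methods

## Gene models, introns, and splice motifs

Coordinates are 1-based closed (the GFF3 convention) throughout the library;
the only conversion is the BED-style intron table written to disk, which is
0-based half-open and says so in its header. Introns are the gaps between
consecutive exons of an mRNA: a transcript with *n* exons has exactly *n − 1*
introns, and exon plus intron lengths tile the transcript span — both
identities are enforced by tests. Intron ordinals run 5'→3' in transcript
orientation, so intron 1 of a minus-strand gene is the genomically rightmost
gap.

Donor and acceptor dinucleotides are read in transcript orientation: on the
plus strand they are the first and last two intron bases; on the minus strand
the genomic boundary 2-mers are reverse-complemented and swapped. A model and
its reverse-complemented mirror therefore yield identical motifs (a tested
invariant).

Classification is by the joint (donor, acceptor) pair — GT-AG, GC-AG, AT-AC,
GA-AG, or Others. A GA donor paired with anything but AG is Others, because
the named classes are pair motifs, not donor motifs. "Canonical" means GT-AG
only; GC-AG is counted as non-canonical, matching how published genome-wide
tables roll the classes up. Two conventions handle degenerate cases: introns
shorter than 4 nt cannot carry two distinct 2-mers and are counted under
Others, and so are introns with an N at a boundary position. Percentages are
rounded half-up to two decimals for display; raw counts are always retained
and all rollup identities (canonical + non-canonical = grand total) hold on
the raw counts exactly.

Multi-isoform genes: by default every intron of every mRNA counts once per
transcript; a `dedup` flag collapses introns that share (seq_id, strand,
start, end). Annotation practice varies on this point and published tables
rarely state which convention they used, so both are exposed.

## Coverage and splicing efficiency

SAM input is parsed with pysam; unmapped, secondary and supplementary records
are dropped, and records with CIGAR operations outside {M, I, D, N, S} are
rejected with a warning. Replicates are taken from RG tags when present,
otherwise one group per file.

Per-base depth counts M and D operations (a deletion consumes reference
inside an aligned segment); N gaps and soft clips contribute nothing. A
feature's coverage is its mean per-base depth; the cross-replicate summary is
the mean of replicate means with their sample standard deviation (ddof = 1,
zero for a single replicate). With n = 3 biological replicates the n vs n − 1
choice changes s.d. by ~22%; the sample convention is used because these are
estimates from a sample of replicates.

**Coverage-ratio efficiency** is `1 − intron_cov / mean(flank_covs)`, clamped
to [0, 1]; it is the primary statistic because it is computable directly from
a per-feature coverage table. It assumes the two flanking exons are
constitutively included and uniformly covered — it will be biased for introns
whose flanking exons sit at the transcript ends, where coverage ramps down
over one read length.

**Junction efficiency** is `spliced / (spliced + unspliced)`, where a spliced
read carries an N gap exactly matching the intron with ≥ `min_anchor` aligned
bases on each side, and an unspliced read is continuously M-aligned across
the donor boundary (the last exon base and first intron base, in transcript
orientation) with the same anchor requirement. The default `min_anchor = 3`
excludes 1–2 bp spurious overhangs while keeping nearly all genuine junction
reads of a 100 bp read informative. Insertions do not break reference
continuity of an M run; deletions and N gaps do.

Both estimators are consistent for `1 − r` when reads sample the transcript
pool uniformly per base (see below) and agree within binomial error on
simulated data across retention 0–0.5, a tested invariant.

## Trouvelot mycorrhization indices

The class weights are the standard MYCOCALC realisation of the Trouvelot
scoring system: colonization classes 0–5 map to 0, 1, 5, 30, 70, 95% of the
fragment colonized, and arbuscule classes A1–A3 to 10, 50, 100% arbuscule
abundance within the colonized part. With N fragments, n_c per class:

    F  = 100 (N − n0) / N
    M  = Σ_c w(c) n_c / N
    m  = M N / (N − n0)                       (0 when nothing is colonized)
    mAi = 100 Σ_{frag ∈ Ai} w(class) / ((N − n0) m)
    a  = (100 mA3 + 50 mA2 + 10 mA1) / 100
    A  = a M / 100

These satisfy A = a·M/100 exactly, A ≤ min(a, M), m ≥ M, the mAi shares of m
(including the implicit A0 share) sum to 100, and all indices are invariant
under replicating the fragment table — all tested. A class-0 fragment must be
A0; the parser rejects violations with the offending line number.

Group tests follow the pairing used in mycorrhization studies: a
Kruskal–Wallis omnibus test (tie-corrected, chi-square reference on k − 1 df;
delegated to scipy and validated against a hand-rank oracle) with a Fisher
LSD post hoc run on the rank-transformed data — pairwise t statistics on
group mean ranks using the pooled ANOVA-on-ranks mean squared error with
N − k degrees of freedom — at a significance threshold of 0.01. The rank-LSD
combination is the coherent nonparametric reading of "Kruskal–Wallis with
Fisher LSD post hoc"; published analyses rarely print the exact post-hoc
formulas, so this explicit definition is the contract here. Pairwise designs
use a pooled-variance Student t-test (threshold 0.05), with Welch's variant
behind a flag.

## Synthetic data

The generators exist to give every stage a ground truth. They emulate the
*statistical* structure of the real inputs, not their biology:

* **Genomes** — uniform ACGT background (motif counts are boundary-planted,
  so composition is irrelevant to them); genes laid left to right on one
  chromosome with 300 bp intergenic spacers; per-gene exon count, exon and
  intron lengths drawn from uniform ranges (defaults 2–8 exons of 80–300 bp,
  introns 60–400 bp, minimum 20 bp so planted boundary 2-mers never collide);
  strands drawn independently (default half minus). Each intron's boundary
  2-mers are overwritten according to a motif class sampled from the spec
  distribution; the default distribution (GT-AG 98.09%, GC-AG 0.52%, AT-AC
  0.01%, GA-AG 0.01%, Others 1.37%) mirrors a typical dicot annotation set.
  "Others" is realised as a uniformly random non-matching pair. The manifest
  records every intron's planted class and pair.
* **Reads** — a read is an (isoform, start) pair. Isoforms arise from
  independent per-intron Bernoulli retention at rate *r*; the pair is drawn
  uniformly over all start positions of all molecules weighted by isoform
  probability (implemented by rejection against the longest isoform). This
  length-weighted draw is what makes per-base depth uniform across isoforms —
  sampling the isoform first and the start second would overweight fully
  spliced (shorter) molecules at junctions and bias both estimators. Spliced
  reads carry N operations exactly matching the skipped introns; reads
  through a retained intron are pure M. Per-replicate read totals are the
  target depth times a multiplicative factor drawn uniformly from
  [1 − 0.15, 1 + 0.15], emulating library-size variation so cross-replicate
  s.d. columns are exercised (defaults: 100 bp reads, 50 reads/base, three
  replicates, matching a triplicate root RNA-seq design). No sequencing
  errors, quality scores, or fragment-length model: reads arrive "perfectly
  aligned", so passing tests validate the quantification logic, not alignment
  robustness.
* **Fragment scores** — i.i.d. colonization classes from a spec distribution,
  arbuscule classes independent of colonization class given colonization
  (class 0 forced to A0). The manifest stores the sampling probabilities and
  the plug-in index expectations they imply (e.g. E[M] = Σ p_c w(c)); per-plant
  index means match these within standard error in tests. Real root systems
  have spatially correlated colonization along the root; that correlation is
  deliberately absent, so the generator tests index arithmetic, not ecological
  variance structure.

All generators are deterministic given spec + seed, to the byte.

## Numerical and scale choices

* Percentage display rounds half-up to 2 decimals (decimal arithmetic, not
  binary floats), because half-even rounding disagrees with printed tables on
  boundary cases. Class percentages may sum to 100 ± 0.03 after rounding.
* Statistical tolerance in simulation tests is three binomial standard errors
  at the realised number of informative reads, plus a fixed 0.01 allowance
  for the coverage estimator (alignment-edge effects at molecule ends).
* Test simulations use a four-exon transcript and target its *middle* intron
  so both flanking exons are interior; the coverage-ratio estimator is only
  unbiased away from transcript ends (see above).
* `scripts/acceptance.py` simulates ~6 × 10⁵ reads (~5 × 10⁵ of them
  junction-informative) for its efficiency estimate. The implied efficiency,
  95.43%, lies 0.07 percentage points from the 95/96 integer-rounding
  boundary, so the standard error must be driven well below that gap for the
  rounded value to be stable; ~5 × 10⁵ informative reads put the boundary
  ≈ 2.5 standard errors away. The test suite uses ≥ 2,000 informative reads,
  which suffices for its 3-standard-error bands.
* Degenerate statistics are defined, not errors: all-identical data gives
  H = 0, p = 1 (Kruskal–Wallis) and t = 0, p = 1 (t-test with zero variance
  and equal means).

## Known limitations

* The coverage-ratio estimator conflates intron retention with any other
  source of intronic coverage (overlapping genes, unannotated exons); on real
  data the junction estimator is the safer cross-check.
* GFF3 parsing expects mRNA/exon(/CDS) features linked by Parent; GTF and
  splice-graph annotations are out of scope.
* Genome-wide motif counts of real species and published F/M/A/a values
  depend on specific annotation releases and unpublished raw scoring data;
  the package reproduces the *arithmetic* of those tables and validates the
  pipeline on synthetic ground truth instead.
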