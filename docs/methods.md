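# Methods

## The analysis

Given one deeply sequenced single-end RNA-seq library, the package
measures how transcriptome coverage and expression reliability depend on
sequencing depth by *in silico* subsampling:

1. **Filter.** Reads shorter than `min_length_bp` (default 17 bp) or
   containing more than `max_n_count` Ns (default 2) are removed before
   any analysis. A read failing both rules is counted once, under the
   length rule, so `n_input = n_removed_short + n_removed_n + n_retained`
   holds exactly. Filtering precedes subsampling: every depth ladder is
   drawn from the same filtered pool, so depths are comparable.
2. **Subsample.** For each target depth *k*, draw `n_replicates`
   (default 4) independent subsets of exactly *k* reads, uniformly
   without replacement. Replicates are independent draws from the full
   pool, not nested subsets; a consequence worth knowing is that
   detection counts are monotone in depth only in expectation, not
   necessarily per replicate.
3. **Quantify.** Assign reads to genes (below), compute
   `RPKM_g = 1e9·C_g/(N·L_g)`, and average RPKM per gene across the
   replicates of a depth. `N` counts assigned reads only — unassigned
   and ambiguous reads are excluded from the denominator.
4. **Report.** Detection counts/percentages per depth (detected means
   RPKM > 0, i.e. at least one assigned read — the simplest count-based
   convention); percentiles {5, 25, 50, 75, 95} of log2 RPKM over
   expressed genes (linear interpolation between order statistics);
   Pearson correlations of log2 RPKM between each depth and the
   full-depth reference, overall and within expression quartiles.

## Correlation conventions

Cross-depth correlations use log2 RPKM and exclude genes with zero
expression in either profile; log2 of zero is left undefined rather
than patched with a pseudocount, since those genes are excluded anyway.
Replicate–replicate correlations at one depth use raw RPKM with zeros
kept: the exclusion rule exists to keep undetected genes from dominating
cross-depth comparisons, and does not apply within a depth.

Quartiles (Q1 = bottom 25% … Q4 = top 25%) are computed on the
reference profile's expressed genes, ranked by RPKM ascending with ties
broken by gene id, and split into four contiguous blocks as equal as
integer division allows (remainders go to the lower quartiles). When a
lower depth is correlated against the reference, quartile membership is
fixed by the reference; this measures how well the reduced depth
recovers the reference's strata rather than re-stratifying each depth.
Pearson is the default correlation (Spearman available via
`depth_correlation(..., method="spearman")`).

Two correlations can be compared with Fisher's r-to-z test,
`z = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3))`, a conventional
choice for independent correlation comparisons.

## Subsampling algorithm

`reservoir_sample` implements Algorithm L: a single pass, O(k) memory,
each input item included with probability exactly k/N. Output order is
the reservoir order — arbitrary but fully determined by the seed. Seeds
for the (depth, replicate) grid are derived from one base seed by a
splitmix64 hash of (base_seed, depth, replicate), so every cell is an
independent reproducible stream with no dependence on evaluation order.

## Read-to-gene assignment

Mapping against a real genome is out of scope; reads are assigned by an
exact-match k-mer method adequate for the synthetic benchmark (and for
any data where reads are exact substrings of the transcript set):

* every 31-mer of every transcript is indexed (2-bit encoded in a
  sorted uint64 array; lookups are vectorized binary searches);
* per read, k-mers are sampled at stride ⌈len/3⌉ with the final valid
  position always included (≥ 2 seeds per read longer than k);
* the read is assigned to gene *g* iff the intersection of its k-mers'
  gene sets is exactly {g}; an empty intersection (including reads
  shorter than k, or all-N reads with no valid k-mer) leaves it
  unassigned; a larger intersection marks it ambiguous.

Ambiguous reads are discarded from counts and from `N`. This is the
simplest defensible multi-mapping policy; commercial mappers make other
choices, so absolute RPKM values are comparable within a run, not
across tools. With random transcript sequences, 31-mer collisions
between genes are vanishingly rare; the test suite measures ≥ 99.9%
agreement between k-mer assignment and the simulator's provenance tags
rather than assuming it.

Gene lengths come from a two-column TSV or from a GTF/GFF annotation,
where the length is the exon-union convention: bases covered by the
union of the gene's exon intervals, overlaps merged, strand ignored
(pyranges does the parsing and interval merging; tests check it against
an independent per-base bitmap).

## The synthetic-data generator

The generator emulates the statistical structure the analysis needs,
not any particular organism's sequence:

* **Universe**: `n_genes` genes (reference scale 15,000), i.i.d. uniform
  ACGT sequences with lengths uniform on 300–5000 bp. Uniform lengths
  are a simplification; real transcript lengths are right-skewed, but
  length enters the analysis only through the RPKM normalization.
* **Silent fraction** (default 0.10): genes with true abundance exactly
  0, so even exhaustive sequencing detects well under 100% of the
  annotation — matching the observation that a single tissue never
  expresses the whole genome.
* **Abundance**: log-normal over expressed genes, σ = 1.8 (location
  cancels under normalization). No public per-gene abundance table
  exists for the motivating tissue, so this is a modeling stand-in: a
  heavy-tailed profile spanning several orders of magnitude, wide
  enough that the four expression quartiles behave distinctly — which
  is the property the quartile analysis requires.
* **Read sampling**: source gene with probability ∝ abundance ×
  (L − readlen + 1) (the number of distinct fragment start positions,
  the fragment model implicit in RPKM — this makes estimated RPKM
  asymptotically proportional to true molarity), start position uniform.
  Read ids carry a `|gene…` provenance tag used only as a testing
  oracle.
* **Defects**: with probability 0.01 a read gets ≥ 3 interspersed Ns;
  with probability 0.01 it is truncated to 5–16 bp. Both rates are
  modeling choices (just enough to exercise both filters, ~2% combined
  loss, consistent with a high-quality run); both defect classes are
  removed by the default filter policy, so downstream reads are clean.
  No substitution errors are simulated: the assigner is exact-match,
  and error modeling is orthogonal to the depth question.
* Qualities are a constant placeholder (Phred 40); no positional or GC
  bias, no paired ends, no isoforms.

Because the generator's reads are error-free exact substrings, passing
tests demonstrate the pipeline's arithmetic, sampling and reporting are
correct — not that any particular real library saturates at a given
depth. On real data, mapping losses, sequencing error and annotation
quality shift the absolute curves; the qualitative shape (coverage
rarefaction; low quartiles degrading first) is driven by the
heavy-tailed abundance distribution, which real transcriptomes share.

## Reference problem sizes

The packaged scaled study uses 15,000 genes, 3 M simulated reads, four
1 M-read replicates for replicate consistency, and a depth ladder of
{0.1, 0.33, 0.5, 0.66, 1.0} × the filtered pool (fractions are taken of
the post-filter read count, since that pool is what the ladder samples
from). At this scale the minimum pairwise replicate RPKM correlation is
≈ 0.999, mean detected genes and the overall depth-vs-reference
correlation are non-decreasing in depth, and Q4 ≥ Q1 at every depth.
One-tenth-scale runs (as in `examples/config.yaml`) show the same
qualitative behavior and finish in seconds.

## Numerical and degenerate-input conventions

* RPKM conservation: Σ_g RPKM_g · L_g/1000 = 1e6 exactly whenever
  N = Σ counts; used as an internal consistency check in tests.
* Zero assigned reads → RPKM is undefined (error), not zero-filled.
* Correlation strata with fewer than 3 common expressed genes report
  r = NaN with their n; quartile assignment requires ≥ 4 expressed
  genes.
* `compare_correlations` requires |r| < 1 and n > 3 (atanh and the
  variance term are undefined otherwise).
* k = N subsampling returns a permutation of the input; k = 0 returns
  an empty set; k > N is an error naming both numbers.
* Determinism: a pipeline config plus its base seed reproduces every
  TSV byte-identically (floats are written with fixed formats).

## Known limitations

* The assigner requires reads to match transcripts exactly; it is not a
  substitute for a spliced aligner on real reads.
* Single-end reads only; no isoform-level quantification (gene-level
  exon-union lengths throughout).
* Detection is a hard ≥ 1-read threshold; at very shallow depths this
  makes coverage estimates optimistic relative to thresholded
  definitions (e.g. RPKM above a floor).
* The depth ladder's replicate averages reuse one deep library;
  subsampling captures sampling noise only, not library-preparation or
  flow-cell variation between true technical replicates.
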