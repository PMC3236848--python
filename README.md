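# seqsat

Sequencing-depth saturation analysis for bulk RNA-seq.

How many reads does a library need before sequencing deeper stops paying
off? `seqsat` answers this with the standard subsampling ("rarefaction")
design: starting from one deep single-end read set, it draws replicated
random subsamples of fixed sizes without replacement, quantifies per-gene
expression at every depth, and characterizes two saturation surfaces:

* **transcriptome coverage** — how many annotated genes are detected
  (≥ 1 assigned read) at each depth, and
* **measurement reliability** — how well expression at a reduced depth
  correlates with the full-depth measurement, overall and stratified by
  expression quartile (Q1 = bottom 25% of expressed genes … Q4 = top 25%).

The reliability stratification is the informative part: overall
correlations look reassuring even at shallow depth because they are
dominated by abundant transcripts, while the low-abundance quartiles
degrade much earlier. The package is aimed at people planning RNA-seq
experiments (how deep to sequence per sample) and at anyone who wants a
reproducible, scriptable implementation of the subsampling analysis.

## Model and definitions

Expression is quantified as RPKM (reads per kilobase of exon per million
mapped reads):

```
RPKM_g = 10^9 · C_g / (N · L_g)
```

with `C_g` the reads assigned to gene *g*, `N` the total assigned reads
in the read set, and `L_g` the gene's exon-union length in bp (bases
covered by the union of its exon intervals, overlaps merged). Expression
is log2-transformed for the depth comparisons; genes with zero
expression in either of the two compared profiles are excluded from
correlations, and quartile membership is fixed by the full-depth
reference profile.

A "technical replicate" at depth *k* is one uniform draw of *k* reads
without replacement from the deep read set (single-pass reservoir
sampling, Algorithm L, so inputs larger than memory stream through in
O(k) space). Four independent replicates per depth are drawn by default;
per-depth expression is the per-gene mean RPKM over replicates.

Reads are assigned to genes by a deterministic exact-match k-mer method
(31-mers sampled along the read; a read is assigned iff the intersection
of its k-mers' gene sets is a single gene). This replaces a read mapper
for the package's synthetic benchmark data; ambiguous reads are excluded
from both counts and the mapped total.

A built-in simulator generates the benchmark inputs: an annotated
transcriptome with a heavy-tailed (log-normal) abundance profile, a
configurable fraction of silent genes, and reads with occasional
interspersed Ns and sub-17 bp fragments to exercise the pre-mapping
filters (reads shorter than 17 bp or with more than 2 Ns are removed).

## Worked example

Run the packaged demo experiment — a 2,000-gene transcriptome, 200,000
simulated 75 bp reads, and a 20k/60k/120k subsampling ladder with four
replicates per depth:

```
seqsat run --config examples/config.yaml
```

The run directory (`seqsat_demo_run/`) contains the simulated truth
tables, per-replicate count and RPKM tables, and four TSV reports.
`reports/detection.tsv`:

```
sample  depth  n_detected  n_detected_min  n_detected_max  n_replicates  n_annotated  percent_detected
  demo  20000     1277.75            1265            1288             4         2000           63.8875
  demo  60000     1536.50            1532            1540             4         2000           76.8250
  demo 120000     1649.75            1641            1659             4         2000           82.4875
  demo 196105     1702.00            1702            1702             1         2000           85.1000
```

Coverage climbs steeply at first and flattens toward the full-depth
reference (196,105 reads survive filtering; 85.1% of the 2,000 genes are
ever detected — the rest are silent or too rare). `reports/correlation.tsv`
shows reliability against the full-depth profile:

```
sample  depth stratum        r  n_genes
  demo  20000 overall 0.967371     1566
  demo  20000      Q1 0.520557      305
  demo  20000      Q4 0.988771      425
  demo 120000 overall 0.995690     1698
  demo 120000      Q1 0.930745      422
  demo 120000      Q4 0.999393      425
```

At one tenth of full depth the overall correlation already looks high
(r = 0.97), but the bottom quartile sits at r = 0.52 — abundant genes
saturate long before rare ones. Replicate agreement
(`reports/replicate_correlation.tsv`) exceeds r = 0.98 at every depth,
confirming the subsampling itself adds little noise.

The same stages are available individually (`seqsat simulate`,
`filter`, `sample`, `quantify`, `saturate`; see `--help`) and as library
functions (`seqsat.subsample_reads`, `seqsat.compute_rpkm`,
`seqsat.depth_correlation`, …).

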