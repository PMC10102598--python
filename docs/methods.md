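# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices behind `barseqfit`.

## Data model

A screen consists of four tables. The **gene table** gives, per gene, a
replicon, 1-based inclusive coordinates, strand, GC fraction and the
number of non-repetitive nucleotides (all coordinates stay 1-based
inclusive throughout the package; no internal conversion is performed, so
the central-window arithmetic has a single convention). The **pool
table** maps each barcode to an insertion position and its Tn-seq read
count; gene assignment and the within-gene fraction
`(pos − begin + 1)/(end − begin + 1)` are derived from the genome at
analysis time, always in the + coordinate direction regardless of gene
strand — the central-insertion rule is positional, and one convention
keeps every oracle simple. The **counts table** is barcode × sample
non-negative integers, and the **experiment design** assigns samples to
Time0 groups and conditions. Replicon lengths and the main-chromosome
flag travel in an optional `replicons.tsv` sidecar; when absent they are
inferred from gene extents, with the gene-richest replicon taken as the
main chromosome.

## Essentiality calling

Only genes with ≥ 100 non-repetitive nt are analyzable. For each
analyzable gene we count distinct central insertion positions (fraction
in [0.1, 0.9], strand ignored when deduplicating) and their summed
Tn-seq reads, then form

* `dens` — positions per non-repetitive nucleotide, divided by the
  median over analyzable genes (median 1 by construction);
* `normreads` — reads per kb of non-repetitive sequence, GC-corrected,
  again median-scaled to 1.

GC correction bins analyzable genes by GC fraction in bins of width
0.05 and divides each gene's reads/kb by its bin median; bins with fewer
than 10 genes fall back to the global median. This is robust,
assumption-light and exactly reproducible. The density denominator is
the gene's total non-repetitive length, not the central-region length —
a recorded convention, since either reading is defensible. Median
scaling uses only analyzable genes with the standard even-count median.
A library whose median raw density is 0 is degenerate: statistics are
returned as NA with a warning, and the caller refuses to classify.

A gene is **essential** when `dens < 0.2`, `normreads < 0.2` and no
fitness could be measured for it (mutant abundance at Time0 too low);
**nearly essential** when exactly one statistic is below 0.2, or both are
but fitness was measurable; otherwise **dispensable**. A separate
dispensability check works directly from (position, reads) pairs:
central positions with more than one read are counted, and a gene with
≥ 10 qualifying positions carrying ≥ 100 total reads is dispensable for
viability (single-read positions are ignored as likely mapping
artifacts).

## Fitness estimation

Per condition sample, the Time0 samples of its group are summed into one
reference vector. With pseudocount `ps = 1` on every count (symmetric
and testable; configurable), strain fitness is

    r_s = log2((n_cond + ps)/D_cond) − log2((n_t0 + ps)/D_t0),

where `D = Σ counts + ps·n_strains` for each side. The strain weight is
the inverse of the count-based variance
`v_s = (1/(n_cond + ps) + 1/(n_t0 + ps))/(ln 2)²`. Strains are usable
when central (10–90%) and `n_t0 ≥ 3`; a gene acquires fitness when its
usable strains carry ≥ 30 summed Time0 reads. These explicit cutoffs
implement the usual "insufficient abundance at Time0" NA behaviour;
missing values are encoded as NA, never 0, and the t matrix shares the
same NA mask.

**Positional normalization.** Actively replicating cells over-represent
origin-proximal sequence, which shifts raw log ratios along the
chromosome. For replicons with ≥ 100 genes we subtract a centered
running median of width 251 genes (windows truncated at replicon ends);
smaller replicons (e.g. a plasmid) are centered on their plain median.
Finally the mode of the main-chromosome values — estimated with a
Gaussian KDE (Silverman bandwidth) evaluated on a grid of step 0.01
aligned to multiples of 0.01 and padded 0.5 beyond the data range, ties
resolved toward 0 — is subtracted from **all** genes, so plasmid genes
are calibrated against the chromosomal mode. The aligned grid makes the
normalization exactly antisymmetric under swapping condition and Time0
roles, a property the tests assert.

**Significance.** `t = f / sqrt(σ0² + max(Vcount, Vspread))` with
`Vcount = 1/Σw`, `Vspread` the weighted sample variance of strain ratios
about the gene mean divided by the strain count (undefined for
single-strain genes, which then use `Vcount` alone), and a variance
floor `σ0 = 0.1` in log2 units so that no measurement becomes
arbitrarily significant on counting statistics alone. This variance
model is this package's explicit contract.

**Quality control.** Per experiment: `gmed`, the median summed Time0
reads over genes with fitness (≥ 50 to pass); `cor12` and `mad12`, the
Pearson correlation and median absolute difference of gene fitness
recomputed independently from insertions in the first half
([0.1, 0.5)) versus second half ([0.5, 0.9]) of each gene (each half
normalized like the full estimate, with a halved Time0-abundance
threshold; pass at `cor12 ≥ 0.5`, `mad12 ≤ 0.5`). These thresholds are
package defaults, not literature claims. Failing experiments are flagged
but still reported.

## Phenotype analytics

* **Significant phenotype:** `|f| > 0.5` and `|t| > 4` per
  (gene, experiment); the per-gene summary counts genes significant in
  at least one experiment.
* **Empirical FDR:** Time0-vs-Time0 null comparisons are built
  leave-one-out — each Time0 sample in a group with ≥ 2 Time0 samples is
  compared against the sum of the others. With `n_fp` genes significant
  in any of `n_null` such comparisons, the expected false-positive count
  among `n_cond` condition experiments is
  `round(n_fp · n_cond / n_null)` (nearest integer, computed in exact
  integer arithmetic) and the FDR divides by the number of genes with a
  significant phenotype.
* **Specific phenotype:** `|f| > 1`, `|t| > 5`, `|f| < 1` in ≥ 95% of
  the gene's measured experiments, and `|f|` above the gene's 95th
  percentile of `|f|` plus 0.5. The percentile uses linear interpolation
  between order statistics; "95% of experiments" counts non-NA entries
  only, and genes with < 20 measured experiments are skipped (too few
  values for a stable percentile).
* **Cofitness:** Pearson correlation over each pair's shared non-NA
  experiments (pairwise-complete), suppressed below
  `min(50, n_experiments)` shared experiments or when a member has zero
  variance; `r ≥ 0.8` marks high cofitness, and each gene's best partner
  is reported.

## Synthetic data

The generator emulates the study conditions of a large sulfate-reducer
screen so every stage is testable against ground truth:

* **Genome:** two replicons (main chromosome + plasmid, ~6% of genes on
  the plasmid), gamma-distributed gene lengths (mean ≈ 950 nt, minimum
  200 nt), exponential intergenic gaps, per-gene GC following an AR(1)
  walk around 0.63 (positional autocorrelation, as in real genomes), 1%
  of genes with reduced non-repetitive length, and a configurable
  fraction (default 12%) of genes flagged essential —
  `round(fraction × n_genes)` exactly.
* **Pool:** insertion positions uniform over the summed replicon
  lengths; draws landing centrally in an essential gene are rejected and
  redrawn, except with a configurable leakage probability (default 0)
  modelling rare escapers, which are retained at 1% of their drawn
  abundance. Barcodes are unique random 20-nt ACGT strings
  (collision-checked); Tn-seq reads are negative binomial (mean 20).
  At the default scale used in the recovery tests (3,400 genes, 80,000
  strains) the median non-essential gene carries ~16 usable strains,
  matching the ~15 of the real library.
* **Counts:** initial strain abundances are log-normal (σ = 1,
  normalized to sum 1) — pooled libraries are strongly uneven, and the
  heavy tail stresses the inverse-variance weighting — drawn once per
  Time0 group and shared by its samples. A condition sample multiplies
  each disrupted strain's abundance by `2^f_true(gene, condition)`
  (intergenic and non-central strains use 0), then draws counts
  multinomially at the requested depth; a Dirichlet-multinomial option
  adds overdispersion. `f_true` is defined as the expected final
  normalized log2 ratio, not a per-doubling rate, so the doublings
  parameter (default 5, the midpoint of a typical 4–6-doubling assay)
  only scales an optional within-experiment drift term (default off).
  Every stochastic function takes an explicit integer seed; there is no
  global random state.

Planting helpers define the truth: condition-wide effects uniform on
[−3, 1] for a random 20% of genes (parameter-recovery tests),
co-regulated modules sharing a per-condition N(0, 1.5²) signal plus
N(0, 0.3²) gene-level noise (cofitness tests), and condition-specific
effects of magnitude 2 (specificity tests). True effects are clipped to
|f_true| ≤ 4.

**What the generator does not emulate:** raw reads (FASTQ), barcode
sequencing errors, PCR chimeras, positional insertion bias, genuine
copy-number gradients (the normalization is exercised with planted
gradients instead), batch effects between Time0 groups, and
growth-condition-dependent depth variation. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

The recovery suites run at three scales chosen to mirror the study while
remaining desk-sized: 3,400 genes / 80,000 strains / 21 Time0 samples at
depth 10⁶ for null calibration, essentiality and parameter recovery;
1,200 genes / 30,000 strains / 32 conditions for module and specificity
recovery; 200 genes / 5,000 strains for unit-level checks. Degenerate
inputs fail loudly: empty genomes, negative depths, unknown conditions,
zero-read samples, and conditions without a Time0 group all raise
validation errors, and CLI exit codes distinguish validation failures
(1) from internal errors (2). Weighted-variance terms are clipped at 0
before division to absorb floating-point cancellation; running-median
windows must be odd.

## Known limitations

* The t statistic's variance model is a package contract; other
  RB-TnSeq pipelines use related but not identical estimators, so t
  values are comparable within a run, not across tools.
* Essentiality inherits the insertion model's assumption of roughly
  uniform insertion pressure; strong regional insertion bias would
  inflate false calls and is not corrected beyond GC.
* Cofitness on few experiments is noisy; the overlap floor guards
  against unstable correlations but cannot make 20 experiments behave
  like 700.
* The pairwise-complete cofitness matrix is O(genes²) memory per block;
  the blocked implementation keeps this modest but very large genomes
  (> 10⁴ genes) may warrant a sparse reporting floor above 0.8.
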