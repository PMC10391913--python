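# Methods

`divscan` implements the inference chain used in two-population livestock
resequencing studies: hard site filtering, windowed divergence scanning
with joint top-quantile sweep calling, allele-sharing phylogenies, LD
decay summaries, mixed-model association, and integration with external
expression evidence. This note records the statistical definitions, the
defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate.

## Site filtering

Sites are biallelic SNPs with diploid dosages in {0, 1, 2, missing}.
The filters are strict inequalities, read literally from the usual
reporting convention:

* missing fraction < `max_missing_frac` (default 0.10),
* minor allele frequency > `min_maf` (default 0.05), computed over
  non-missing calls,
* optionally, genotypes supported by fewer than `min_depth` (default 2)
  reads are set to missing when the VCF carries FORMAT/DP. Depth
  filtering conceptually belongs to variant calling, upstream of this
  package's entry point, so VCFs without DP are simply unaffected.

Boundary sites (exactly 10% missing, MAF exactly 0.05) are removed.
Half-calls (`0/.`) are treated as missing — VCF dialects disagree and the
conservative reading costs little. Phased (`|`) and unphased (`/`)
separators are equivalent because every downstream statistic is
dosage-based. Internally all intervals are 0-based half-open; VCF
positions stay 1-based at the I/O boundary.

## Windowed diversity and divergence

Windows are fixed-width (default 5 kb) and non-overlapping by default;
a smaller step is supported but must divide the window size. Per window:

* **pi** per population: sum over variant sites of the unbiased per-site
  heterozygosity `2 p (1-p) n/(n-1)` (`n` = non-missing chromosomes),
  divided by the *window length in bp*. Monomorphic positions therefore
  contribute zero, matching the per-bp windowed pi of standard VCF
  tooling.
* **FST**: Weir & Cockerham (1984) two-population variance components
  `a` (among populations), `b` (among individuals within populations),
  `c` (within individuals), combined per window as the ratio of sums
  `sum(a) / sum(a+b+c)` — the weighted windowed estimator. Negative
  window estimates are reported unclipped; clipping is presentation, not
  estimation. Sites where either population has fewer than two genotyped
  diploids are excluded and counted.
* **log2 pi ratio** in a configurable direction (A/B or B/A). Windows
  where either pi is zero are marked unusable rather than given an
  infinite ratio.

A window needs at least `min_sites` (default 3) usable sites to be
ranked. Without this, near-empty windows with one extreme site dominate
the upper tail artifactually.

## Sweep calling

The flagging rule is the *intersection* of the marginal top-q sets
(default q = 0.05) of windowed FST and of the log2 pi ratio — the "red
corner" of the joint distribution — not their union, which would double
the nominal call rate. The threshold is the k-th largest value with
k = ceil(qN): with all-distinct values each marginal set has exactly k
members; ties at the threshold are included. Flagged windows within
`gap` bp (default 0, i.e. abutting) merge into regions whose summary
statistics are maxima over members. A gene is assigned to a region iff
their half-open intervals share at least 1 bp; the candidate (PSG) list
is the deduplicated union over regions. Scans are run once per ratio
direction, producing separate A-over-B and B-over-A candidate lists.

## Allele-sharing distance and neighbor joining

The distance between individuals i and j is the mean over shared
genotyped sites of a per-site contribution: 0 for identical homozygotes,
0.5 for homozygote-vs-heterozygote and for two heterozygotes, 1 for
opposite homozygotes. These four cases are reproduced exactly by the
expected allele difference `p_i(1-p_j) + p_j(1-p_i)` with `p = dosage/2`,
which is the extension implemented (a heterozygote is at 0.5 even from an
identical heterozygote; the self-distance of an individual is defined as
0). The normalizer L is the count of pairwise-complete SNP sites, not a
bp span: the formula averages per-site contributions, and a per-site mean
stays comparable across pairs with different missingness.

Trees are Saitou-Nei neighbor joining, deterministic given the matrix
(ties in the Q criterion break to the lowest index pair). Negative branch
lengths are clamped to zero with the deficit moved to the sibling branch
(pair distance preserved); raw lengths are available for oracle tests.
Bootstrap resamples SNP sites (columns) with replacement, the standard
phylogenetic bootstrap; support counts the replicates containing each
internal bipartition of the original tree. The default 1000 replicates
follows common practice; recovery tests use 200 to keep runtimes short,
which does not change the support *fraction* being tested.

## LD decay

r2 between two sites is the squared Pearson correlation of dosage
vectors over pairwise-complete samples (composite/Rogers-Huff LD). This
needs no phasing and coincides with haplotype r2 under HWE. All
intra-chromosomal pairs up to `max_dist` are binned by separation
(half-open uniform bins); per-bin pair caps with seeded uniform
subsampling keep large panels tractable. The linkage-range summary
follows the half-maximum convention: `half_max = r2_max / 2` exactly, and
the linkage distance is the midpoint of the first bin whose mean r2 has
dropped to half_max or below — a discrete first-crossing readout, no
interpolation. `fit_decay_length` fits `A exp(-2d/L) + c` to the binned
means: under the generator's first-order copy model the *correlation*
decays as `exp(-d/L)`, so r2 decays at twice the rate and the fitted L
estimates the correlation length itself.

## Mixed-model GWAS

Per SNP, `y = X a + g b + u + e` with `u ~ N(0, sg2 K)` and
`e ~ N(0, se2 I)`. K is the centered-genotype relationship matrix
`(1/m) sum (x-xbar)(x-xbar)^T` over polymorphic sites with per-site mean
imputation of missing calls. The fixed effects default to an intercept
plus the top 2 eigenvectors of K (sign-fixed for determinism); a
categorical population indicator can be passed instead. The variance
ratio `lambda = se2/sg2` is REML-estimated once on the null model — a
single eigendecomposition of K, an 81-point grid in log lambda over
[1e-5, 1e5], and a bounded 1-D refinement — then fixed for all SNP tests
(the EMMAX approximation; exact per-SNP restimation is available behind a
flag for cross-checks on small panels and changes little at these sample
sizes). Each SNP is tested by GLS under `sg2 (K + lambda I)` with a
two-sided Wald chi-square(1) test; the residual variance uses n - p - 1
degrees of freedom so that with K = I the p-values coincide with OLS.
Missing phenotypes drop the sample (kinship is subset accordingly);
missing genotypes at a tested SNP are mean-imputed so one kinship matrix
serves all SNPs. Significance is `-log10(p) > 4`, strict, as printed; no
FDR layer is added beyond it.

## Expression integration

Differential-expression tables are consumed, never computed: the
upstream count-model fitting belongs to dedicated RNA-seq tooling. The
genome-wide call is `|log2FC| >= 2` (inclusive) and `p < 0.01` (strict);
the candidate-gene check relaxes to `>= 1` and `< 0.05`. Candidates
absent from the table are reported as "not assayed", not errors. The
evidence table is the outer union of gene identifiers across sweep lists
(both directions), per-trait GWAS hit genes and DEG calls, with boolean
flags, in deterministic lexicographic order.

## Synthetic data

The generator emulates the study design rather than full coalescent
realism:

* **Design**: two populations of 32 diploids each by default.
* **Frequencies**: ancestral p ~ U(0.05, 0.95); population frequencies
  Balding-Nichols `Beta(p(1-F)/F, (1-p)(1-F)/F)`. F is exactly the
  parameter the Weir-Cockerham estimator targets, which makes recovery
  tests sharp — this is why Balding-Nichols was preferred over a
  coalescent simulator.
* **Sweeps**: inside a planted region both populations draw at an
  elevated `F_local`; the target population's frequency is then moved
  toward the nearer boundary so its per-site heterozygosity is divided
  *exactly* by the configured factor (solving `q'(1-q') = q(1-q)/factor`
  on the same side of 0.5).
* **LD**: each haplotype carries a latent uniform quantile that persists
  between consecutive sites with probability `exp(-d/L)` (default
  L = 20 kb, the order of magnitude reported for livestock panels),
  giving approximately exponential r2 decay. First-order copying is
  deliberately simpler than recombination graphs; it produces the decay
  curve the LD module needs without an ancestral-process simulator.
* **Phenotypes**: causal dosage effects plus a polygenic term with
  covariance proportional to the realized kinship (variance fraction
  `h2_background`) plus Gaussian noise. When `causal_var_frac` is set the
  scales are chosen so the causal component explains exactly that
  fraction of variance.
* **Defaults**: one 1-Mb chromosome at 0.006 SNPs/bp (the genome-wide
  SNP density of a deep goat resequencing panel), giving 200 windows of
  5 kb — large enough for stable tail quantiles, small enough for
  second-scale tests.

What the simulations do **not** emulate: genealogical correlation
between sites beyond first-order copying, mutation-model detail,
genotyping error, reference bias, or selection acting through time.
Passing recovery tests therefore demonstrates estimator correctness under
the stated frequency model, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

* Quantile thresholds are order statistics (no interpolation), so tie
  handling is explicit and reproducible.
* FST windows with no usable site, and ratio windows with zero pi, are
  missing/unusable and excluded from ranking, never coerced to 0 or inf.
* NJ tie-breaks are index-ordered; eigenvector signs are fixed by the
  largest-magnitude entry; all stochastic steps take explicit seeds —
  the full pipeline is byte-reproducible for a fixed seed.
* Kinship eigenvalues are clipped at 0 before REML; p-values are floored
  at the smallest positive float before taking logs.
* Test problem sizes (200 windows, 200 bootstrap replicates, n <= 500
  cohorts) were chosen as the smallest sizes at which the tested
  quantities are stable; all are configurable upward.

## Known limitations

* The Wald test with a fixed variance ratio is slightly anticonservative
  at small n (visible but within band in the calibration tests); exact
  per-SNP REML narrows this at a large runtime cost.
* Composite r2 understates haplotype r2 when HWE fails within
  populations.
* The sweep caller's intersection rule has no significance calibration —
  it is an outlier scan, as in the source methodology.
* Windowed pi uses the window length as denominator, so windows
  truncated at a chromosome end are mildly deflated.
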