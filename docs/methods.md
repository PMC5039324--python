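# Methods

This note documents the models behind each stage of the toolkit, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical and design decisions that were
genuinely open.

## Study design

The emulated experiment keeps replicate populations ("lineages") at 400,
900 and 1550 uatm pCO2 for two generations and reciprocally transplants the
adults, yielding seven (origin → destination) treatments — 400→400,
900→900, 1550→1550, 400→900, 400→1550, 900→400, 1550→400 — in two
replicates: fourteen pooled samples, pool sizes drawn uniformly from 28–76
individuals. Each sample is a pool, not an individual: expression counts
and allele counts are population-level measurements.

## Expression preprocessing

*Isoform collapsing.* Contigs sharing an assembly component **and** an
annotation string are summed into one "Unigene" row (same component with
different annotations stays split). Column sums are conserved exactly; the
Unigene id is the component id plus a short digest of the annotation.

*Scale normalization.* The median-of-ratios estimator: for each gene with
strictly positive counts everywhere, form the ratio of each sample's count
to the gene's geometric mean (computed in log space); a sample's size
factor is the median ratio. Genes containing a zero are excluded from the
pseudo-reference. No post-hoc rescaling is applied, so re-estimated factors
after normalization equal the geometric mean of the original factors,
which is ≈ 1 but not exactly 1.

*Gene filters.* After normalization a gene is excluded iff its sample
standard deviation (n−1 denominator — a convention choice, the source
procedure does not specify the denominator) exceeds its mean, or any sample
has a zero count. A variance-vs-mean variant of the noise rule is available
behind a flag (`use_variance=True`) because the procedure is described both
ways in the literature this follows; the SD reading is the default. The
filter is idempotent.

## ANCOVA hypothesis screen

Analysis scale defaults to log2(normalized count + 1); the linear model
is fit per line pair with group coding g = ∓½ (see README for the model).
Coding ±½ makes b₂ directly the between-line difference at the covariate
midpoint, which is how "elevation" is defined here. Elevation is tested in
the full-interaction model (not the classical sequential common-slope
ANCOVA); the covariate is centered so the two tests are orthogonal under
the balanced design.

Classification (alpha = 0.05, ties at p = alpha count as significant):

1. *precondition* — the 400-origin line over destinations {400, 900}
   versus the 900-origin line must show **no** significant slope or
   elevation difference (pure plasticity at the moderate level);
2. on the 400-origin versus 1550-origin pair over destinations {400, 1550}:
   slope only → H1, elevation only → H2, both → H3, neither → none.

With two replicates per treatment each pair fit has 8 points and 4 residual
df. **No multiple-testing correction is applied across genes** — the screen
is a hypothesis-mining device, not a FWER-controlled discovery procedure;
downstream enrichment operates on the resulting lists.

Shapiro–Wilk normality p-values of the pooled residuals are reported as a
diagnostic column only; they do not gate the classification.

Degenerate fits (zero residual variance) report p = 0 for nonzero contrasts
and p = 1 for zero contrasts and are flagged. Each pair requires at least
one residual df; fewer raises an error.

### Power under the two-replicate design

The attainable sensitivity of the screen is fixed by the design, not the
implementation. For a planted between-line separation of 3 residual SDs the
t noncentrality is 3·√2 ≈ 4.24 at 4 df, giving per-contrast power 0.880;
the plasticity precondition, being a conjunction of two null tests at
alpha = 0.05, passes with probability ≈ 0.91. Hence per-class sensitivity
is bounded near 0.91 × 0.88 × 0.95 ≈ 0.76 for H1/H2 and 0.91 × 0.88² ≈ 0.70
for H3. The measured values (≈ 0.73–0.76 and ≈ 0.70) sit at this bound;
cross-misclassification between H1 and H2 is far below 1%.

## Co-expression pattern filter

All eight inequalities are strict; exact ties fail. The decision is
invariant under any strictly increasing transform of the means, so the
analysis scale is immaterial. Two of the eight rules (400→400 > 1550→400
and 400→1550 > 1550→1550) are transitive consequences of the others, so no
real-valued mean vector can violate either of them alone; the test suite
verifies the six independent rules with single-violation fixtures and the
two redundant rules with minimal (two-rule) violations. Under an
exchangeable null the match probability is exactly 18/5040 ≈ 0.00357
(rank-order enumeration), which the Monte-Carlo rate reproduces.

## Pool-seq CMH scan

*Biallelic calling.* The two alleles with the highest summed counts over
the used pools are retained (N and deletion columns never qualify; ties
break toward sync column order). A site is testable iff every used pool has
coverage ≥ `min_coverage` (default 10) at the two alleles and the global
minor-allele count is ≥ `min_minor_count` (default 2). The thresholds are
design choices in the spirit of standard pool-seq pipelines; both are
flags and are recorded in the scan parameters.

*Statistic.* Classic CMH without continuity correction by default (a
correction flag exists); strata with any zero margin are excluded. For a
single stratum the statistic equals (n−1)/n times the Pearson chi-square,
which the tests verify to 1e-10 together with a statsmodels cross-check.

*Multiplicity.* Bonferroni with denominator = the number of testable sites
in *this* run (reproducibility of the artifact's own decisions, rather than
any fixed historical site count). The 900-uatm pools are read and carried
but excluded from the strata. Default pairing is replicate-wise:
(400A, 1550A), (400B, 1550B), (400→1550A, 1550→400A), (400→1550B,
1550→400B) — transplants count as replicates of their origin lineage, on
the assumption that allele frequencies do not change over the short
transplant period. Arbitrary pairings are injectable.

## GO enrichment

Flat gene → term map; any GO-DAG ancestor propagation must be applied to
the map beforehand (the structure-aware step is delegated, as when using an
external enrichment service). Unannotated universe genes count toward the
universe size. Terms with zero list hits are excluded from the FDR family.
Benjamini–Yekutieli is the default adjustment — the literal reading of
"FDR under dependency" for overlapping terms — with Benjamini–Hochberg as
an option. Recommended universes: all genes surviving the expression
filters for expression-derived lists; all contigs with ≥ 1 tested SNP for
CMH-derived lists.

## Synthetic-data generator

*Expression.* Per-gene baselines are Normal on the log2 scale (defaults:
mean 5.5, SD 2.5, spanning the observed range from tens to thousands of
counts); treatment effects are added on the log2 scale and counts drawn
negative-binomial with a shared dispersion (size k = 20; variance
mu + mu²/k). The within-treatment biological variance is not known from the
emulated study, so it is exposed through `nb_dispersion` rather than fixed.
Planted structure:

* **H1** — only the 1550-origin reaction norm's slope changes, pivoted at
  the 975-uatm midpoint so elevation is untouched; `effect_h1_log2fc` is
  the endpoint-to-endpoint swing.
* **H2** — the whole 1550-origin line shifts by `effect_h2_log2fc`
  (default −0.42 log2 units with per-gene SD 0.2, matching the reported
  scale of the helicase down-regulation).
* **H3** — both.
* **pattern** — fixed treatment offsets satisfying all eight inequalities
  exactly in expectation, scaled to `effect_pattern_log2`.

Planted fractions default to 0.024 / 0.024 / 0.001 / 0.012 so the class
sizes at the default 28 879 genes are on the scale of the original
discovery counts. `effect_sign_alternate=True` alternates the sign of
planted effects gene by gene; without it a large one-directional planted
fraction leaks into the size factors (the median-of-ratios reference
absorbs part of the signal), which is itself a useful, realistic failure
mode but not what a recovery benchmark wants. Per-sample depth factors are
log-uniform in [0.5, 2] so size-factor estimation is non-trivial. Genes are
emitted as 1–3 isoform contigs (multinomial split) plus a matching
annotation table so the collapsing step is exercised end to end.

*Pooled SNPs.* Each origin lineage carries a per-site alternate-allele
frequency (base frequencies uniform on [0.05, 0.95]); "selected" sites add
`delta_f` (default 0.3) to both 1550-uatm lineages consistently, null sites
are identical across lineages. Transplant pools inherit their origin
lineage's frequency. Read depth is fixed at `coverage` per pool and site
(default 50); alternate reads are Binomial(coverage, pool frequency).
Under the default `fixed_lineage_freq` model the pool frequency is the
lineage frequency, and the CMH chi-square tail is well calibrated (measured
family-wise error after Bonferroni ≈ 0.02–0.08 at nominal 0.05). The
`individuals_then_reads` model first resamples the pool frequency as
Binomial(2N, f)/2N for a pool of N individuals, adding the classic
pool-seq variance term — total read-frequency variance
p(1−p)(1/(2N) + (1 − 1/(2N))/C), verified by simulation. That model is the
realistic one for finite pools, and it makes the read-level CMH test
anti-conservative by the variance-inflation factor 1 + (C−1)/(2N) (≈ 1.49
at C = N = 50, inflating the far tail by orders of magnitude); it is
therefore *not* the default for calibration benchmarks, and users testing
real pool-seq data should be aware that the same inflation affects real
experiments. Sites are grouped 5 per contig; output is biallelic by
construction (reference in the A column, alternate in T).

*GO annotations.* Background terms are assigned independently per gene
(default probability 0.05 per term); one planted term's probability is
multiplied by an enrichment factor inside a chosen subset.

All generators consume one integer seed and are bit-reproducible; truth
labels partition genes/sites and are allocated deterministically (largest
remainder, within one gene of the requested fraction).

## Pipeline and problem sizes

`run_all` executes simulate → prep → ANCOVA scan → pattern scan → CMH scan
→ enrichment of the recovered H2 list, writing plain TSV intermediates, a
manifest (parameters, versions, derived seeds, SHA-256 checksums) and a
log. Reruns with the same seed are checksum-identical. The default
configuration (28 879 genes, 20 000 sites) completes in seconds on one CPU.

The acceptance script and test suite use desk-scale problem sizes chosen
for stable statistics: 3 000 genes (600/600/120 planted per class) for
recovery, 5 000 genes for null calibration, 10 000 sites × 100–200
replicate experiments for CMH error control, 10⁵ draws for the pattern
null rate. These sizes are the package's own benchmarking choices.

## Known limitations

* The generator plants piecewise-constant treatment effects with a shared
  NB dispersion; real data have per-gene dispersions, batch structure and
  correlated genes, so passing recovery benchmarks here does not certify
  power on real data — only correctness of the decision logic and
  calibration under the stated model.
* The ANCOVA screen inherits the design's 4 residual df; its sensitivity
  ceiling (see power section) is a property of two-replicate reciprocal
  transplants generally.
* Normality is diagnosed, not enforced; with counts this low-df t test is
  only approximate, though the null p-value distribution is
  indistinguishable from uniform at the simulated depths.
* No mixed-effects/tank-effect modelling, no Fst or sliding-window SNP
  statistics, no GO-DAG handling, no raw-read processing.
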