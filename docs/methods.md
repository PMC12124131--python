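# Methods

`rvcollapse` implements a rare-variant case-control analysis pipeline of the
kind used in biobank-scale gene discovery: variant- and genotype-level
quality control, qualifying-variant (QV) collapsing models, exact gene- and
variant-level association statistics, stratified exact meta-analysis,
permutation-based inflation estimation, Firth-penalised sensitivity and
survival models, and a power analysis for rare carrier effects. A synthetic
cohort generator provides the statistical structure these analyses assume,
so the whole pipeline is testable without access-controlled cohort data.

## Statistical model

### Collapsing tests

For a gene g and a QV model m, every participant is classified as a carrier
or non-carrier. Under the dominant architecture a carrier holds at least one
qualifying allele in g; under the recessive architecture a carrier is
homozygous-alt at a qualifying site, hemizygous on X, or heterozygous at two
or more distinct qualifying sites (putative compound heterozygote — phase is
not resolved, so two heterozygous calls in the same gene are treated as
trans). The resulting carrier-by-status 2×2 table
(a = case carriers, b = case non-carriers, c = control carriers,
d = control non-carriers) is tested with a two-sided Fisher exact test using
the point-probability criterion: all tables with the observed margins whose
conditional hypergeometric probability is at most the observed table's
probability times (1 + 1e-7) contribute to p. This is the convention of the
standard R implementation and reproduces the published worked-example
p-values to printed precision. Probability sums run in log space
(`scipy.stats.hypergeom.logpmf` + log-sum-exp) so 2×10⁵-control tables do
not underflow.

Effect sizes are sample odds ratios ad/bc with a 95% Woolf interval,
exp(ln OR ± 1.95996·√(1/a + 1/b + 1/c + 1/d)). When any cell is zero, all
four cells are incremented by one (Haldane–Anscombe) before computing the
OR and interval, and the result carries a `corrected` flag; p-values are
always computed on the uncorrected table. The interval reported for a
corrected table is a flagged convenience, not a Woolf CI, and is excluded
from the validation checks (no published method is available to match for
that case).

### Exact stratified CMH

Combining K cohorts conditions on every stratum's margins: each aᵢ is then
an independent central hypergeometric variable and the statistic S = Σaᵢ has
the convolution of those K distributions as its null. The convolution is
computed by dynamic programming in log space (supports are tiny for rare
carriers, so this is exact and fast at any cohort size). Two-sided p uses
the same point-probability rule as the Fisher test; a twice-the-smaller-tail
rule is available behind a flag. The common odds ratio is Mantel–Haenszel,
R/S with R = Σaᵢdᵢ/nᵢ and S = Σbᵢcᵢ/nᵢ, with a Robins–Breslow–Greenland
variance for its CI; both are cross-checked against
`statsmodels.stats.contingency_tables.StratifiedTable` in the tests, while
the exact p agrees with R's `mantelhaen.test(exact = TRUE)` to nine digits
on the worked example. Strata with an empty margin carry no conditional
information and are dropped with a warning.

### Genomic inflation

λ_GC is the ratio of the median χ²₁ quantile of observed unit p-values to
the median quantile of an empirical null obtained by re-running the entire
analysis once with permuted case-control labels (an "n-of-1" permutation);
p = 1 maps to quantile 0. The empirical null, rather than U(0,1), is the
correct reference because exact p-values on discrete tables are
conservative: they carry an atom at p = 1 whose mass is approximately the
modal hypergeometric probability, ≈ 1/(σ√2π) at carrier-count standard
deviation σ. Calibration checks therefore compare observed p-values to the
permutation null (two-sample Kolmogorov–Smirnov) instead of testing
one-sample uniformity, and additionally verify that the fraction of p<0.05
never exceeds the nominal level.

### Firth-penalised models

The sensitivity analysis re-tests a carrier effect with logistic regression
adjusted for sex, age, ancestry principal components 1–4, and exome-wide PTV
burden (the number of genes in which a participant carries at least one
qualifying PTV). Because separated designs are routine at these carrier
counts, the likelihood is penalised with Jeffreys' prior:
ℓ*(β) = ℓ(β) + ½log|I(β)|. The maximiser iterates Newton steps on the
hat-matrix-modified score U* = X′(y − p + h(½ − p)) with step-halving on
penalised-likelihood decrease; convergence at max|U*| < 1e-8 or 25
iterations. Per-term p-values are penalised likelihood-ratio tests with the
term constrained to zero and the penalty still computed from the full-model
information; confidence bounds come from the profile penalised likelihood,
bracketed geometrically and solved by Brent bisection at the χ²₁ 0.95 point.

The same penalty applies to the Breslow partial likelihood for Cox models
of age at diagnosis (Breslow rather than Efron ties is an assumption; the
source protocol does not state its choice). With only a handful of
covariates the Cox maximiser is a Nelder–Mead search on the exact penalised
partial likelihood, with profile-likelihood inference as above; tests hold
it to a fine-grid oracle within 1e-3 and to the unpenalised estimate
asymptotically. Log-rank comparisons use lifelines.

### Power analysis

A person's carrier status is one Bernoulli draw with control probability
q₀ = 2·CAF·(1 − CAF) (Hardy–Weinberg for a rare allele); cases scale the
carrier odds by the odds ratio. Power at a design point is the Monte-Carlo
fraction of simulated cohorts whose two-sided Fisher test reaches α, and
the smallest cohort achieving a target power is found by bisection with
common random numbers. The published sample-size figures for the analogous
calculation were produced by an unstated method; the numbers computed here
come from this HWE-binomial model and are reported as such, not asserted
against the published ones.

## Quality control

Two profiles mirror the two association frameworks. Shared thresholds:
DP ≥ 10, GQ ≥ 20, heterozygous allele-balance binomial test p ≥ 1e-6,
FS ≤ 200 (indels) / ≤ 60 (SNVs), MQ ≥ 40, QUAL ≥ 30, RPRS ≥ −2, MQRS ≥ −8,
caller FILTER = PASS, site missingness ≤ 10%. Differences: het allele
balance ≥ 0.20 for the variant-level profile versus [0.25, 0.8] for
collapsing (which also requires AB ≥ 0.8 for homozygous-alt calls — the
variant-level profile's het rule has no upper bound, an asymmetry kept as
quoted from the source protocol); external-reference coverage ≥ 10× in
≥ 30% vs ≥ 25% of reference exomes; reference allele-count ratio
ac ≥ 0.5·ac_raw (variant-level) versus RPRS ≥ −2 and MQ ≥ 30 for variants
present in the reference (collapsing); only the variant-level profile drops
sites failing genotype QC in more than 20,000 people. A missing metric
passes its own check; a failing record reports every violated rule. A
genotype failing QC becomes missing — it still counts toward missingness
and the per-site failure tally — rather than being dropped. Hemizygous
calls are held to the homozygous-alt rules (the protocol is silent; this is
documented as an assumption). Multi-allelic records must be decomposed
before reading; the reader rejects them because the QC ledger is defined
per alternate allele.

Coding-region restriction reads BED (0-based half-open on disk) and keeps a
site with 1-based position pos when an interval satisfies
start ≤ pos ≤ end. Treating both converted bounds inclusively is one
position more permissive than the textbook conversion at interval starts;
it is the contract fixed by this package's worked examples.

## Qualifying-variant models

A QV model is declarative: internal and external MAF caps, an allowed
consequence set, an optional requirement that missense variants carry the
regional missense-intolerance (MTR) flag, optional internal allele-count
and reference-absence requirements (ultra-rare models), and a zygosity
mode. Protein-truncating consequences are the standard SO-term list
(stop_gained, frameshift_variant, splice donor/acceptor, start/stop_lost,
exon_loss, gene_fusion, bidirectional_gene_fusion, rare_amino_acid_variant,
transcript_ablation). The shipped registry reconstructs a conventional
ten-model panel — `ptv` (PTV, MAF < 0.1%), `raredmg`/`raredmgmtr` (rare
missense, ± intolerance), `flexdmg`/`flexnonsynmtr`/`flexnonsyn`
(PTV+missense at a looser 0.5% cap, ± intolerance), `ptvraredmg`, `UR`
(singleton, absent from the reference), `rec` (recessive, MAF < 1%), and a
synonymous negative control `syn` (MAF < 0.1%). The exact caps used by any
given study live in configuration, not code: every default is editable and
models load from YAML. The intolerance flag is consumed as a boolean site
annotation; no score is recomputed. For replication designs the internal
frequency filter can be switched to control-cohort frequencies only, with
variants absent there passing automatically.

## Synthetic cohorts

The generator emulates the structure the analyses assume, not real genomes:

* Genes carry independent sites in three consequence classes. Each class's
  per-gene cumulative allele frequency (defaults: PTV 3e-4, missense 1e-3,
  synonymous 1e-2) is split across sites by a flat Dirichlet draw, with
  enough sites per class that individual frequencies sit in the rare
  regime (~4e-4 scale). No linkage disequilibrium and no realistic site
  frequency spectrum — both deliberate non-goals; the LD-dependent clumping
  logic is tested with explicitly constructed haplotype pairs instead.
* Genotypes are Hardy–Weinberg: allele counts are binomial over the 2M
  chromosomes and placed by uniform sampling without replacement (realised
  as iid draws with within-site duplicate rejection, which yields exactly
  the without-replacement law). Compound-het and hom-alt carriers arise
  naturally from independent site draws.
* Disease status follows a logistic model: baseline log-odds from the
  population prevalence (default 1%, configurable — the source cohorts'
  prevalence is not stated) plus log(OR) for each effect gene in which the
  person carries a PTV allele. Cases and controls are sampled from the
  population, which preserves carrier odds ratios in the case-control
  sample. Genes without effects are statistically independent of phenotype,
  so their genotypes are drawn directly for the sampled cohort — a
  distributional identity that makes the 18,930-gene runs tractable.
* Sex (cases 63% male by default, matching the epidemiology the source
  cohorts show), recruitment age, ancestry strata with shifted principal
  components, Weibull ages of onset conditioned on diagnosis before the
  censor age (shape 5, scale 75, censor 80 — chosen to put the case onset
  median near 70), and exome-wide PTV burden are attached per sample.
* QC metrics are drawn independently per site and per call, with a
  configurable fraction (default 2%) of records drawn from each metric's
  failing range. No metric covariance is modelled: the filters need
  exercising, not realism.

What passing tests on these cohorts do show: the estimator, the exact
tests, the QC bookkeeping, and the permutation machinery behave correctly
under the stated statistical structure. What they do not show: robustness
to LD between rare sites, to realistic frequency spectra, to correlated QC
failures, or to population stratification beyond label-carrying.

The printed carrier tables of the source study (discovery, replication and
carrier-exclusion analyses) ship as named fixtures and serve as worked
examples throughout.

## Validation design and problem sizes

* Exact-test equivalence: the Fisher p equals an integer-arithmetic
  enumeration oracle on every 2×2 table with n ≤ 60 (628,055 p-values,
  worst deviation ~1e-14); the exact CMH equals a joint-space enumeration
  oracle on all two-stratum margin pairs with per-stratum n ≤ 8 plus a
  seeded panel drawn up to n ≤ 20.
* Parameter recovery: 200 replicates per carrier OR in {2, 4, 10} at CAF
  3e-4 with 2,000 cases / 20,000 controls, run through the full collapsing
  pipeline; the 95% Woolf intervals cover the truth for 96.5% of the 600
  replicates (the Woolf interval is intrinsically a little conservative at
  expected carrier counts of 2–12). The design point fixes the qualifying
  (post-QC) cumulative frequency, so the recovery cohorts are generated
  with QC-failure noise off; QC attrition is exercised elsewhere.
* Negative control: a fully null cohort at the full 18,930-gene scale
  (cohort scaled to 1,000/10,000 to keep the run inside a few minutes)
  gives λ_GC ≈ 1.00, observed synonymous p-values exchangeable with the
  n-of-1 permutation null, and no excess of nominally significant genes.
* Firth: finite estimates under complete separation; agreement with
  iteratively-refined grid-search maximisers of the penalised (partial)
  likelihood within 1e-4 (logistic) and 1e-3 (Cox).

## Numerical choices and degenerate inputs

* Two-sided exact rules use relative tolerance 1 + 1e-7 when comparing
  point probabilities (floating-point ties at the observed probability).
* Genes or sites with zero qualifying carriers are reported with p = 1
  (no information), not dropped; empty-margin strata are dropped from the
  CMH with a warning; a Mantel–Haenszel estimate with a zero denominator
  (concordant zero cells) returns the boundary value with an undefined CI.
* Clumping ties in p break by (chrom, pos); r² is the squared Pearson
  correlation of 0/1/2 dosages over jointly non-missing samples — a
  self-contained stand-in for haplotype-based LD estimates, adequate at
  the scales tested.
* Sex rebalancing removes pseudo-randomly chosen female controls until the
  control male:female odds match the case odds to the nearest integer, and
  only acts when the sex-by-status Fisher p < 0.05.
* All randomness flows from explicit integer seeds; identical seed and
  configuration reproduce byte-identical outputs, including the TSVs
  written by the discovery driver.
* Censor-date arithmetic from specific data releases is generalised to
  explicit per-sample onset/censor inputs; the generator's onset model is
  the documented preset.

## Known limitations

* The exact caps of the original ten QV models are not published in the
  main text; the shipped registry is a labelled reconstruction.
* Quantities depending on unprinted inputs are not reproduced: the
  four-stratum combined CMH (one stratum's counts are unpublished), the
  real cohorts' λ medians, the carrier survival hazard ratio (individual
  ages unpublished), and the published sample-size figures (method
  unstated). Internal-consistency properties of the printed strata cover
  these paths instead.
* Replication-cohort confidence intervals in the source Results text
  follow a conditional-MLE convention this package deliberately does not
  implement (a non-goal); its Woolf intervals match the discovery table.
* The Firth logistic convergence tolerance (1e-8 on the modified score) is
  strict; on pathological designs the optimiser reports `converged=False`
  with the iteration count rather than failing.
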