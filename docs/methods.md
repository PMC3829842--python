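# Methods

## Scope and model of the data

`gsabench` implements sixteen gene set analysis (GSA) statistics behind a
single interface and the evaluation framework used to compare them. The
unit of analysis is a two-group (optionally paired) log2 expression matrix
`X` (genes × samples) together with a collection of gene sets. Each method
emits one score and one p-value per set; the benchmark layer summarizes,
per method, how well a designated *target* set (the disease set expected
to be relevant for a dataset) is detected (sensitivity), how near the top
of the p-value-sorted output it lands (prioritization), and how often sets
are called significant when the phenotype carries no signal (specificity).

Two families of null hypotheses run through everything:

* **competitive / gene-sampling** (ORA, MRGSE, SIGPATHWAY-Q1, GSEAP,
  GAGE): the set is compared against the background of other measured
  genes, with genes as the sampling unit. These work with as few as one
  sample per group but implicitly assume genes are exchangeable — an
  assumption inter-gene correlation violates, which is exactly the
  false-positive inflation the specificity experiment measures.
* **self-contained / subject-sampling** (the rest): the set's association
  with the phenotype is referenced against relabelings of the samples, so
  correlation between genes is carried into the null automatically.

## Gene-level statistics

All methods that need per-gene association scores use an empirical-Bayes
moderated t. Per-gene residual variances `s²` (pooled two-sample, or
one-sample on within-block differences for paired designs) are shrunk
toward a prior `s0²`:

    s2_post = (d0·s0² + d·s²) / (d0 + d),     t_mod = effect / sqrt(s2_post·c)

with `(s0², d0)` estimated by moment-matching the scaled-F marginal of
`s²` on the log scale (closed form via the inverse trigamma function).
`t_mod` is referred to a t distribution on `min(d0 + d, G·d)` degrees of
freedom; when the observed spread of `log s²` does not exceed its pure
sampling variance, `d0 = ∞` and the prior collapses to the arithmetic
mean of the variances (fully pooled t). Both branches are cross-checked
against limma's `lmFit`/`eBayes` in the test suite (agreement to ~1e-6 on
t). Two-sided p-values throughout; BH step-up for FDR.

## The sixteen set statistics

Implementation choices that the underlying publications leave open, and
how each null is drawn:

| method | statistic | null |
|---|---|---|
| ORA | hypergeometric tail P(X ≥ k) of DE/set overlap | analytic |
| MRGSE | Wilcoxon rank-sum of p-value ranks, set vs rest, one-sided | exact ≤ 20 genes, else normal + continuity |
| SAFE | Wilcoxon rank-sum of \|t\| ranks | sample permutation |
| SIGPATHWAY-Q1 | standardized mean of t in set | random same-size gene sets |
| SIGPATHWAY-Q2 | standardized mean of t in set | sample permutation |
| GSA | restandardized maxmean | sample permutation |
| PADOG | mean of weighted \|t\|, weights 1 + √((f_max−f)/(f_max−f_min)) | sample permutation, per-permutation standardization across sets |
| GAGE | per-case fold-change shift vs background (Welch t), Stouffer-combined | analytic (independence assumed — deliberately, as the original does) |
| CAMERA | standardized mean difference of t, set vs rest, scaled by √VIF, VIF = 1+(m−1)ρ̄ | normal |
| GLOBALTEST | Q = ‖Xu‖²/m on row-standardized set matrix, u = centered labels | exact enumeration when C(n, n₁) ≤ 20 000, else Satterthwaite chi-square on the *exact* permutation moments |
| GSEA | weighted KS enrichment score (weight exponent 1) | sample permutation, signed pools |
| GSEAP | same ES on the fixed moderated-t ranking | random same-size gene sets |
| PLAGE | first-singular-vector sample projection, moderated t downstream | moderated t |
| ZSCORE | Σ z_gs/√m per sample | moderated t |
| SSGSEA | rank-weighted ECDF difference per sample (τ = 0.25) | moderated t |
| GSVA | Gaussian-kernel CDF transform (bandwidth sd/4) + KS walk | moderated t |

Notable numerical decisions:

* **Permutation p-values** are `(b+1)/(B+1)`. When a null space is small
  enough to enumerate (relabelings, sign patterns, or gene subsets), the
  enumeration replaces sampling and the p-value is exact; the identity
  labeling is excluded from enumerated relabeling banks so the same
  formula still yields the exact randomization p. Tail counts use a
  `1e-9`-relative tolerance so exact ties survive independent
  floating-point evaluation. 1000 permutations is the default contract
  for every resampling method.
* **Enrichment score.** The running sum between hits is linear, so its
  extrema occur immediately before/after hits; the ES is computed from
  the m hit positions in O(m log m) and exact ties between the positive
  and negative extreme resolve positive. Verified against fgsea's
  `calcGseaStat` and a brute-force running-sum oracle.
* **GSEA p-value convention**: positive and negative null ES are pooled
  separately and the observed ES is compared within its own sign pool.
* **GSA restandardization** uses 100 size-matched random gene sets, drawn
  once and reused across permutations. Because the same bank standardizes
  the observed and every permuted statistic, the permutation p-value is
  exact regardless of the bank size; the bank only affects power.
* **GLOBALTEST.** With rows standardized, `A = XᵀX/m` annihilates the
  ones vector and Q equals the subset quadratic form `1_Sᵀ A 1_S` over the
  random case subset S. Its first two permutation moments have closed
  forms in contractions of A (verified against brute-force enumeration);
  a Satterthwaite chi-square on those moments is accurate in the tails
  (false-positive calibration holds at α = 0.05) and within ~0.02 of a
  10 000-permutation p at n = 20 everywhere. For designs with
  C(n, n₁) ≤ 20 000 the subset space is enumerated outright and the
  p-value is exact — the approximation is reserved for designs where it
  is demonstrably adequate.
* **GAGE's independence assumption** when combining per-case-sample
  p-values (Stouffer on signed z; Fisher available via
  `params={"combine": "fisher"}`) is retained on purpose: it is the
  mechanism behind the method's characteristic false-positive inflation,
  which the benchmark is designed to expose.
* **Single-sample scores** are tested downstream with the same moderated
  t machinery (sets playing the role of genes, paired-aware); a single-set
  matrix falls back to the ordinary t because the empirical-Bayes fit is
  not identifiable from one row. ssGSEA normalizes each set's score
  vector by its range across samples — a per-row variant of the usual
  matrix-range normalization; it leaves the downstream t unchanged and
  keeps the per-set API self-contained.

## Benchmark layer

Per (dataset, method) pair the benchmark records the target set's p-value
and its tie-averaged rank as a percentage of sets analyzed. Per-method
summaries are the medians over datasets (sensitivity surrogate,
prioritization), classical sensitivity at fixed α, and the
phenotype-permutation false-positive percentage. Robust Z-scores

    z = (x − median(x)) / (1.4826 · MAD(x))

are computed across the methods within a category; the 1.4826 normal-
consistency factor is required to reproduce the published reference
table's printed Z-scores, so the "MAD" in the combination is the
normalized estimator. Methods whose FP% at α = 1% exceeds 3% form
category II and their specificity Z joins the sum; the 3% threshold was
chosen to sit between the empirical FP range of well-calibrated methods
(≤ ~2.5%) and the inflated gene-sampling group (≥ ~5%). Ranks are
ascending in the Z-sum, ties broken by lower median rank then method id.

Ranking stability splits the datasets at the median of each of four
features (total sample size, target set size, paired/unpaired design, and
effect size measured as the % of genes with nominal p < 0.05) and reports
the Spearman correlation of each subset ranking with the overall ranking
per category; subsets with fewer than three datasets are flagged low-n.

The phenotype-permutation experiment permutes group labels (sizes
preserved, identity excluded). Pairing is ignored under this null —
labels are exchangeable when there is no signal — so permuted datasets
are analyzed as unpaired. Per-method failures on individual permuted
datasets are logged and excluded from that method's totals rather than
aborting a 16-method run.

## Synthetic data generator

The generator emulates the statistical structure of RMA-normalized
two-group microarray data, which is what the benchmark design assumes:

* Gaussian baseline, mean 8, sd 2 (log2-intensity scale).
* Compound-symmetry correlation ρ within each set via one latent factor
  per set; genes in several sets take the factor of the first set
  containing them, target first, so the target set always carries its
  full configured correlation (assigning factors by lexicographic set id
  instead would dilute the target's correlation through overlaps and
  break the generator's own covariance contract).
* A designated target set in which a fraction `de_fraction` (default 0.5)
  of genes is shifted by `effect_size` (default 0.8) per-gene sd in cases,
  with `direction_mix` controlling the down-regulated share (default 0,
  coordinated up-regulation).
* Paired designs add a per-block random intercept with sd = baseline_sd/2.
* Sets (default 50, sizes 10–100, target 40) are drawn with replacement
  across sets, giving PADOG a non-degenerate gene-frequency spectrum;
  defaults are 2000 genes and 10 samples per group.

What it does **not** emulate: probe-level noise, batch effects,
platform-specific intensity distributions, heavy-tailed or count-based
(RNA-seq) noise, and realistic pathway topology or hub-gene structure.
Passing the calibration/inflation/recovery suites therefore demonstrates
the statistical mechanics of the methods under the assumed Gaussian
factor model, not their behavior on any particular real dataset.

## Validation experiments and problem sizes

The test suite runs three simulation experiments at sizes chosen to keep
a full single-CPU run of the suite within a few minutes:

* **Calibration**: 10 uncorrelated null datasets (ρ = 0, no effect) at
  the generator's default scale (2000 genes, 50 sets, 10v10, 1000
  permutations) give 500 set-level tests per method; every
  subject-sampling method's FP proportion at α = 0.05 must fall in the
  central 99% binomial band.
* **Inflation**: the same design with ρ = 0.2 must push every
  gene-sampling method's FP at α = 0.01 to at least twice nominal.
* **Signal recovery**: 20 replicate datasets per effect size at a reduced
  scale (600 genes, 20 sets of 10–40 genes, target 20, 8v8, 200
  permutations). With δ = 0.8 and half the target shifted, every method's
  median target rank must be below 50%; median target p must be
  non-increasing across δ ∈ {0, 0.5, 1.0}. The reduction (relative to the
  null experiments) trades per-dataset resolution for replicate count,
  which is what the medians need.

Reference arithmetic (robust-Z combination, categorization, scenario
Spearman) is validated against a published 42-dataset compendium
evaluation of these sixteen methods whose per-method summary columns are
bundled in `gsabench.reference`. Two entries of that published table are
internally inconsistent at the printed precision (a sign typo in one
Z-score, and two values that do not reproduce from the printed raw
columns, evidently computed from unrounded inputs); the tests assert the
recomputed values and note the discrepancies in comments.

## Known limitations

* CAMERA is implemented in its parametric VIF form without the
  small-sample residual-df refinements of the reference implementation.
* GSVA here follows the kernel-CDF + KS-walk construction with the
  transformed values as walk weights; it is not a bit-exact reimplementation
  of the GSVA package (whose rank-statistic details differ), and the same
  caveat applies to SAFE/GSA/sigPathway relative to their R originals.
  Exactness claims are therefore anchored to enumeration oracles and to
  limma/fgsea where the statistic is genuinely identical.
* Multi-class phenotypes, covariate adjustment, rotation tests and
  topology-aware pathway statistics are out of scope.
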