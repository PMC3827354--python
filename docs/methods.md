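# Methods

## The model

MDR collapses an *n*-locus genotype space into a single binary attribute.
For a locus set `L = (l_1, …, l_n)` the individuals partition into genotype
cells; each observed cell is scored and labelled high- or low-risk, and the
resulting one-dimensional classifier is evaluated against case/control
status. The package implements three variants that share this skeleton:

| method  | cell score                                   | ranking error     |
|---------|----------------------------------------------|-------------------|
| mdr     | `cases / controls`                           | `(FP+FN) / total` |
| mdr_e   | `cases / controls`                           | balanced error    |
| mdr_er  | `(cases/P*) / (controls/N*)`                 | balanced error    |

where `P*` and `N*` are the training-set case and control totals and the
balanced error is `1 − (sensitivity + specificity)/2`. A cell is high-risk
when its score is **greater than or equal to** the threshold `T` (default
1; configurable, including the case:control-ratio threshold variant some
practitioners use). Limit conventions: a non-empty cell with zero controls
scores `+inf` (high-risk at any finite `T`); zero cases scores 0
(low-risk); an empty cell is undefined and never labelled. Two identities
hold and are property-tested: with `P* = N*` the percentage-ratio score
equals the plain ratio cell-by-cell, and on exactly balanced data the
balanced error equals the standard error, so `mdr` and `mdr_e` coincide
there.

Under class imbalance the two changes matter independently. With 1:4
controls per case, almost every cell holds more controls than cases, so the
plain ratio classifier labels almost everything low-risk and the standard
error is minimized by the trivial all-low model (error = case fraction).
The balanced error removes the second failure; the percentage-ratio score
removes the first by comparing each cell's case share against its control
share, i.e. against the base rate.

## Model selection

Ten-fold cross-validation (configurable `k`): individuals are permuted
uniformly and dealt round-robin into folds. The default split is
deliberately *not* stratified — random group assignment lets the training
control:case ratio fluctuate (≈ 3.4–4.0 around 3.65 for a 193/704 dataset,
which the test suite checks); a stratified option pins the ratio when that
fluctuation is unwanted. Per fold, all `C(m, n)` locus sets are enumerated
in lexicographic order; the first set attaining the minimum training error
wins. The cross-validation consistency (CVC) of a set is the number of
folds that chose it. The final model maximizes CVC, with ties broken by
lowest mean prediction error over the folds that chose it, then by
enumeration order ("found first"). Final statistics are computed on a
refit over the full dataset, not averaged over folds; per-fold prediction
errors are also retained. `repeated_runs`/`fit_repeated` repeat the whole
search over distinct CV seeds and report each set's selection frequency;
the modal model's frequency is the "consistency" figure (e.g. 66/100).

Test individuals whose genotype cell was absent from training are routed
to low-risk (conservative toward the majority class) and counted in
`unseen_cell_individuals` so users can audit how often it happened.

## Numerical conventions

- The balanced error is computed from the integer-rational form
  `(FN·N* + FP·P*) / (2·P*·N*)` instead of `1 − (sens+spec)/2` in floating
  point. Mathematically equal errors then compare bitwise equal, which
  keeps the "first found" tie-break deterministic and makes `mdr` and
  `mdr_e` provably select the same model on balanced folds.
- Scores are stored at full precision; two-decimal rounding is display-only.
- Odds ratios use `(TP·TN)/(FP·FN)` with a Woolf log-OR interval
  `exp(ln OR ± 1.96·√(1/TP+1/FP+1/FN+1/TN))`; a zero cell triggers the
  Haldane–Anscombe +0.5 correction on all four cells (logged). Reported
  "accuracy" is balanced accuracy, `1 −` balanced error.
- Significance is a Pearson chi-square on `[[TP,FN],[FP,TN]]` (1 df, no
  continuity correction). Note that this post-labelling test is strongly
  anti-conservative as a test of SNP–disease association, because the
  high/low split is chosen from the same data: under a flat-penetrance null
  its nominal-5% rejection rate exceeds 20% (a test asserts this). For a
  calibrated per-model test use `evaluation.cell_chi_square_p`, the
  chi-square on the raw genotype-cell × status table, whose null rejection
  rate sits at the nominal level.
- `make_cv_plan` refuses splits whose training complement lacks a class;
  balanced-error evaluation raises on a test fold with an empty class
  rather than returning a silent placeholder.

## The simulator

`synthetic.generate` draws genotypes per SNP under Hardy–Weinberg
equilibrium from its minor allele frequency (code = minor-allele count,
0/1/2, SNPs independent) and assigns disease status from a penetrance table
over the causal loci. Rejection sampling keeps drawn individuals until the
case and control quotas are met exactly, which leaves non-causal SNPs
independent of status and reproduces a case-control (outcome-dependent)
sampling design. The default study profile is 77 SNPs, 193 cases, 704
controls (ratio 3.65), with MAFs drawn once per seed from Uniform(0.05,
0.5). `fixture_from_cells` inverts a cell-count table into a concrete
dataset, which is how the published worked examples are executed rather
than transcribed.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error or missingness, and
covariates. Passing tests therefore demonstrate correctness of the
algorithms and their behaviour under idealized imbalance and epistasis, not
robustness to those real-data complications.

## Study conditions used in the test suite

Problem sizes were chosen as the smallest that exercise each property
cleanly:

- Oracle equivalence: the per-fold search is compared against an
  independent dictionary-based brute-force re-implementation on 210 random
  6-SNP / 60-row instances (70 per method).
- Planted-effect recovery: two-locus joint-carrier penetrance (baseline
  0.07, risk 0.21, MAF 0.3), 75 cases / 300 controls (1:4), 12 SNPs, 50
  replicates. At this moderate effect size neither method is perfect;
  MDR-ER recovers the causal pair roughly three times as often as classic
  MDR, and the test asserts the ordering with the frequencies left free.
- Null calibration: flat penetrance 0.25, 20 SNPs, 150 cases / 300
  controls; the fraction of the 190 two-locus cell tables with
  `cell_chi_square_p < 0.05` must lie in a generous binomial band around 5%.
- Deterministic recovery: carrier penetrance 0.02/0.6 yields CVC 10/10 and
  20/20 modal frequency, used to pin the selection plumbing.

## Known limitations

- The exhaustive search is O(C(m, n)) per fold; orders 2–5 are supported
  and practical for tens to a few hundred SNPs, but the package provides no
  stochastic search heuristics for genome-scale inputs.
- No multiple-testing correction is applied across locus sets, matching
  standard MDR reporting; the post-hoc chi-square caveat above applies.
- The threshold `T` is fixed per run, not optimized; finding an optimal
  per-dataset threshold is a different (and harder) route to imbalance
  robustness than the percentage-ratio classifier implemented here.
- File input is limited to the MDR flat format and its CSV dialect; VCF or
  PLINK inputs should be converted upstream.
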