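# Methods

## The model

`klsnet` implements individual-level gray-matter (GM) morphological
connectomes. Group-level structural covariance networks correlate regional
morphometry *across* subjects and therefore yield one network per group;
the individual-level alternative implemented here treats each region's
voxelwise GM volume values as an empirical distribution and defines the
edge between regions i and j of a *single* subject as the similarity of
those two distributions.

For each region, the probability density of the (modulated) GM volume
values of its voxels is estimated by Gaussian kernel density estimation
with an automatic bandwidth and discretised on a grid shared by all regions
and subjects. With discrete probabilities P and Q, the directed
Kullback-Leibler divergence is

    D_KL(P || Q) = sum_i P(i) ln( P(i) / Q(i) ),

its symmetrised form is D_KL(P, Q) = D_KL(P || Q) + D_KL(Q || P), and the
edge weight is

    KLS(P, Q) = exp( -D_KL(P, Q) )  in (0, 1],

equal to 1 exactly when the distributions coincide. A cohort of subjects
with an n-region atlas yields one symmetric n x n KLS matrix per subject
(n = 116 for the AAL whole-brain parcellation these networks are usually
built on).

Downstream, each weighted matrix is binarized over a sparsity sweep, graph
metrics are summarised by their area under the curve (AUC) over sparsity,
groups are compared with covariate-adjusted linear models, edges with
network-based statistics (NBS), and the resulting significant features feed
nested cross-validated classifiers.

## Numerical conventions

Choices the underlying methodology leaves open are fixed as follows and
recorded in each run's manifest and KLS sidecar metadata:

- **Kernel and bandwidth.** Gaussian kernel; Scott's rule
  (sigma * n_voxels^(-1/5)); Silverman available via `bw_method`.
- **Evaluation grid.** 256 points (configurable) spanning the pooled cohort
  range padded by 3 pooled bandwidths. A common grid is essential: KL
  divergence between densities discretised on different supports is not
  comparable across subjects.
- **Probability floor.** Discrete probabilities are renormalised, floored at
  eps = 1e-12 and renormalised again. Without the floor the divergence is
  undefined wherever Q(i) = 0; with it, KLS is bounded below by roughly
  exp(-2 ln(1/eps)) ~ 1e-24, so weights never underflow to 0.
- **Logarithm.** Natural log. KLS orderings are base-invariant; absolute
  values are not, so the base is part of the metadata.
- **Diagonal.** Self-similarity is fixed to 0 and excluded from
  thresholding; it carries no network information.
- **Edge counts.** At sparsity s, K = round(s * n(n-1)/2) with halves
  rounded away from zero; ties at the threshold boundary are broken by
  weight descending, then lexicographic (i, j), making binarization
  deterministic. Edge sets are nested across the sweep by construction.
- **Disconnected pairs.** Excluded from the characteristic path length
  (mean over reachable pairs) and contributing 0 to efficiencies — the
  common toolbox convention, which keeps Lp finite at low sparsity. A graph
  with no reachable pairs has Lp = +inf.
- **Small-world normalisation.** lambda = Lp / <Lp_rand>, gamma =
  Cp / <Cp_rand>, sigma = gamma / lambda against degree-preserving
  Maslov-Sneppen rewired surrogates (target 10K successful swaps per
  surrogate, capped proposals; a shortfall is logged with the achieved
  count). At full scale 1000 surrogates per graph are standard; the
  desk-scale pipeline default is 20, configurable. On very sparse graphs
  the surrogate ensemble can have zero mean clustering; gamma and sigma are
  then NaN and the affected AUCs are skipped (and listed) rather than
  fabricated.
- **Betweenness.** Unnormalized Brandes values; the normalisation constant
  is monotone and irrelevant to group inference.
- **NBS.** Covariates are regressed out of every edge once; edgewise
  pooled-variance t tests on the residuals; the default tail is `decrease`
  (patients < controls) with `increase` and `both` available; component
  statistic = edge count; family-wise error from the maximum component size
  over group-label permutations with the (1 + b)/(1 + P) estimator, so
  p is never 0. Residualise-once-then-permute is simpler than
  Freedman-Lane and matches the regression-before-permutation description
  this design follows.
- **Covariate-adjusted metric tests.** OLS of each AUC on
  group + sex + age + education; the group coefficient's two-sided t test.
  With no covariates this reduces exactly to the equal-variance two-sample
  t test. FDR (Benjamini-Hochberg) is applied to nodal metrics across
  nodes within each metric family; the seven global metrics are reported
  uncorrected.
- **Power computation.** Smallest per-group n such that a two-sided
  two-sample t test with noncentrality d*sqrt(n/2) and 2n-2 degrees of
  freedom reaches the requested power; exact noncentral-t evaluation, no
  normal approximation. d = 0.80, alpha = 0.05, power 0.8 gives 26.

## Classification harness

Three classifiers — L2 logistic regression, linear SVM, random forest —
are evaluated with stratified nested cross-validation (outer 10-fold,
inner 5-fold). Per outer fold a min-max scaler is fit on the training
portion only; the inner loop selects the hyperparameter maximising
fold-averaged accuracy (C in 2^-5..32 for LR/SVM; n_estimators 10..200
step 10 for RF at full scale). Out-of-fold predictions are pooled before
computing accuracy, ROC AUC, sensitivity (patient recall; patients are the
positive class) and specificity. Significance comes from label-permutation
tests in which the *entire* nested CV is re-run per permutation. Feature
contributions are mean linear weights (LR/SVM) or impurity importances
(RF) across outer folds; the reported "shared top features" are those in
the top 20% by absolute contribution in all three models.

Two implementation notes. The linear SVM is used because per-feature
weights only exist for linear kernels. The RF grid search exploits that,
for a fixed random state, scikit-learn's k-tree forest consists of the
first k trees of the maximal forest, so one maximal forest per inner fold
scores the whole n_estimators grid exactly (verified against direct fits
in the test suite). Because tree and liblinear fits on small cohorts are
dominated by fixed per-fit overhead, the desk-scale configurations search
n_estimators up to 30-50; the full 10-200 grid is the package default for
real analyses.

## Synthetic cohorts

No patient MRI data can ship with the package, so every stage is exercised
on simulated cohorts with known ground truth (`klsnet.simulate`):

- Each region's voxel values are truncated-at-zero Gaussians
  (location 0.5, scale 0.1 in modulated GM volume units); each subject
  perturbs each region's mean by a between-subject component
  (tau = 0.3 of the voxel scale). Voxel counts per region are drawn once
  per cohort from 250-350 (small-test spec: exactly 300).
- Covariates: sex ~ Bernoulli(0.15 male), age ~ N(46, 12.3),
  education ~ |N(11, 4.8)|, matched across groups unless a confound
  (group age shift and/or an age effect on all region means) is requested.
- **Planted subnetwork.** The regions spanned by the requested edges
  receive equally spaced patient-specific mean offsets. The spacing is
  derived by inverting a closed-form model of the KLS edge: for Gaussian
  regions with common scale, the symmetric KL divergence is approximately
  (delta_mu / sigma_eff)^2 (sigma_eff inflated by the KDE bandwidth), which
  makes the KLS a noncentral-chi-square transform with closed-form mean and
  variance. The generator solves for the mean separation whose implied
  between-group effect size on the *edge weight* equals the requested
  `similarity_shift` (in pooled-SD units), so every planted pair is
  weakened by at least the stated effect — without ever touching the KLS
  values directly; the whole KDE -> KL -> KLS chain stays exercised.
- **Planted node.** One region drifts from all others by the same
  mechanism, producing the expected nodal degree/efficiency reduction after
  sparsity thresholding.
- Default desk-scale spec: 12 regions, 300 voxels/region, 20 + 20
  subjects — the full pipeline runs in minutes on one CPU. The cohort-scale
  defaults (55 patients vs 57 controls, 116 regions) match the study design
  the pipeline targets.

What the generator does *not* emulate: spatial voxel correlation and
smoothness, registration/segmentation error, multimodal or skewed GM value
distributions, site effects, and realistic covariance between regions.
Passing tests therefore demonstrate the correctness and calibration of the
estimators on clean distributional data, not performance on real MRI; on
real data the KLS edges are noisier and effect sizes far smaller.

## Problem sizes used in the shipped tests and acceptance script

Simulation-based checks run at desk scale, sized to run comfortably on a
single CPU: NBS calibration uses 200 null and
50 planted cohorts at 500 permutations; the acceptance script uses 100 and
20 cohorts at 300 permutations plus one full pipeline run (20 surrogates
per threshold, 1000 NBS permutations, 50 CV permutations, RF grid to 30).
Full-scale settings (1000 surrogates, 5000 permutations everywhere,
RF grid to 200) are plain configuration changes.

## Known limitations

- KLS values depend on the shared grid and floor; matrices computed with
  different grid settings are not comparable.
- The Lp convention (reachable pairs only) makes Lp non-monotone across
  very sparse thresholds in principle; Eglob is the better-behaved
  integration measure there.
- The NBS null permutes residualised data, which is exact only under
  exchangeable errors; with strong covariate-group dependence a
  Freedman-Lane scheme would be preferable.
- `sigma`/`gamma` are undefined where the surrogate ensemble has no
  triangles; affected AUCs are reported as missing.
- The classification stage assembles features from statistics computed on
  the same cohort; reported accuracies are
  internal-validation figures, not external-cohort estimates.
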