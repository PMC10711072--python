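# Methods

## Scope and design

`nigraquant` quantifies substantia-nigra (SN) degeneration in Parkinson's
disease from three co-acquired midbrain MRI contrasts — neuromelanin-
sensitive T1 (NM, 0.5×0.5×3 mm³), quantitative susceptibility mapping
(QSM, ppb, 0.5×0.5×1 mm³) and susceptibility map-weighted imaging (SMWI,
derived from QSM and the SWI magnitude) — and evaluates the resulting
nine SN-mask parameters and their composite as PD classifiers and as
correlates of clinical severity.  Because no imaging data are deposited,
the package ships a calibrated synthetic phantom that reproduces the
published cohort's statistical structure; every downstream stage is
exercised against it.

## Feature extraction

Masks are binary label volumes on each modality's native grid (no
cross-modality resampling; the NM and iron protocols are analysed
separately, as acquired).  The SN mask is bilateral and confined to three
analysis slices; a background ROI on the same slices provides reference
statistics.  Conventions:

- **Area** = in-mask voxel count × in-plane voxel area (0.25 mm²),
  pooled over hemispheres and the three slices.  The alternative
  (per-slice averages) would scale all sizes by 1/3 and was rejected
  because pooled areas reproduce the calibration cohort's printed scale.
- **Percentiles** use linear interpolation between closest order
  statistics (`numpy.percentile` default), making the contrast range
  bit-stable and testable against a sort-based oracle.  The contrast
  range requires ≥ 10 in-mask voxels and a positive 10th percentile.
- **NM high-signal threshold**: background mean + k·SD with k = 3 by
  default — the standard normalisation of NM-MRI against an adjacent
  reference region.  The exact "optimized" rule used on the real cohort
  is not public; an alternative `auc_sweep` mode selects the cutoff
  maximising group-separation AUC of the thresholded area over a pooled
  2nd–98th percentile grid on a labelled calibration cohort, with ties
  resolved toward the higher (more specific) cutoff.
- **QSM low-χ threshold**: fixed 70 ppb, strict `<`.
- **SMWI low-signal threshold**: the 10th percentile of the
  background-mask SMWI signal (the source protocol states only
  "thresholding for low signal voxels"; a background quantile is the
  scanner-scale-free choice).
- **SMWI synthesis**: weight w(χ) = 1 for χ ≤ 70 ppb, 0 for χ ≥ 170 ppb,
  linear between, applied to the magnitude as w⁴.  The cited weighting's
  constants are not published; 70 ppb aligns the lower knee with the QSM
  cutoff, and 170 ppb/power 4 give strong nigral contrast while keeping
  the weight positive across the plausible χ range.  All three constants
  are configurable in `ThresholdPolicy`.

Degenerate inputs (empty masks, all-background variance zero, one-class
ROC, < 3 correlation pairs) raise typed errors or warnings rather than
returning silent defaults; error messages are tagged with the offending
modality during batch extraction.

## Composite marker and classification

The composite is the raw product of NM contrast range, NM thresholded
area and QSM low-χ area — no z-scoring or rescaling, so its scale is
unitless × mm⁴ and cutoffs are cohort-specific.  Rank-based evaluation
(AUC) is invariant to any monotone rescaling, which the suite checks.
Classification at a cutoff assigns the patient label to the low side,
with ties going to the patient side (favouring sensitivity,
deterministic).

## Statistics

- **Effect size**: |Δmean|/s_pooled with the usual pooled variance and
  *no* small-sample correction; recomputation shows the uncorrected
  variant matches the calibration cohort's printed column (e.g. 1.151
  for χ, where the corrected value 1.146 does not).  `corrected=True`
  applies the J factor.
- **Group tests**: pooled-variance t-test or Kruskal–Wallis; `auto`
  screens both groups with Shapiro–Wilk at α = 0.05.
- **ROC**: Mann–Whitney concordance with ties counted ½; 95% CI by
  DeLong's placement-value variance (implemented here; no installed
  package provides it); operating points by Youden's J over score
  midpoints, ties toward specificity.
- **Correlations**: Spearman with average ranks; the Bonferroni family is
  the full feature × clinical grid (20 cells at the default 4 × 5),
  matching a "survived correction" screen.
- **Agreement**: ICC(2,1) (two-way random, absolute agreement, single
  rater) via pingouin; Fleiss' κ via statsmodels; Cohen's κ via
  scikit-learn — each validated against explicit ANOVA/ P̄–P̄ₑ closed
  forms in the tests.

## The synthetic phantom

**Study conditions (defaults).** 111 controls / 80 patients; per-group
feature and clinical (age, MMSE, UPDRS-I/II/III, H&Y, LEDD, sex)
marginal summaries and the pooled feature–clinical Spearman targets of
the calibration cohort.  All randomness derives from one seed.

**Marginal families.** Gaussian for signal intensities, χ, unthresholded
mask sizes and age.  Nonnegative skewed scores (UPDRS, LEDD, 30−MMSE,
contrast-range−1) use gamma marginals moment-matched to the printed
(mean, SD): several of these print a coefficient of variation above 1,
which no zero-truncated normal can attain, while clipping a normal at 0
would bias means by up to ~10%.  Each thresholded size is modelled as a
beta-distributed *surviving fraction* times its parent mask size,
moment-matched on the product — this enforces thresholded ≤ unthresholded
structurally while matching the printed moments exactly.  The iron mask
is a single physical object, so the QSM and SMWI mask sizes are one
draw.  A useful external check: with these families the model-implied
per-feature AUCs come out at 0.54–0.85 and the composite at ≈ 0.93,
close to the calibration cohort's ROC column, although no AUC is ever
targeted during calibration.

**Dependence.** One latent severity per subject drives the four
discriminant imaging parameters (negatively, except χ positively) and
the clinical scores (Gaussian one-factor copula); every marginal is an
increasing transform of its latent score, so rank structure is
inherited.  Loadings are initialised analytically (two-component mixture
moment algebra for the within-group correlation each pooled target
requires, then a rank-1 SVD) and refined by a deterministic simulated
least squares against the pooled Spearman targets, because the heavy
marginal skew makes closed-form pooled-rank algebra inaccurate.
Loadings are sign-constrained so that severity never raises the NM
contrast range or thresholded area and never lowers χ.  One target cell
(NM thresholded size × UPDRS-I, −0.173) is unreachable under that
monotonicity: the between-group separation implied by the printed
marginals already yields ≈ −0.31 pooled; the fit accepts that residual
rather than introduce an anti-severity coupling.  Age couples only to
the NM mask sizes (target −0.22), independent of severity.  H&Y loads on
severity at 0.6 (not a printed target), is rounded to half stages and is
0 for controls; LEDD and sex are independent, patients-only/Bernoulli.

**Volume rendering.** Image-level mode paints two elliptical SN
templates (lateral:AP aspect 1.6) on three slices per grid, a
rectangular background ROI, and per-subject in-mask value multisets
constructed so that noiseless extraction reproduces the sampled truth
exactly: constant order-statistic blocks pin the interpolated 10th/90th
percentiles, a bounded water-fill sets the exact mean, and block
boundaries realise exact above/below-cutoff counts (sizes are quantised
to the 0.25 mm² lattice; truth records are updated to the painted
values).  The NM background level is placed at the order-statistic gap
that makes the background-mean threshold recover the intended
high-signal count — physically, per-subject receiver scaling.  Values
are assigned posterolateral-first, so NM signal attenuates
posterolaterally (the depigmentation pattern) and low χ sits
dorsolaterally (the nigrosome-1 locale); the magnitude volume is painted
as desired-SMWI/w(χ)⁴ so that SMWI derivation inverts exactly.  Painted
χ is capped at 160 ppb (weight must stay positive to invert); truly
unreachable sampled combinations (e.g. mean χ below 70 ppb with almost
no low-χ voxels) are projected to the nearest paintable values, truth
updated accordingly.  Noise is additive Gaussian per volume in native
units (default SD 3) — at ROI-statistic level this is sufficient; Rician
noise, coil inhomogeneity, partial volume and registration are out of
scope.

**Reader and rater simulation.** Visual PD/non-PD ratings are Bernoulli
per reader conditional on the true group, with per-reader
(sensitivity, specificity) defaulting to a senior/senior/junior/
non-neuroradiologist profile ((1.00, .98), (.99, .96), (.94, .89),
(.74, .80)).  A second segmenter's feature table adds Gaussian
measurement noise sized for a target ICC(2,1) (defaults 0.88/0.95/0.97
for NM/QSM/SMWI), treating the first table as noise-free.

**What passing tests do and do not show.** The phantom reproduces
printed *summary* structure — marginals, rank-correlation pattern, and
(emergently) discrimination.  It does not model the real joint feature
distribution, spatial anatomy, segmentation variability or MR physics,
so cohort-level quantities that depend on the unpublished joint
distribution (exact AUCs, sensitivities/specificities, p-values) are
checked as properties and plausibility bands, not as point targets.

## Numerical and reproducibility choices

Problem sizes were chosen for stable estimates at interactive runtimes:
the default pipeline run uses the study-sized cohort (191 subjects);
population-level AUC comparisons use a 30× cohort at the same group
mix; parameter-recovery uses 100 study-sized replicates; sample-SD
convergence of the heavy-tailed marginals is checked at 150,000 per
group, where a 2% band exceeds 2.5 sigma (at 10,000 the sampling SE of
the SD for a cv-2.5 gamma is ≈ 3%, so tighter checks there would be
noise-dominated).  The copula fit is cached per study condition
(marginals, targets and group mix); the calibration simulation uses a
fixed internal seed independent of cohort seeds, so identical configs
always yield identical cohorts and byte-identical pipeline outputs.

## Known limitations

- The severity model is single-factor; real NM and iron measures are
  reported to be largely uncorrelated within groups beyond shared
  disease severity, but any richer within-group structure is not
  modelled.
- Recovered per-replicate effect sizes for heavy-tailed features are
  intrinsically noisy at n = 80 (sample-SD dispersion ≈ 35% for the
  patient contrast range), a property of the printed moments, not of the
  estimator.
- The "optimized" NM threshold and SMWI weighting constants of the
  source protocol are approximations (documented above) pending their
  publication.
- Visual nigrosome-1 rating is simulated, never computed from images;
  QSM reconstruction from phase and automated SN segmentation are out of
  scope.
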