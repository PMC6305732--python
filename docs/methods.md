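# Methods

This note documents the statistical procedures the package implements, the
defaults it chooses where the underlying method leaves them open, what the
synthetic data generator does and does not emulate, and the numerical
decisions that make results deterministic.

## Panel preprocessing

The canonical panel holds 15 measures: 11 raw plasma concentrations
(methionine, SAM, SAH, homocysteine, adenosine, cysteine, Glu-Cys, Cys-Gly,
tGSH, fGSH, GSSG) and 4 derived quantities — SAM/SAH, tGSH/GSSG, fGSH/GSSG,
and the percent oxidized glutathione fraction 2·GSSG/(tGSH + 2·GSSG),
stored as a fraction in [0, 1]. Derived columns supplied in input files are
validated against recomputation (relative tolerance 1e-6) and rejected on
conflict; the recomputed values are always the ones kept, so every table in
memory satisfies the panel's algebraic identities exactly. Rows missing any
measure are excluded at load time with a logged count, mirroring the
complete-panel inclusion criterion of the motivating study design.

Normalization is a z-score with the sample (n−1) standard deviation
convention, fit on training samples only and then frozen; validation, trial
and held-out data are always scaled by the frozen training parameters.
Constant training columns are an error, not silently passed through.

For trials that assay the panel at two follow-up visits, the two timepoints
are averaged on the raw concentrations and the derived ratios recomputed
from the averages. The alternative — averaging the ratio columns directly —
would break the panel identities (the two disagree whenever the denominators
differ between visits); recomputation was chosen to preserve them.

## Fisher discriminant classifier

The scatter matrices carry class-size prefactors: each cohort's summed
outer-product scatter in S_W is multiplied by its sample count, and S_B
weights each class mean deviation likewise. The prefactors rescale S_W
relative to the textbook pooled within-class scatter but leave the
two-class discriminant direction unchanged, which the test suite verifies
against the closed form S_W⁻¹(x̄_ASD − x̄_TD).

Numerics: S_W receives a relative ridge ε·I with ε = 1e-8·tr(S_W)/m before
use, because exhaustive subset search inevitably visits collinear subsets;
the eigenproblem is solved as the symmetric generalized problem
S_B v = λ S_W v (scipy.linalg.eigh) rather than by forming S_W⁻¹S_B. The
returned direction is unit-norm and oriented so the ASD training mean score
exceeds the TD mean — the sign convention that makes "Type II error = mass
below threshold" well defined everywhere downstream. A fit with identical
class means (J = 0) raises a degeneracy error; the subset search catches it
and scores such subsets 0.5, flagged, keeping sweeps total.

The C-statistic is the rank-based AUC (Mann–Whitney U divided by
n_pos·n_neg) with ties counted ½ — the standard midrank convention. Subset
selection ranks subsets by the *fitted* C-statistic, with cross-validation
applied to the chosen model afterward; this mirrors the selection procedure
the package is designed to reproduce, and its optimism is why the
leave-one-out confusion metrics are reported separately. Confusion rates
with zero denominators are reported as undefined (None), never as 0.

## Score densities and the balanced-error threshold

Each cohort's score density is an equal-weight Gaussian mixture centered on
the reference scores. Bandwidth: Silverman's rule of thumb,
0.9·min(sd, IQR/1.34)·n^(−1/5), per score set — chosen as the standard
deterministic default since the underlying method specifies only that the
kernel parameter is tuned; the bandwidth used is recorded in every report.
Densities are tabulated on a fixed grid of 2,048 points spanning the pooled
score range extended by 4 bandwidths per side (the larger of the two
cohorts' bandwidths), then renormalized to unit trapezoidal mass to remove
edge truncation bias. Tail masses are cumulative trapezoids; at exact grid
points the tabulated cumulative is returned without interpolation, so
complement identities hold bit-exactly.

The threshold H₀ is the grid point minimizing |TypeI(θ) − TypeII(θ)|, where
TypeI(θ) is the TD mass above θ and TypeII(θ) the ASD mass below θ. TypeI
is non-increasing and TypeII non-decreasing in θ, so the balance point is
essentially unique; exact ties are broken by the median tying grid point
(deterministic and symmetric).

## Treatment shift metric

Trial cohorts are scored with the frozen case-control model (frozen
normalization, direction, and H₀). Pre- and post-treatment score KDEs are
tabulated on the *frozen threshold grid* — extended by whole grid steps only
when a score set spills past it — so a cohort whose scores equal the TD
training scores reproduces the TD density exactly and its Type II error is
exactly the complement of the frozen Type I error. The reported change is
TypeII_post − TypeII_pre in probability units; positive means movement
toward the TD reference.

The effect size is the median of paired (pre − post) score differences —
positive when the cohort moves toward TD under the ASD-positive orientation
— with a percentile bootstrap CI: participants (paired rows, never
individual scores) are resampled with replacement 10,000 times and the
0.025/0.975 quantiles of the resampled medians form the 95% CI. Percentile
rather than BCa intervals because the quantile definition is the direct
specification of the interval. One seeded generator per report; the seed is
recorded. Effect sizes are in units of the unit-norm discriminant
direction, so they are comparable across arms of the same model but not
across models.

## Kernel PLS regression

Dual-form KPLS with a Gaussian kernel. Per component: the score
t ∝ K_c·y_res is extracted from the centered (deflated) kernel, both kernel
and response are deflated by the projector (I − ttᵀ), and predictions use
the dual coefficients U(TᵀK_cU)⁻¹Tᵀy with the test kernel centered by the
training statistics. A linear kernel is retained solely as a test oracle
(full-component linear KPLS reproduces ordinary least squares on full-rank
data to 1e-6).

Defaults where the method leaves parameters open:

- **Kernel width σ**: median pairwise Euclidean distance among the
  normalized training Δ-vectors — scale-adaptive, deterministic, recorded
  per fit.
- **Components**: selected once by an inner leave-one-out sweep over
  1..min(10, n−2) on the first training fold, then held fixed across outer
  folds. The sweep exploits the nesting of KPLS truncations: one fit at the
  maximum count per inner fold yields predictions at every smaller count,
  since component contributions are additive.
- **Normalization** (predictor z-scores, response centering) is refit
  inside every cross-validation fold; the held-out sample never influences
  any training statistic.

Leave-one-out R² = 1 − Σ(y − ŷ_loo)²/Σ(y − ȳ)², which can be negative.
Requesting more components than the residual rank supports truncates with a
warning rather than failing.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset: cohort-specific multivariate log-normal concentrations for the 11
raw measures (block correlations: 0.30 within the methylation arm, 0.35
within the glutathione/redox arm, 0.10 across), with the ASD cohort's log
means shifted so redox markers (GSSG +0.52 log units, tGSH −0.27) separate
more than methylation measures (methionine −0.16). The derived ratios are
always recomputed, never sampled, so every generated table passes panel
validation by construction. The default log-mean levels are
plausible-magnitude plasma values; the covariance is fabricated, since true
inter-metabolite covariance cannot be known without the raw data, and is
documented as such.

Treatment arms draw pre-treatment panels from the ASD distribution and move
each participant's log-concentrations a configured fraction of the
ASD-to-TD gap (defaults 0.85 / 0.80 / 0.30 / 0.10 for the four arms, the
last emulating a small-but-nonzero placebo drift), plus per-participant
log-scale noise (0.35 of each measure's log sd). The behavior response is
ΔVABS = Σ cᵢ·Δmᵢ/scaleᵢ (+ optional tanh nonlinearity) plus Gaussian noise;
by default the noise is scaled so the link explains 50% of the response
variance within the generated arm. VABS scores are rounded to 0.1.

Default sizes are the motivating study's: 92 ASD / 82 TD case-control and
arms of 33, 8, 14, 19 (74 treated participants pooled). Under the default
configuration the fitted five-measure C-statistic lands around 0.95–0.98
with cross-validated sensitivity/specificity in the high 80s to low 90s —
a realistic operating regime for this kind of panel, chosen once and not
tuned to any particular number.

What the generator does **not** emulate: assay noise structure, age/sex
covariates, missing-data mechanisms, batch effects, or realistic
inter-metabolite kinetics. Passing tests on synthetic data therefore
demonstrate the correctness and statistical behavior of the *procedures*
(oracle agreement, null calibration, planted-signal recovery), not clinical
performance on real cohorts.

## Problem sizes and determinism

The exhaustive FDA search covers all C(15,5) = 3003 five-measure subsets in
a few seconds; KPLS subset sweeps are run over explicit candidate lists
(every sweep is O(C(m,k)·n²·LOO)). Every stochastic step — generation,
bootstrap, pipeline orchestration — flows from one integer seed through
splittable generators, and reports with the same seed are byte-identical.
Enumeration order is lexicographic in canonical measure order and ranking
ties break lexicographically, so search outputs are reproducible snapshots.

## Known limitations

- The fitted C-statistic used for subset ranking is optimistic by design
  (it matches the selection procedure being modeled); rely on the
  leave-one-out confusion metrics for honest classification accuracy.
- KDE-based error rates inherit bandwidth sensitivity; only the Silverman
  default is exercised by the test suite.
- Effect sizes depend on the unit-norm scaling of w and are not comparable
  across differently trained models.
- The regression's kernel width and component count are data-dependent
  defaults; no uncertainty is attached to R² estimates.
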