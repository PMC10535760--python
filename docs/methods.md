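# Methods

`lfnmr` implements a complete analysis chain for urinary metabolic
fingerprinting with a benchtop low-field (~80 MHz) ¹H NMR instrument in a
small two-group case–control design, together with a synthetic-data
generator used to validate every stage against known ground truth.  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Synthetic spectra

A spectrum is simulated as

```
I_i(x) = d_i · Σ_s c_is · (1/m_s) Σ_m L(x; μ_s + δ_sm + ε_is, γ_s) + b_i(x) + η
```

where `L(x; μ, γ) = γ²/((x−μ)² + γ²)` is the height-normalised Lorentzian
(absorption-mode lineshape; closed-form area `γ·[arctan((b−μ)/γ) −
arctan((a−μ)/γ)]` over `[a, b]`, used by the integral tests), `μ_s` the
signal's chemical shift, `δ_sm` its multiplet line offsets, `γ_s` the half
width at half maximum, `c_is` a log-normal per-subject concentration
(parameterised by arithmetic mean and CV), `d_i` a log-uniform per-sample
dilution factor, `ε_is` Gaussian chemical-shift jitter drawn per signal
per sample (all lines of a multiplet move together, as a shift change
moves the whole resonance while J-couplings stay fixed), `b_i` an optional
smooth baseline and `η` white noise.

Defaults mirror the study conditions this pipeline targets: 8 "sepsis"
vs 10 "control" samples, axis 0.05–9.00 ppm at a ~0.001 ppm grid, dilution
in [0.5, 2], jitter 0.003 ppm, noise 0.004 intensity units.  The default
signal panel is urine-like (lactate and alanine doublets — a 7 Hz coupling
spans 0.0875 ppm at 80 MHz — citrate, creatinine, a carbohydrate envelope,
urea, hippurate aromatics, formate), with fold changes of the informative
signals in the 0.8–1.5 range typical of urinary sepsis signatures.
`group_fold_change` multiplies the sepsis-group mean concentration, i.e.
it is the expected FC[sepsis/control] of that signal.  Line widths are a
free parameter (default HWHM 0.010–0.025 ppm); benchtop instruments vary
and no claim is made that the defaults match a specific spectrometer.

The single seed is expanded through `numpy.random.SeedSequence` into
independent substreams (dilution, concentrations, jitter, noise,
baseline) so that regenerating one ingredient leaves the others
bit-identical.

What the generator does *not* emulate: quantum-mechanical multiplet
structure and second-order coupling effects, relaxation-dependent line
shapes, peak-overlap changes with field strength, pH-dependent shift
drift, and realistic baseline chemistry.  Tests passing on these
synthetic spectra therefore demonstrate correctness of the algorithms
under the stated statistical structure, not instrument-level fidelity.

MS-like feature tables are generated separately: `n_informative` columns
separate the groups by a stated number of within-group standard
deviations, and a declared fraction (`latent_share`) of each informative
column's variance is carried by one latent group factor; passing the same
factor into two blocks creates the shared structure the two-block
decomposition is tested against (`generate_shared_blocks` additionally
reports the realized per-block variance fractions of the shared, unique
and noise parts).

## Preprocessing

**Peak picking** uses continuous-wavelet-transform ridge detection with
the Mexican-hat kernel (`scipy.signal.find_peaks_cwt`) over scales
0.002–0.05 ppm, SNR threshold 3 (SNR is the apex height over a robust
noise scale estimated from first differences).  Each ridge position is
snapped to the local apex; ridge artifacts sitting on monotone slopes
(frequent at broad scales near line tails) are discarded.  Peak scale is
attributed as the empirical half width at half maximum.

**Alignment** is cluster-based and segment-wise.  The reference spectrum
minimises the summed symmetric nearest-peak distance to all others (ties
break to the lowest index).  For each target, the pooled reference+target
peak list is recursively split at its largest gap (the single-linkage
two-cluster cut in one dimension), and every segment is shifted by the
integer lag maximising its FFT cross-correlation with the reference,
bounded by `max_shift` (default 0.05 ppm, which must exceed one grid
step).  Points vacated at segment edges repeat the boundary value, so no
artificial minima appear at segment joins; recursion stops below 32
points or when no adequate inter-cluster gap remains.

Aligning to one *real* spectrum stamps that spectrum's own shift errors
onto the entire cohort: the expected residual deviation from the true
line positions equals the reference's own mean absolute jitter, so no
single-reference scheme can cut the error from truth by half.
`align_spectra` therefore runs a second pass aligning every spectrum
(including the reference) against the average profile of the raw input
spectra, whose smeared peaks sit at the consensus positions
(≈ true centers to O(σ/√n)).  With 0.005 ppm jitter this reduces the mean
absolute peak-position error by 62–71% in the recovery experiments;
`align_clupa(refine=False)` retains the plain single-reference behaviour.

**Water exclusion** removes the 4.50–5.25 ppm region by default.

**Intelligent bucketing** splits each contiguous retained region
recursively at the deepest interior local minimum of the cohort-average
spectrum such that both children remain at least `min_width` (default
0.04 ppm) wide; a minimum must be strictly lower than at least one
neighbour, so constant stretches never split.  Bucket values are
per-sample trapezoidal integrals; adjacent buckets share their boundary
grid point, which makes the bucket integrals tile each region's total
integral exactly (conservation is tested at 1e−9 relative).  The bucket
count is an outcome of the data, not a target.  The vendor tooling whose
behaviour this reproduces is proprietary; equivalence beyond the stated
contract (boundaries at average-spectrum minima, minimum width) is not
claimed.

**PQN.**  Rows are first integral-normalised to the cohort-mean total;
the reference is the element-wise median profile across all samples (the
original default; a control-only reference can be supplied); each row is
divided by the median of its variable-wise quotients against the
reference.  The per-sample record keeps both factors; their product is
the estimated relative dilution, which correlates ≥ 0.95 with the planted
dilution in the recovery experiment (50 spectra, ≤ 10% informative
signals).  A global intensity rescaling of the input passes through the
output unchanged in shape (pqn(cX) = c·pqn(X)) with identical estimated
factors.  For the NMR path PQN is applied after bucketing; the generic
feature-table path offers log10 (zeros replaced by half the column's
smallest positive value) and mean-centering.

## Outlier screening (per-group PCA)

PCA is a mean-centered SVD; the retained component count defaults to the
number of eigenvalues above the mean eigenvalue.  Hotelling's T² uses the
retained scores over their eigenvalues; Q is the squared reconstruction
residual.  Two threshold families are provided:

* **training** (default): the screened samples are the ones the model was
  fitted on.  T² of a training sample follows (n−1)²/n·Beta(A/2,(n−A−1)/2)
  exactly under normality, so the beta quantile is used; for Q the same
  beta tail shape is applied at Box's moment-matched effective degrees of
  freedom (g = θ₂/θ₁, h = θ₁²/θ₂ from the residual eigenvalue moments).
* **new**: the classical limits for samples outside the training set —
  A(n−1)/(n−A)·F₁₋α(A, n−A) and Box's g·χ²₁₋α(h).

The F-form applied to training samples under-flags (≈0.043 at α = 0.05,
n = 200), which is why the training mode exists; in the null calibration
experiment the training-mode T² and Q rates are 0.050 within Monte-Carlo
error.  Box's approximation was preferred over Jackson–Mudholkar for
numerical robustness at the very small per-group n this design has.  The
calibration experiment uses a covariance with well-separated leading
eigenvalues: under an isotropic null the "top A components" are not
identifiable and no subspace-based threshold is exactly calibrated.

## PLS2C classification

The class response is coded +1 (sepsis) / −1 (control) and centered; the
symmetric coding keeps the decision threshold at 0 independent of class
sizes (class-proportion coding can be emulated by supplying coded
responses).  NIPALS deflates X only; the regression vector is
`b = W(PᵀW)⁻¹q`; ŷ ≥ 0 classifies as sepsis (ties to the positive class,
documented).  The implementation agrees with an independent PLS
regression oracle to machine precision and reduces to ordinary least
squares for one component on one variable.

**Metrics.**  MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn)),
defined as 0 when a marginal is empty; AUC is the Mann–Whitney statistic
with ties counted ½.

**Cross-validation** is stratified 5-fold repeated 20 times; per repeat
the out-of-fold predictions are pooled into one confusion matrix (MCCcv)
and one score set (AUCcv).  The summary across repeats is the mean by
default and the median is also available: with repeat-level pooled
confusions the two can differ, and published analyses do not always state
which aggregation they used.  Centering is re-estimated inside every
training fold.

**Component selection** takes the first local maximum of the summarized
MCCcv curve (plateaus resolve to the smaller A; a curve still rising at
A_max selects A_max, otherwise strictly rising sequences would never
yield a model), subject to passing the permutation test at α = 0.05.

**Permutation test**: the class response is permuted uniformly (default
1000 permutations), the full pipeline — including cross-validation for
the cv-statistics, with the same fold seed as the observed analysis so
the null matches the design — is recomputed, and
p = (1 + #{perm ≥ observed})/(1 + n_perm), never below 1/(n_perm+1).
Null p-values are uniform (KS-checked in the calibration experiment).

**Post-transformation** rotates the A-dimensional score space so that the
fitted response lies entirely on one predictive score t_p ∝ T q; the A−1
remaining directions are orthonormalised within span(T) against t_p and
are therefore exactly uncorrelated with ŷ.  Fitted values are unchanged
(tested to 1e−10).  The predictive block t_p p_pᵀ (p_p the regression of
centered X on t_p) is the rank-1 part of X carrying the between-group
separation, used as the second block of the two-block analysis.

**VIP**: VIP_j = √(p·Σ_a q_a² t_aᵀt_a (w_ja/‖w_a‖)² / Σ_a q_a² t_aᵀt_a);
Σ_j VIP_j² = p identically.

## Stability selection

Binary matrix sampling draws Bernoulli masks over observations
(p = 0.7) and predictors (p = 0.5); 500 sub-training sets yield 500
PLS2C sub-models fitted at the globally selected component count (capped
by each sub-problem's rank; re-selecting A per sub-model would be
unstable at this n).  A sampled predictor is *selected* when its VIP
exceeds 1, the conventional relevance cut.  Draws leaving fewer than two
samples of a class or fewer than two predictors are rejected and redrawn.
Significance: the whole procedure is re-run once with a permuted response
on the same masks; predictors whose selection frequency exceeds the
(1−α) quantile of the null frequencies form the relevant set (the number
of null reruns is configurable; one rerun gives p null frequencies, which
is already a p-sized null sample).  Out-of-bag predictions are aggregated
per sample by the median score and thresholded at 0 for the out-of-bag
MCC.  On the recovery design (8 informative of 84 variables at 2 sd,
20 + 20 samples) sensitivity and precision reach ≥ 0.8.  Because the
variable masks are positional, permuting columns changes which subsets
co-occur in sub-models: selection frequencies are order-invariant in
distribution, not realization by realization.

## Two-block joint/unique decomposition

**OPLS-W2A.**  Parallel components come from Wold's Mode A inter-block
iteration (u → w₁ → t₁ → w₂ → t₂ until the relative score change falls
below 1e−10, at most 500 iterations), which maximises the inter-block
score covariance; both blocks are deflated by their own score/loading
pair after each component.  The alternating update is exactly power
iteration on X₁ᵀX₂, so it is warm-started at that matrix's leading
singular pair and the loop then polishes the fixed point — without the
warm start the iteration stalls when the leading singular values nearly
tie, precisely the situation under a permutation null.  After `k_par`
components, each block's deflated remainder is projected onto the
orthocomplement of its parallel scores and its dominant principal
directions become the orthogonal components.  Variance bookkeeping per
block: parallel = total − remainder after projection, orthogonal = the
retained singular values squared, residual = the rest; the three sum to
one exactly.

**oCPCA.**  The block is projected onto the orthocomplement of the
constraint scores (e.g. the parallel scores — the constraint is on the
score space, since the unique variation of interest is sample-wise) and
the remainder is decomposed by SVD; with no constraints this is plain PCA
of the (centered) block.  Variance fractions are reported against the
original block's total, and the retained count defaults to eigenvalues
above the mean eigenvalue ("eigenvalue structure" rule), overridable.
This construction is a reimplementation from the stated outputs (parallel
and orthogonal components, per-part variance percentages, correlation
with an external predictive component), not a certified replica of any
specific prior code.

On constructed blocks sharing one latent factor (35% shared, 35% unique,
30% noise), the parallel score correlates ≥ 0.9 with the factor and the
first oCPCA component recovers the planted unique fraction within 5
percentage points.

## Univariate statistics

The cohort-descriptor tests are a pooled-variance Student t-test (with a
summary-statistics entry point, which reproduces printed cohort-table
p-values such as 0.68 and 0.41 from means/SDs alone — Welch's version
does not), the chi-squared test on the 2×2 table without continuity
correction (reproducing 0.81 for 2/8 vs 3/10), and the Mann–Whitney test.
Mann–Whitney uses the exact U distribution for small untied samples and
the tie-corrected normal approximation otherwise (`method="auto"`): at
n = 8 vs 10 the exact distribution is what published per-ROI p-values
match.  Per-ROI statistics report AUC (sepsis scored high, the same
implementation as the classifier metric), the Mann–Whitney p-value and
the fold change of group medians, undefined (with a warning) when a
median is non-positive.  The LF/HF correlation map computes all pairwise
Pearson coefficients between two tables on the same samples, two-sided
p-values by the exact t transform, Benjamini–Hochberg q-values over all
defined cells, and a significance mask at q < 0.10; constant columns are
masked out with a warning.

## Pipeline

`lfnmr run` drives simulate → preprocess → qc → fit → stability →
twoblock → stats from one YAML configuration.  Artifacts carry a
configuration hash and per-file checksums in a manifest; identical
configurations produce byte-identical runs (no timestamps).  The demo
configuration uses a reduced permutation count for the cross-validated
statistic; the full 1000-permutation analysis is the library default.

## Problem sizes of the validation experiments

Recovery and calibration experiments run at deliberately compact sizes
chosen to make their Monte-Carlo error small relative to the asserted
margins: 18–50 spectra of ~9000 points for alignment/PQN, 20 random
4000-point configurations for bucketing, 200 replicates × 99 permutations
(n = 40, p = 10) for permutation calibration, 500 sub-models for
stability recovery, 40 × 60/50 blocks for the two-block recovery, and
1000 replicates at n = 200 for the T²/Q calibration.

## Known limitations

* Intelligent bucketing and oCPCA reimplement behaviour whose original
  implementations are proprietary or described only by name; they satisfy
  the documented contracts but are not bit-compatible replicas.
* Alignment shifts are integer grid lags; sub-grid-step alignment error
  remains.
* The stability-selection null uses one permuted rerun by default;
  raising `n_null` sharpens the threshold at proportional cost.
* The out-of-bag and cross-validated performance estimates share all the
  usual small-n caveats: with 8 + 10 samples their sampling variability
  is large, which is visible in the repeat-level MCCcv distributions.
* The T²/Q training-mode thresholds are exact under normality for T² and
  moment-matched for Q; heavy-tailed data will not be calibrated.
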