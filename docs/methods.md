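# Methods

This note documents the models and procedures implemented in `twotask2p`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Setting and data model

The pipeline analyzes populations of neurons recorded with two-photon
calcium imaging while the same animal performs two visual decision tasks in
different physical contexts — a virtual T-maze navigated on a spherical
treadmill ("TM", ball context) and a steering-wheel task performed on a
platform ("SW", wheel context) — plus passive conditions on each apparatus
and optionally a hybrid task (wheel apparatus, maze visual scene, sharing
the wheel context). Inputs are per-neuron deconvolved activity traces at
10 Hz per plane, trial tables, ROI pixel × time fluorescence patches with a
neuropil surround (surround ≈ 5× the cell's pixel count), movement traces,
and widefield retinotopy maps. Upstream steps — motion correction, cell
detection, signal extraction, spike deconvolution, cross-day ROI matching,
wheel-movement detection, video processing — are out of scope; their
outputs are inputs here.

## Isolation distance

Per neuron and condition, cell and neuropil pixel rows are stacked into one
pixels × time matrix; the mean time course across all stacked pixels is
subtracted from every row; the centered matrix is reduced by SVD and each
pixel is summarized by its score on the first component. The statistic is
the closed-form Bhattacharyya distance between two Gaussians fitted to the
cell-pixel and neuropil-pixel scores,

    D = 1/4 (m_c - m_n)^2 / (v_c + v_n) + 1/2 ln[(v_c + v_n) / (2 sqrt(v_c v_n))],

which accounts for the typically smaller variance of the neuropil
distribution and is invariant to a common rescaling of the fluorescence.
Neurons with D > 0.3 (strict) are classified active.

Numerical choices:

- *Centering.* "Subtract the mean over time" is implemented as removing the
  across-pixel mean time course from every row (default), which cancels
  fluorescence shared by cell and surround and leaves the contrast the
  statistic is after; per-pixel temporal centering is available behind
  `center="per_pixel"`.
- *Gaussian form.* The two-Gaussian closed form on (mean, variance) of the
  score groups is used rather than an empirical-histogram estimator, which
  is unstable at realistic pixel counts (tens of cell pixels).
- *Sign.* The principal component is oriented so the mean cell loading is
  ≥ the mean neuropil loading; the distance itself is sign-invariant.
- Variances use ddof = 1; an identically zero centered matrix or fewer than
  two pixels in either compartment are errors.

Neuropil correction of traces is `cell − c · neuropil` with c = 0.7 by
default, the midpoint of typical per-cell estimates (~0.6–0.8); per-cell
estimation of c is upstream.

## Task specificity

Activity summaries (isolation distance or mean deconvolved rate — the two
give similar results; the pipeline stage uses mean rate) are compared
across conditions with Spearman rank correlation (average ranks for ties;
exact enumeration p-values for n ≤ 10, t approximation above). Neurons are
categorized by strict thresholding in the two tasks (both / TM-only /
SW-only / neither) and by the preference index (a − b)/(a + b), undefined
(NaN) at 0/0. Within- vs across-context correlation sets are compared with
a one-tailed two-sample t test (within > across) or one-way ANOVA across
labeled groups. Cross-day comparisons resolve neurons to the union of ids
across the day pair, with zero activity for a cell not detected on one day
— the faithful reading of activity-based segmentation missing inactive
cells.

The silent-population simulation makes explicit why across-task
correlations over all neurons are uninformative when a silent majority is
included: each neuron draws a once-per-neuron baseline b ~ s·LogNormal(0, 1)
present in both tasks plus independent per-task Gaussian noise; active
neurons add a fixed amplitude in their preferred task(s). With ≥ 95% silent
neurons and the baseline dominating the noise, the across-task Pearson r
exceeds 0.99 even when the active minority is perfectly exclusive. The
shared-baseline noise model is this package's construction (only the
resulting correlation is externally anchored); all knobs are exposed. The
silent fraction default (0.97) is a configurable choice consistent with
anatomy-motivated arguments, not a measured value.

## Encoding models

Single-neuron activity is regressed on a design matrix with one indicator
column per frame lag around each event (stimulus onset by side, −50..500 ms;
choice by direction, −150..400 ms; reward, −100..400 ms) and one lagged copy
per 250 ms step of each continuous signal (−500..500 ms; wheel velocity
split into nonnegative clockwise/counter-clockwise channels, ball forward
velocity, turning). Window edges round *outward* to the 10 Hz frame grid
(−50 ms → −1 frame), each column carries metadata (predictor, side, lag),
overlapping event windows add, and columns are z-scored with an unpenalized
intercept — a shared penalty across heterogeneous predictors is only
meaningful on a common scale. Sides that never occur produce no columns.

The ridge solution minimizes ‖y − Xw‖² + λ‖w‖² over penalized coordinates
(normal equations; the intercept is excluded from the penalty). λ is chosen
per neuron from {0.01, 0.05, 0.1, 0.5, 1} by 11-fold cross-validation with
*contiguous* time-block folds — neural traces are autocorrelated, so random
frame folds would leak — maximizing the mean held-out variance explained;
final weights are refit on all data and the reported CV variance explained
comes from held-out predictions concatenated across folds. Per-session λ
selection is available by fitting one model to a stacked population.
Neurons with CV VE > 8% in a task count as encoding task-relevant
variables. Only the linear (squared-error) fit is implemented. The
position–heading style maze model is represented by raised-cosine basis
functions over corridor position and heading entered as design columns — an
explicit simplification (`raised_cosine_basis`), not a port of the original
model.

## Combined-conditions choice probability

Per-trial activity is the mean deconvolved trace over [t_start, t_choice)
(stimulus presentation through motor execution of the choice; half-open
frame window). Trials flagged as stimulus repeats after errors and trials
with reaction time < 125 ms (strict) are excluded; a session needs ≥ 10
remaining trials of each choice, and validity is a typed outcome rather
than an exception. Within each stimulus condition c (contrast × side; zero
contrast is a single condition, giving nine conditions for the
{0, 6, 12, 25, 50}% set — zero-contrast inclusion is switchable by simply
omitting those trials), U_c counts (R-trial, L-trial) pairs won by the
R-trial with ties as ½ (Mann–Whitney convention, computed via average
ranks). The pooled statistic is

    ccCP = 2 · (Σ_c U_c) / (Σ_c n_R(c) n_L(c)) − 1  ∈ [−1, 1],

negative when activity is higher on left choices. Significance: choice
labels are shuffled within condition (preserving per-condition class
counts, hence robust to condition imbalance), 1,000 times by default, with
the two-sided add-one-smoothed p = (1 + #{|ccCP*| ≥ |ccCP|})/(1 + N) — never
exactly zero. Cross-task comparison of ccCP uses only neurons with
isolation distance > 0.3 in both tasks and flags sessions with < 10 such
neurons invalid.

## Behavior and movement

The psychometric model is P(right | c) = γ_L + (1 − γ_L − γ_R) Φ((c − μ)/σ)
with signed contrast c, bias μ, slope σ, lapses γ_L, γ_R (logistic core
available). Fitting maximizes the Bernoulli likelihood with multi-start
L-BFGS-B under bounds (σ ∈ [0.1, 200], lapses ∈ [0, 0.45], μ ∈ [−100, 100]);
estimates pinned at a bound (e.g., step-function data) are flagged. The
cumulative-Gaussian-with-lapses form is a standard choice; the original
fitting reference did not pin down the functional form, so it is
configurable.

Movement modulation is the Pearson correlation between a neuron's trace and
a movement signal, both smoothed with a 1-s s.d. Gaussian (truncated at
±4 s.d., renormalized, reflective boundaries — mean-preserving) for the
running analysis; smoothing of one or both series is configurable for
face/pupil-style traces. Movement traces recorded at higher rates are
block-averaged onto the frame grid. Significance uses a circular-shift
null: correlations at all T shifts are obtained at once by FFT
cross-correlation, N = 1,000 shifts are drawn uniformly on [1, T − 1], and
the two-sided add-one p is computed as above. Shifts are applied after
smoothing.

## Field sign

Azimuth and elevation maps are optionally Gaussian-smoothed (default
σ = 2 px), gradients taken by central differences (one-sided at borders),
and the per-pixel sign is sin(angle(∇elevation) − angle(∇azimuth)) — bounded
in [−1, 1], NaN where a gradient vanishes, and oriented so the identity
mapping (azimuth along x, elevation along y) is +1; the opposite global
convention differs only by an overall sign and does not move the reversal
borders that delineate areas. Regions are 4-connected components of
|sign| > 0.3, labeled positive and negative separately. Hemodynamic
correction of widefield movies (heartbeat-band filtering) is upstream.

## Synthetic sessions

The generator is a pure function of (config, seed) and emulates exactly the
statistical structure the analyses assume. Each neuron draws a latent class
(TM-only / SW-only / both / silent; default fractions 0.40/0.35/0.15/0.10,
reflecting an imaged population in which over half of active neurons are
single-task), a response gain (log-normal, σ = 0.3), a shared baseline
(log-normal, scale 0.05 a.u.) present in every condition, and independent
signed choice preferences per task. Traces are kernel-convolved event
responses — Gaussian bump kernels (stimulus: amplitude 1.0, latency 0.2 s,
width 0.3 s; choice: 0.8/0.1/0.25 with amplitude scaled by (1 ± preference)
per direction; reward: 1.2/0.15/0.3) at trial events for neurons matching
the condition's context, spontaneous 0.3 Hz Poisson events in passive
conditions — plus baseline plus independent Gaussian noise (s.d. 0.02,
optionally AR(1)-colored; the trial-to-trial correlation structure of real
traces is not asserted, so the coefficient is an exposed knob defaulting to
white), rectified at zero. Deconvolved activity is simulated directly as
nonnegative amplitudes; calcium-indicator kinetics and deconvolution are
deliberately not modeled.

Trials draw contrast uniformly from {0, 6, 12, 25, 50}% with a uniform side
for nonzero contrast; choices are Bernoulli from the configured
psychometric curve (default bias 0, slope 10, lapses 0.05); reward is
choice = side, with zero-contrast trials rewarded randomly with probability
0.5 (configurable — the rule at zero contrast is a convention); reaction
times are log-normal (median 0.8 s, σ_log 0.4); after an error the stimulus
repeats with probability 0.5 and the trial is flagged. ROI patches are a
shared neuropil time course plus, for cell pixels, known per-pixel weights
times a temporal signal whose variance relative to the background is the
`separation` knob — at 0 the compartments are statistically identical, and
the per-pixel PC1 loadings are analytically known. Retinotopy layouts are
piecewise-linear maps with known signs ("single-non-mirror",
"mirror-pair"); running and wheel traces are smoothed noise (wheel with
signed turn pulses at choices).

What passing tests do and do not show: the generator matches the analyses'
assumptions by construction (kernel-linear responses, exclusive context
classes, exchangeable trials), so green tests demonstrate correctness and
calibration of the *methods* — not that real parietal data satisfy those
assumptions. Real traces have slow drift, correlated noise across neurons,
overlapping ROIs, and nonstationary behavior that the generator does not
emulate.

## Problem sizes and runtime choices

Test and pipeline defaults are sized for quick iteration on one CPU: 40–80
neuron sessions of 2–6 minutes per condition, 10–20 seeds for
median-over-seeds properties, 2,000 null neurons for the type-I-error
calibrations of both permutation tests, and 100 seeds × 10,000 neurons for
the silent-population simulation. The pipeline caps per-neuron encoding
fits at 30 neurons per task by default (`max_encode_neurons`). Kernel-
recovery tests use generating kernels whose support fits inside the fitting
windows, so the indicator model is well-specified; with the wider default
kernels, truncation at the window edge biases the recovered shape — a
property of windowed encoding models generally, worth remembering when
choosing windows for real data.

## Known limitations

- Per-cell neuropil coefficients, GLM (non-Gaussian) encoding fits, spike
  history/coupling terms, population choice decoding, and atlas
  registration of sign maps are not implemented.
- The exact Spearman p-value enumerates all n! pairings and is only used
  for n ≤ 10; at n = 10 it costs a few seconds.
- The position–heading maze model is a raised-cosine simplification, not
  the original model.
- Session invalidity (too few trials or too few both-active neurons) is
  reported, not raised; callers must check the typed result.
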