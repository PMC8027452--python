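# Methods

This note documents the models implemented in `coeruleus`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Neuromelanin signal quantification (`nms`)

A nucleus is quantified against a reference region on a shared voxel
lattice. The anatomical template is grown by `layers` iterations of
one-voxel morphological dilation (face-adjacent 6-connectivity by
default, 26-connectivity available) to absorb individual variation in
where nucleus voxels fall; the defaults are 3 layers for the LC and 1
for the larger VTA/SNc. The dilation is performed in voxel space and
ignores anisotropy (the phantom lattice is 0.5 x 0.5 x 2 mm).

The peak is the intensity argmax over the dilated search region, ties
broken to the lowest (k, j, i) index for determinism, and it is reported
whether the peak falls inside the undilated template (a quality check,
not a failure). For each fraction f in {0.5 ... 0.9} the nucleus set is
every search-region voxel with intensity >= f x peak — the closed
inequality guarantees the peak itself survives at f = 1 — excluding any
voxel shared with the reference mask, which preserves the disjointness
the contrast assumes. The contrast (N - C)/(N + C) applies the ratio to
the means (not a mean of per-voxel ratios); it is scale-invariant and
lies strictly inside (-1, 1) for positive images.

Note that when the nucleus hyperintensity is only ~15% above background
— the realistic regime — thresholds at small fractions of the peak lie
below the background level, so the 50-80% masks may coincide (the whole
search region survives) while the 90% mask shrinks sharply. This
mirrors the tiny high-threshold mask volumes seen in real data and is
not a bug.

## Physiological-noise separation (`physio`)

Brainstem BOLD is modeled as slow activation-related signal + one
periodic (cardiorespiratory) component + white noise:

* state: a random-walk scalar (slow signal, process variance `q_walk`)
  stacked with one 2-dimensional resonator per periodic rotating by
  angle 2 pi f_t TR per scan (process variance `q_osc`);
* measurement: the sum of the walk and each resonator's first
  coordinate, plus N(0, `r_meas`) noise.

A forward Kalman pass and an RTS backward pass give the full-data
posterior; the cleaned component is the smoothed walk, the periodic
component the summed smoothed resonator coordinates, and the residual
the exact remainder, so the three always add back to the input. One
periodic (no harmonics) is the default; harmonics are available via
`n_periodics`.

The physiological frequency trajectory is estimated first by a
deterministic grid tracker: a Hann-windowed local periodogram on a
uniform grid of candidate frequencies (default 21 points across the
band, window ~4 cycles of the slowest candidate), smoothed by a sticky
first-order transition prior (stay probability 0.98) and read off as
the forward-posterior argmax. This replaces an interacting-multiple-
models filter on purpose: it is simpler, deterministic and testable,
and no IMM parameters were available to match. The default search band
(0.2-0.5 Hz, respiration) is a configuration choice, clipped just below
Nyquist when TR = 1 s.

Noise variances are chosen by maximizing the Kalman innovation
likelihood over a small multiplicative grid anchored at the sample
variance, with one refinement: among grid points within 2 log-likelihood
units of the optimum, the smallest resonator process variance wins.
Under a tone-free input the likelihood is nearly flat in `q_osc` and an
unconstrained maximizer lets the resonator soak 1-3% of white noise;
the parsimony rule keeps the null periodic fraction below 1% while a
genuine tone separates candidates by far more than 2 units.

Where cleaning helps: a 0.2-0.5 Hz tone is nearly orthogonal to ~45 s
block regressors, so removing it barely changes activation-GLM betas.
It matters on the connectivity path — a tone in the seed series
corrupts the deconvolved neural estimate and hence the PPI interaction
regressor (errors-in-regressors attenuation) — which is exactly where
the pipeline applies it.

## Cue-reactivity GLM (`glm`)

The task is an alternating two-condition block design; the default
schedule mirrors the cue-reactivity protocol (six blocks per condition
per run, 45 s block cycle beginning with a 2 s fixation cross followed
by a 36 s picture period; TR = 1 s, 540 scans). The regressor models the
36 s picture period; the fixation cross is unmodeled baseline.

The HRF is the standard double-gamma (response peak 6 s, undershoot
16 s, dispersions 1, response:undershoot ratio 6, 32 s kernel),
normalized to unit sum so a sustained unit boxcar plateaus at 1.
Boxcars are convolved at 0.1 s resolution and sampled at scan times. A
128 s discrete-cosine high-pass basis and the six motion parameters
enter as nuisance columns; the intercept is last. For scan-grid
convolution (PPI regressors, simulation) the kernel is binned per TR —
the exact discretization for a signal piecewise-constant over scans —
which also keeps the convolution operator full rank.

First-level fits use two-pass AR(1) prewhitening: OLS residuals give a
single lag-1 autocorrelation pooled across voxels (clipped to
(-0.99, 0.99)), both data and design are filtered (first row scaled by
sqrt(1 - rho^2)), and the whitened OLS gives betas and residual
variance with df = T - rank(X). For rho = 0 this reduces exactly to
OLS. Rank-deficient designs are rejected naming the collinear columns
(pivoted QR).

Group inference: voxelwise one-sample t over subject contrast maps
(zero-variance voxels flagged and reported as signed infinity), and
cluster-extent FWE by sign-flip permutation: 26-connected suprathreshold
clusters of the two-sided p < 0.001 t map; each permutation flips whole
subjects' signs, and a cluster's corrected p is the fraction of
permutations (identity flip included, so p >= 1/(n_perm + 1)) whose
maximum cluster size reaches its own. Permutation replaces random-field
theory deliberately: it is exact under sign exchangeability and needs
no smoothness estimate. Note the permutation needs the subject maps,
not just the observed t map, so `cluster_fwe` takes the N x V contrast
matrix.

## Generalized psychophysiological interaction (`gppi`)

The seed series (mean over seed voxels after cleaning and
mean-correction) is deconvolved by ridge-regularized least squares,
`min ||y - Hn||^2 + lambda ||Dn||^2`, with H the HRF convolution
operator on the scan grid and D a first-difference penalty; lambda
defaults to a generalized-cross-validation choice over a log grid
(1e-4 to 1e2). This is a transparent, testable stand-in for toolbox
deconvolution schemes; in the noise-free small-lambda limit
deconvolution followed by reconvolution is the identity.

The interaction regressor per condition is the HRF convolution of the
(mean-corrected) neural estimate times the condition's block indicator
sampled on the scan grid — the standard reading of "multiplied by the
blocks of interest" — and the gPPI design contains psychological
regressors, the observed seed series as physiological regressor, one
interaction regressor per condition, nuisance and intercept, fit with
the same AR(1) machinery. The gPPI measure is the drug - neutral
interaction-beta difference. Including the task regressors is what
separates connectivity from co-activation; the tests plant
condition-independent coupling with equal task amplitudes and verify
the interaction contrast stays at zero while the physiological beta
does not.

## Statistics (`stats`)

Partial correlation residualizes both variables on [1, covariates] and
correlates the residuals; p is two-tailed from t = r sqrt(df/(1 - r^2))
with df = n - 2 - k. Adjusted group differences report the group
coefficient's t from the least-squares fit on [1, group, covariates];
with no covariates this equals the pooled-variance two-sample t
exactly. The demographics table uses the plain two-sample t and the
Pearson chi-square without continuity correction (df = 1). The
threshold-robustness profile repeats the partial correlation per
fraction-of-peak mask and reports raw per-threshold p values with the
test count alongside — no multiple-testing correction, replicating the
reporting convention of the analysis it implements. Sex is coded
female = 1 (arbitrary but fixed).

## Synthetic data (`synth`)

The generators ARE the stated world; their defaults encode the study's
published conditions and are not tuned.

* Neuromelanin phantom: 16 x 48 x 48 lattice of 2 x 0.5 x 0.5 mm
  voxels; background 100 a.u.; nuclei are isotropic Gaussian bumps in
  millimetres truncated at 3 decay scales (LC: decay 1.2 mm, amplitude
  1.15; VTA/SNc: decay 1.8 mm, amplitude 1.10), smooth and unimodal so
  fraction-of-peak thresholds are well defined; the SCP reference box
  sits at background; additive Gaussian noise (sd 2 a.u.; Rician
  magnitude bias is out of scope). The group effect adds 0.05 to the LC
  amplitude for users only. One fixed lattice is shared by all subjects
  (spatial normalization is out of scope).
* BOLD run: TR 1 s, 540 scans, six 45 s blocks per condition. Seed
  neural signal = task boxcars + AR(1) fluctuation (sd 1, lag
  correlation 0.5) — the fluctuation is what makes coupling
  identifiable, since the interaction regressor would otherwise be
  collinear with the task regressor. Target voxels carry a smooth
  Gaussian blob weight (peak 1 at the grid center): shared task
  response, extra drug response (0.5) at the blob, and coupling
  gamma_drug x seed x drug-indicator + gamma_neutral x seed x
  neutral-indicator (defaults 0.8 / 0.2) plus optional
  condition-independent coupling. All neural signals are HRF-convolved;
  a physiological sinusoid (0.3 Hz, amplitude 0.5, random phase),
  motion-locked nuisance (random-walk motion, amplitude 0.1) and white
  noise (sd 0.5) are added afterwards.
* Cohort: 44 users / 59 controls; age 46.5 +/- 7.2 vs 43.7 +/- 9.8;
  7/44 vs 15/59 women; AUDIT 4.8 +/- 5.7 vs 3.7 +/- 4.3; FTND
  3.6 +/- 2.8 vs 0.3 +/- 1.2 (AUDIT/FTND truncated at 0); CCQ marginal
  40.0 +/- 16.2. Per-subject coupling contrasts are normal (sd 0.2)
  around the BOLD defaults — a simple unimodal choice, since no
  distribution is prescribed — and craving is drawn jointly with the
  requested correlation (default 0.44) via a bivariate-normal
  construction, so the target correlation is exact in expectation.

What the generators do **not** emulate: k-space/scanner artifacts,
Rician noise, true motion displacement (motion enters only as a known
nuisance signal), spatial autocorrelation of noise, multi-site effects,
or anatomically realistic templates. A green end-to-end test therefore
establishes that the estimators are correct and calibrated on their
stated generative model, not that the published human effect sizes are
reproduced — no subject data are deposited, so those are out of reach
by construction.

## Numerical choices and degenerate inputs

* Peak ties: lexicographic lowest index. Empty search masks, empty ROI
  masks, N + C = 0, non-finite series, rank-deficient designs, zero
  pooled variance and zero marginals are hard errors with named causes.
* The AR(1) coefficient is clipped to (-0.99, 0.99); zero-variance
  voxels in the group t map yield signed infinities plus a flag rather
  than NaN.
* Kalman initialization: diffuse prior, 10 x max(series variance,
  measurement variance) on the diagonal; the batch-Gaussian oracle in
  the tests reproduces the same convention.
* Determinism: every stochastic step takes a seed (numpy Generator);
  identical configurations and seeds give byte-identical outputs, and
  every output file carries a hash of the resolved configuration.
  Re-running into an existing output directory requires the explicit
  overwrite flag.

## Known limitations

* The pipeline runs on a single shared lattice and performs no
  registration or resampling.
* One AR(1) coefficient is pooled across voxels per fit (a per-voxel
  option would be a straightforward extension).
* The frequency tracker assumes a single dominant physiological tone
  inside the search band; crossing tones (cardiac + respiratory in one
  band) are not disambiguated — the single-periodic model follows the
  analysis it implements.
* Cluster-level inference assumes sign exchangeability of subject
  contrast maps under the null, which the simulated cohorts satisfy by
  construction.
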