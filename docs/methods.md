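# Methods

This note records the models, parameter choices and numerical decisions
behind `hemiscope`, in the order the pipeline runs.  Nothing here states a
result the tests or `scripts/acceptance.py` do not themselves compute.

## Task model

The paradigm is a block design: equal rest and movement blocks of
`block_s` seconds (default 20), starting with rest, for `total_s` seconds
(default 360).  The boxcar is the package's central reference signal: it
is the GLM regressor, the correlation target for every envelope, and the
movement-block mask for %MVE.  Construction is exact (an indicator on the
time grid), so block structure never depends on filtering; durations that
do not tile into whole rest+move pairs, or steps that do not divide the
block length, are rejected rather than truncated.

## Glove kinematics

The glove signal is the average finger-extension angle in degrees
(0–90 after calibration), instructed by a 1 s visual cue.

* **Drift removal**: zero-phase 4th-order Butterworth high-pass at
  0.05 Hz.  Movement content sits near 0.5–1 Hz, so a 0.05 Hz cutoff
  removes sensor drift with negligible passband loss; the input must span
  at least two cutoff periods (40 s).
* **Resampling**: linear interpolation onto a 15 ms grid (the signal is
  smooth at movement rates, so higher-order interpolation buys nothing).
* **Movement count**: (maxima + minima)/2, ignoring extrema whose
  prominence is below 5% of the 5th–95th percentile range — raw extrema
  counting would count noise wiggles.  The count is invariant under
  amplitude scaling.
* **Compliance / MM_glove**: Pearson correlation of the envelope
  (|analytic signal|, 0.5 s moving average — one definition shared with
  the EMG path) with the boxcar, for the instructed and the inactive hand
  respectively.  A zero-variance envelope returns r = 0 with a warning so
  cohort tables never contain computation-induced missing cells.

## EMG processing

Surface EMG over the extensor digitorum communis of the hand contralateral
to the instructed hand, to detect task-locked isometric mirror
contractions.  The chain runs, in order: notch at 45 Hz and 90 Hz
(2nd-order IIR, Q = 30; scanner gradient artifacts), 4th-order Butterworth
high-pass at 10 Hz (movement artifacts), full-wave rectification, 4th-order
Butterworth band-pass 2–130 Hz.  All filters are applied forward–backward,
so envelope timing is unbiased; the sampling rate must be ≥ 260 Hz for the
130 Hz band edge.

Two definitions were genuinely open:

* **"average EMG signal"** for %MVE is the mean *absolute* amplitude of
  the preprocessed signal — the final band-pass re-centres the rectified
  signal, so a plain mean would be ~0 by construction.  The same statistic
  is applied to the task recording (movement-block samples only;
  configurable) and the MVE recording (full duration), so any common gain
  — electrode placement, skin conductance, muscle volume — cancels
  exactly.  This invariance is property-tested.
* **the correlated quantity** is the envelope of the preprocessed signal
  (not the raw signal), with the same envelope definition as the glove.

MM_EMG = r(T, E_EMG) · %MVE holds as a bitwise identity in the result
object.

## ROI analysis

* **Proportional threshold**: within a (segment, hemisphere) label, the
  k = floor(0.15·N) highest-beta voxels, minimum one voxel; an empty label
  is an error.  Ties at the threshold are broken by the lowest linear
  voxel index — determinism over elegance.  Ranking is by signed beta
  ("most active"), not magnitude.
* **Laterality**: both hemispheres of a segment are pooled before
  thresholding, then the selected voxels are counted per side; per-ROI
  mean betas instead use per-hemisphere selection.  LI is antisymmetric
  under swapping the lesion side and invariant under global scaling of
  the betas, both property-tested.
* **Hemisphere flipping** reverses the grid along the voxel axis that
  dominates the world x-row of the affine; an oblique affine with no
  dominant axis is rejected rather than guessed.  For atlases the label
  table's hemisphere column is swapped alongside, so lookups stay
  anatomically correct.  Flipping is an involution.
* **Smoothing** (voxelwise path only; ROI statistics run unsmoothed):
  Gaussian, sigma = FWHM/(2√(2 ln 2)) per axis in mm via the affine's
  voxel sizes; default 8 mm.
* **Block GLM** (a structural stand-in for a full first-level analysis,
  not a reproduction of any package's betas): per voxel, OLS of the
  signal on [boxcar, intercept, discrete-cosine drift terms below
  1/128 s⁻¹]; optional AR(1) prewhitening with a per-voxel lag-1
  coefficient estimated from OLS residuals.  The regressor is the raw
  boxcar — no hemodynamic convolution, appropriate for the fast-TR
  acquisition style it emulates and irrelevant to the estimator checks it
  serves.  Constant time series get beta 0 and a warning.

## Group statistics

* **rm-ANOVA**: classical univariate (sphericity-assumed) mixed GLM.
  Every within effect is isolated by projecting each subject's
  within-cell vector onto an orthonormal contrast basis (Kronecker
  products of per-factor contrasts); pooled between/within sums of squares
  of the projected scores give F with error term effect×subject(group).
  Group sizes may differ; the within main effects test the *unweighted*
  mean of group means (Type III convention, matching mainstream GLM
  software; an equal-n layout is verified against an independent Yates
  sums-of-squares oracle to 6 decimals, and the mixed case against
  pingouin).  Dfs are uncorrected by default with an optional
  Greenhouse–Geisser flag, which scales both dfs of a within effect by
  the epsilon of its projected covariance.
* **Wilcoxon against scale maxima**: zeros (observations at the maximum)
  are dropped (classic signed rank), exact null for ≤ 25 nonzero
  differences, continuity-corrected normal approximation above.  With many
  observations at a ceiling this is conservative; a `zero_method="pratt"`
  option keeps zeros in the ranking for sensitivity analysis.
* **Stepwise regression**: forward entry of the candidate with the
  smallest partial-F p if p < p_in (ties: lowest column index), then
  backward removal of any retained factor with drop-one p > p_out, worst
  first, iterated to a fixed point.  Numerically collinear candidates
  (condition number > 1e8) are skipped with a warning; a zero-variance
  outcome short-circuits to the empty model.  With p_out = p_in the
  procedure reduces to pure forward selection and matches an exhaustive
  enumeration oracle.
* **Voxelwise group test**: pooled-variance two-sample t per voxel after
  smoothing; the family-wise threshold is the (1−α) quantile of the
  max-|t| distribution over permutations of the group labels (identity
  labeling included, slightly conservative).  This is a self-contained,
  assumption-light corrected threshold; output metadata records the
  correction, α, FWHM, permutation count and seed.

## Synthetic data: what it emulates, and what it does not

All randomness flows from one explicit seed (per-component substreams via
`SeedSequence`); identical calls are byte-identical on disk (volumes are
written uncompressed so bytes cannot depend on compression timestamps).

* **Glove**: sinusoidal flexion–extension inside movement blocks with the
  commanded amplitude cycling through three levels (30/60/90°), plus slow
  sinusoidal drift (5°, 0.005–0.02 Hz) and white sensor noise (0.25°).
  The default movement rate is 0.5 Hz — a full flex–extend cycle spanning
  2 s — which puts counted movements near 90 per 6-minute task, the range
  observed for compliant subjects; the visual cue itself cycles at 1 Hz.
  The inactive hand receives `mirror_gain` times the movement component
  plus its own drift and noise.
* **EMG**: a unit-RMS Gaussian carrier band-limited to 20–120 Hz (so the
  preprocessing chain attenuates task and MVE recordings identically),
  amplitude-modulated by the boxcar at `target_pct_mve` percent of the
  MVE amplitude with a 2% resting tone, plus pure 45/90 Hz sinusoidal
  artifacts and sub-10 Hz drift.  Real gradient artifacts have harmonic
  structure and real EMG bursts have onset dynamics; neither matters for
  the estimators under test.
* **Atlas/betas**: a mirror-symmetric 12-label block atlas (each segment
  ≥ 20 voxels so the 15% selection is non-degenerate); beta volumes place
  an "active" voxel budget split between hemispheres as k(1±LI)/2 at
  amplitude `effect` over background noise, making the expected recovered
  LI equal the target up to counting resolution.
* **Cohort tables**: ROI activations share a subject-level global gain
  (SD 0.25) over per-ROI variation (SD 0.15), giving inter-ROI
  correlations near 0.73 — real ROI means are strongly correlated through
  global activation amplitude, which is precisely why the proportional
  threshold exists.  Clinical scores emulate a moderately-to-well
  recovered cohort: FM ≈ N(60.5, 5.6) clipped to [0, 66], ARAT at its
  ceiling of 57 for ~75% of patients, %NHPT ≈ N(69, 22.5) truncated
  positive.  Lesion sides alternate L/R to exercise flipping.  An optional
  linear FM-on-ROI dependence supports power checks of the stepwise
  regression.

Because the generator uses idealized components (stationary noise, exact
block timing, no motion, no lesion geometry), passing recovery tests shows
the estimators are correct and calibrated under their stated assumptions —
not that real recordings meet those assumptions.

## Known limitations

* The null empty-model probability of stepwise regression with k
  candidates at entry p < 0.05 is 1 − P(min_j p_j < 0.05), roughly
  1 − (1−0.05)^k_eff; with 12 candidates it exceeds 10% unless the
  predictors are almost perfectly correlated.  Under the default cohort
  (inter-ROI r ≈ 0.73) the measured empty rate is ~0.8.  A screening
  procedure that must stay empty under the null at a guaranteed rate needs
  an adjusted entry threshold, which the classical procedure implemented
  here does not use.
* The ANOVA assumes a complete within design; missing cells are an error
  by design (listing the offending subjects), not silently dropped.
* The voxelwise permutation test assumes exchangeable subjects under the
  null; it does not model spatial covariance beyond the smoothing kernel.
* Problem sizes in the test-suite and acceptance script (atlas grids of
  12³–24³ voxels, 20-seed recoveries, 500-replicate calibrations) are
  desk-scale choices: large enough for the stated tolerances, small enough
  to run in minutes.
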