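# Methods

## Velocity decoding and the phase convention

Phase-contrast MRI stores through-plane velocity in the voxel phase. We use
the common linear scaling v = VENC·φ/π with φ ∈ (−π, π], positive toward the
reader; φ = π maps to +VENC. Velocities beyond ±VENC alias: the phase wraps
and the decoded velocity jumps by 2·VENC.

### Noise masking and segmentation

The noise floor is the mean time-averaged magnitude of a user-supplied
static-tissue region, optionally plus k standard deviations (`k`, default 0).
Voxels at or below the threshold are excluded; the vessel is the 4-connected
supra-threshold component containing the seed voxel (or, without a hint, the
component with the highest mean magnitude). The end-to-end pipeline
(`StudyConfig.noise_k`) defaults to k = 3: magnitude noise is Rician, so
roughly half of the background exceeds its own mean, and a bare-mean
threshold cannot separate background from vessel rim at finite SNR — a few
background voxels then join the vessel component and can corrupt peak-voxel
selection. Three SDs suppresses this while keeping all lumen voxels.

An optional correction subtracts the mean static-ROI phase per cardiac phase
before decoding (residual eddy-current offset). It is off by default: a
constant phase offset cancels in PI only when it is removed, but most 2D
cine reconstructions already do this at the scanner, and applying it twice
would bias low-flow voxels.

### Aliasing correction

The correction operates on the single peak-voxel waveform in time: anchor at
the sample nearest the waveform median, walk outward, and whenever a
consecutive step exceeds VENC in magnitude shift the later sample by the
multiple of 2·VENC that minimizes the step. This is deterministic,
idempotent on unwrapped data, and exact for a single wrap; waveforms beyond
2×VENC are rejected at simulation time because a double wrap is ambiguous.
The median anchor assumes the majority of the cycle is unwrapped, which
holds when only the systolic peak exceeds VENC.

### Pulsatility measures

The analyzed waveform is the one voxel with the highest time-averaged
(signed, unwrapped) velocity — the centerline voxel under laminar flow, and
the voxel most robustly inside the lumen across the cycle. v_max, v_min and
v_mean are the extrema and unweighted arithmetic mean over the acquired
cardiac phases (near-uniformly spaced), PI = (v_max − v_min)/v_mean
(Gosling), and DF = PI_MCA/PI_LSA. A non-positive v_mean is rejected as
non-physiological (mis-segmentation or venous contamination). Ties in peak
selection break on the smallest row-major linear index; coordinates are
0-based (row, col).

## The digital phantom

A vessel cross-section of radius R (default 2.4 voxels) on a grid (default
32×32) over one cardiac cycle (default 20 phases, VENC 30 cm/s):

* **Magnitude**: lumen signal 1, static background `background_level`
  (default 0.15), blended at the rim by fractional disc coverage computed
  with 16× sub-pixel sampling.
* **Velocity**: laminar (parabolic) radial profile, v(ρ) = v_c·(1 − ρ²/R²),
  scaled by the prescribed centerline waveform. The phase channel
  point-samples this profile at pixel centres rather than averaging over the
  pixel: with the vessel centred on a pixel centre, the centre voxel then
  carries the centerline waveform exactly, so decoding fidelity can be
  asserted to machine precision; sub-pixel phase averaging would instead
  bias the centre voxel low by ≈ 1/(6R²) of the centerline velocity.
* **Noise**: i.i.d. complex Gaussian with per-channel SD 1/SNR added to the
  complex image (magnitude therefore Rician); SNR is lumen magnitude over
  per-channel noise SD, the standard MR convention. `snr=inf` is noiseless.
* **Waveform**: a truncated 3-harmonic Fourier series with a systolic peak
  (peak location and harmonic amplitudes configurable), affinely rescaled so
  v_mean and PI hit their targets exactly. Defaults emulate an LSA
  (v_mean 8.4 cm/s, PI 0.85).

Not modelled: 3D geometry, through-plane motion, gating jitter, spatially
varying eddy-current phase (only a constant offset). Phantom tests therefore
validate the decoding chain, not acquisition physics.

### Noise ceiling of the PI estimate

Because PI takes the max and min of the waveform, per-sample velocity noise
σ_v = VENC/(π·SNR) inflates v_max and deflates v_min by O(σ_v) each
(extreme-value selection over ~20 samples), giving a positive PI bias of
roughly 2·c·σ_v/v_mean with c ≈ 0.6–1.9 depending on waveform peakedness.
At SNR 20 and VENC 30 this floor is ≈ 0.07 for an LSA-like waveform
(measured: bias 0.071, RMSE 0.097 over 200 replicates) and is intrinsic to
the max/min estimator — no smoothing is applied, matching standard practice
for this measurement. At SNR ≳ 100 the bias falls below ~0.015.

## The synthetic cohort

One row per subject (default n = 45). A Gaussian copula links three latent
normals (DF, BG count, CSO count) with configurable correlations; the
DF–BG entry (`latent_rho_df_bg`, default −0.35) is the study's controllable
effect. Age (uniform on 40–90 y) and sex (47% male) load onto the PVS and
pulsatility latents (defaults +0.35 SD/SD age and +0.20 for male sex on PVS,
−0.20 SD/SD age on DF), after which latents are re-standardized, so
`latent_rho_df_bg` is always the *conditional* association the partial
correlation estimates. PVS counts come from Poisson margins (rates 15 BG,
35 CSO) via the quantile transform; the discretization to merged ordinal
scores attenuates the realized rank correlation to roughly 0.55–0.65 of the
latent value, which is why a latent −0.4 yields sample partial correlations
around −0.22. DF and PI_LSA are log-normal (medians 1.03 and 0.85, log-SDs
0.16 and 0.15, consistent with published interquartile ranges);
PI_MCA = DF·PI_LSA by construction. Pulse pressure (50 ± 10 mmHg) shares a
0.45 loading with the PI_LSA latent so the standardized regression has
signal; BMI, smoking history, alcohol intake, hypertension and brain size
are drawn from realistic independent marginals. Everything is deterministic
given the seed.

What passing cohort tests do **not** show: robustness to non-monotone
confounding, informative missingness, or rater disagreement in PVS scoring —
none of which the generator emulates.

## Partial Spearman correlation

Rank x, y and each covariate (average ranks for ties; a binary covariate is
unchanged up to an affine map, so ranking it is harmless), residualize the
ranked x and y on an intercept plus ranked covariates by least squares, and
take the Pearson correlation r of the residuals; p is two-sided from
t = r·√((n−2−k)/(1−r²)) on n−2−k degrees of freedom. Ranking the covariates
is the default (`rank_covariates=False` partials raw covariates instead, for
comparison with software that does). No exact-tie correction is applied to
p; ordinal outcomes enter as ranks of the merged scores. Complete cases are
used per correlation and n is reported per cell. Residual norms below
1e-8·n are treated as zero variance and rejected — at cohort sizes around
45 a merged score column occasionally comes out constant, in which case the
correlation is undefined rather than numerically fabricated.

The 3×2 driver (`run_table4`) crosses {PI_LSA, PI_MCA, DF} with the two
region scores at alpha = 0.05 (two-sided, no multiple-testing correction —
the six cells are reported as-is). Sensitivity analyses re-run the matrix
adding one of {hypertension, pulse pressure, BMI, smoking history, alcohol,
brain size} to age and sex. The standardized regression z-scores the outcome
and continuous predictors (binary covariates stay 0/1) and reports the
predictor's beta from OLS.

## Pipeline and problem sizes

`run_pipeline` chains simulate → extract → score → analyze from a YAML
config; all randomness derives from one top-level seed through named
`SeedSequence` substreams, so identical config + seed gives byte-identical
CSVs. Per subject, both vessels are rendered as phantoms (LSA at VENC 30,
MCA at VENC 100; subject v_mean log-normal around 8.4 / 41.9 cm/s) and
decoded by the velocimetry stack, so the analyzed PI and DF carry realistic
measurement noise. Defaults (45 subjects, 32×32 grid, 20 phases, SNR 20)
run in a couple of seconds; the replication studies in the test suite and
acceptance script use 200 phantom replicates, 1000 null cohorts and 500
powered cohorts, sizes at which the Monte-Carlo error of the reported rates
is ~0.007 or less.

## Known limitations

* Single-wrap aliasing only; the unwrapping anchor assumes a mostly
  unwrapped cycle.
* The PI noise floor above: at low SNR the max/min estimator is biased
  upward, and DF (a ratio of two PIs) inherits both vessels' noise.
* The cohort generator draws covariates independently except where noted;
  real risk factors are correlated with age, so sensitivity analyses on
  synthetic data understate real-world attenuation.
* PVS scoring implements only the count→score mapping; detection and rating
  of PVS on T2-weighted images is out of scope.
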