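# Methods

## Problem and approach

Carotid atheromatous plaques that move asynchronously with respect to the
adjacent arterial wall — or whose luminal (top) and wall-side (bottom)
surfaces move asynchronously with respect to each other — are thought to be
mechanically unstable. `plaquesync` quantifies these synchronisation
patterns from B-mode ultrasound image sequences in five stages:

1. **Tracking.** Four expert-annotated interfaces in the first frame — the
   anterior and posterior wall–lumen interfaces on normal wall (AWL, PWL)
   and the plaque top and bottom surfaces (PTS, PBS) — are tracked per pixel
   with adaptive block matching and Kalman smoothing.
2. **Waveforms.** The tracked positions yield six waveform sets: the wall
   diameter (the most clearly cyclic vertical AWL–PWL distance), radial and
   longitudinal displacements of PTS and PBS pixels, and the per-pair plaque
   radial distances |PTS − PBS|.  Plaque contours lose 25 pixels at each end
   so only plaque tissue is analysed.  All series pass a zero-phase
   4th-order Butterworth high-pass at 0.6 Hz.
3. **Synchronisation features.** Per vertical pixel pair, the normalized
   cross-correlation

       r_d = Σᵢ (x(i) − m_x)(y(i−d) − m_y)
             / sqrt(Σᵢ (x(i) − m_x)² · Σᵢ (y(i) − m_y)²)

   is evaluated at all lags of the signals confined to one average cardiac
   cycle.  The maximum-|r| peak yields a sign (positive = in-phase) and an
   absolute lag d_max in seconds.  Three correlation types (CC1: plaque
   radial deformation vs wall diameter; CC2/CC3: top vs bottom radial /
   longitudinal displacement) are each summarised by the synchronisation
   percentage (share of positive peaks) and seven statistics of the d_max
   distribution — 24 features per plaque.
4. **Echogenicity.** Intensities are re-mapped so the blood-region median is
   0 and the adventitia-region median 190; the plaque grayscale median
   (GSM), averaged over frames inside the tracked PTS/PBS polygon, labels
   the plaque echolucent (GSM < 25) or echogenic.
5. **Association.** Features are standardised, projected on the principal
   components covering 95% of variance, the training minority class is
   rebalanced with ADASYN, and a Random Forest is evaluated by leave-one-out
   cross-validation; univariate group differences use the two-sided
   Wilcoxon rank-sum test at p ≤ 0.05.

Because clinical recordings cannot be redistributed, the package ships a
first-class synthetic-data module whose phantoms carry exact ground truth.

## Synthetic data

**Waveform model.** Tissue displacement follows a unit-peak sum of
`n_harmonics` cosines of a cardiac fundamental with 1/k amplitude decay — a
simple periodic stand-in for arterial pulsation, not a claim about true
plaque kinematics.  Defaults describe a resting subject imaged under the
standard protocol: fundamental 0.9 Hz (54 bpm), 3 harmonics, radial peak
amplitude 0.4 mm, longitudinal 0.25 mm, 4 s at 25 frames/s (≥ 3 cardiac
cycles), plus slow additive drift (0.05 mm at 0.2 Hz, emulating breathing or
transducer motion, which the 0.6 Hz high-pass must remove) and 0.01 mm
Gaussian measurement noise.  The key ground-truth dial is
`top_bottom_delay`, the phase delay of the plaque top surface relative to
the bottom; `wall_plaque_delay` delays the whole plaque relative to the
wall.

**Image phantom.** A piecewise-constant reflectivity map (dark lumen 15,
plaque 60, wall tissue 120, adventitia 190 on the 8-bit scale) at
12 pixels/mm is given speckle by spatially correlated (σ = 1.5 px)
multiplicative noise of 35% contrast.  Frames are backward warps of that
single speckle realisation by an analytic displacement field that is
piecewise linear in depth between the moving interfaces (walls anti-phase,
producing a pulsatile diameter; plaque surfaces delayed per the model), plus
2 grayscale units of per-frame sensor noise.  Ground-truth trajectories are
the exact material paths of the warp, obtained by fixed-point iteration of
p = p₀ + u(p, t).  The phantom reproduces what block matching needs —
speckle texture, interface contrast, pulsatile kinematics with controllable
phase delays — and deliberately omits acoustic physics (beamforming, RF
speckle statistics, attenuation, out-of-plane motion), so passing tests
demonstrate correctness of the measurement chain, not clinical performance.

**Cohorts.** Labelled feature tables are sampled from per-group normal
distributions, used to test the statistical and classification stages at
published group means (e.g. mean CC2 phase shift 0.16 vs 0.23 s, sd 0.14,
group sizes 26/71).

## Numerical and design choices

* **Tracker.** 1.6 × 1 mm² reference blocks (odd pixel sizes, 19 × 13 at
  12 px/mm) are cut in frame 1 and matched by normalized cross-correlation
  inside a ±5 px search window centred at the prediction of a per-pixel,
  per-axis constant-velocity Kalman filter.  The reference texture is never
  updated (no drift accumulation); adaptivity is the predictive
  re-centring.  Sub-pixel refinement fits a parabola through the similarity
  peak; similarity ties break toward the smallest displacement, then
  lexicographically.  Kalman noise defaults are process 0.5 px² and
  measurement 0.25 px²: at the phantom's pulsatile velocities (≈1.4
  px/frame) stiffer settings (e.g. process 0.01 px²) lag the motion by over
  a pixel RMS, while the chosen defaults track it within ≈0.2 px RMS and
  still suppress matching jitter.  The search window is clamped to the
  image and to ±20 px of a pixel's starting position — wall motion is
  bounded, so larger excursions are lost tracks, not measurements.
* **"Most clear cyclic motion"** is operationalised as the fraction of
  DC-free periodogram power within ±1 bin of the in-band (0.6–3.0 Hz ≈
  36–180 bpm) peak, maximised over candidate AWL–PWL columns.
* **Filtering** is forward–backward (zero-phase) so lags are unbiased; the
  effective response is the squared Butterworth magnitude (< 1% loss at
  1.2 Hz, > 99.9% rejection at 0.1 Hz).
* **Cycle window.** Signals to be correlated are confined to one average
  cycle, length round(frame_rate / f₀), starting at the first wall-diameter
  local minimum that leaves one window of filter warm-up before it.  This
  bounds lags by one cycle and makes them comparable across plaques.
* **Lags** are reported as absolute values in seconds (published phase
  shifts are non-negative with minima near 0); ties at equal |r| break
  toward the smaller |lag|, which is conservative for asynchrony claims.
  Pure-tone pairs windowed to one cycle can bias the peak by one sample, so
  one sample (0.04 s at 25 frames/s) is the stated lag resolution.
* **Lag statistics** use the sample (n−1) standard deviation and biased
  standardised central moments with excess kurtosis; a constant sample has
  skewness = kurtosis = 0 by convention.
* **Cross-correlation arithmetic** uses one accumulation kernel for
  numerator and denominator and a single square root of the product of
  energies, so the lag-0 self-correlation is exactly 1 in floating point.
* **GSM.** The affine map is anchored on first-frame reference medians and
  applied to all frames; the plaque polygon uses per-frame rounded contour
  positions; the boundary GSM = 25 counts as echogenic (the threshold is
  strict: echolucent iff GSM < 25).  Division precedes scaling in the
  affine map so a pixel at the adventitia median maps to exactly 190.
* **Classification.** PCA, ADASYN (k = 5, full balance β = 1) and Random
  Forest tuning (trees 100–900 step 200, per-split features 2..p, inner
  10-fold CV on the balanced training fold) are all refitted inside every
  leave-one-out fold, so the held-out plaque never leaks into
  standardisation, components, synthetic samples or tuning.  The AUC pools
  the held-out class probabilities (leave-one-out yields one score per
  sample, so a per-fold ROC is undefined).  Because repeated-run tests
  (permutation nulls) need hundreds of complete LOOCV evaluations, the
  default configuration uses a fixed 100-tree forest (`tune=False`); the
  full grid remains available via `tune=True` and is exercised on a small
  grid in the test suite.  Note that pooled LOOCV AUC is pessimistically
  biased on small cohorts (the held-out sample's class is always
  under-represented in its training fold): under permuted labels the mean
  AUC measured ≈0.40 at n = 16 and ≈0.52 at n = 40, so null-calibration
  checks use cohorts of at least 40 samples.
* **Wilcoxon** tests are two-sided rank-sum with exact enumeration for
  small tie-free samples and tie-corrected normal approximation otherwise;
  fully tied data return p = 1 with a warning.
* **Variability experiment.** Annotation variability is emulated by
  displacing all contours radially by 0–2 px (sub-pixel included); the
  per-pair d_max distributions of each correlation type are compared with
  the original annotation by rank-sum test.

## Problem sizes

Image phantoms are 160 × 160 px (13.3 × 13.3 mm), 100 frames (4 s), with a
9.2 mm plaque (111 contour pixels, 61 pairs after trimming).  Property
tests use 100 seeded waveform phantoms for delay recovery, 1000 for the
law-of-large-numbers check, 200 replicates for test calibration/power, and
200 label permutations for the classifier null.  These sizes make every
stage's behaviour measurable on a single CPU while preserving the study's
stated acquisition parameters (25 frames/s, 12 px/mm, ≥ 3 cycles, 25-pixel
trimming).

## Known limitations

* The phantom's displacement field is layered (1-D in depth per column);
  it cannot probe rotation, shear along the vessel axis, or out-of-plane
  decorrelation.
* Block matching near the trimmed plaque ends and inside the thin plaque
  cap suffers the aperture problem; with a delayed (internally shearing)
  plaque, longitudinal tracking error can approach a pixel there, though
  recovered phase shifts remain within one sample of the truth.
* The classifier benchmark demonstrates machinery (leak-free LOOCV,
  balancing, tuning), not clinical discriminative power: synthetic cohorts
  are far simpler than patient data.
* GSM values depend on the synthetic intensity model only through the
  anchored normalisation; no texture or histology realism is claimed.
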