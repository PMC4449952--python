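# Methods

## Problem

During percutaneous coronary interventions, device navigation happens
largely on "vessel-free" fluoroscopy frames, because contrast-agent
injections are limited. Motion-compensated guidance needs a per-frame
*respiratory surrogate*: a scalar signal correlated with the patient's
breathing displacement that can be computed in real time from the X-ray
stream itself. The dominant nuisance is cardiac motion: coronary
arteries and catheters deform at ~1–1.5 Hz, an order of magnitude faster
than breathing (~0.2–0.3 Hz) and with comparable image contrast.

## Pipeline

1. **Downsampling.** Each frame is block-averaged by an integer factor
   chosen from the frame side: sides in [256, 768) → 4 (512 → 128,
   600 → 150), sides ≥ 768 → 8, smaller frames are kept. Block means
   (not decimation) suppress aliasing of thin vessels into the coarse
   grid.
2. **Vessel removal.** Grayscale morphological closing with a discrete
   disk (pixel (i, j) in the element iff i² + j² ≤ r²) fills dark
   structures thinner than the disk with surrounding background. The
   radius is `ceil((d/2) / (spacing · factor))` pixels with d = 11 mm —
   a maximal coronary diameter of 5–7 mm times a projection
   magnification of about 1.5 — clamped to ≥ 3; typical XA spacings give
   r = 7–8. Borders are edge-replicated so a diaphragm touching the
   frame edge is not distorted. The stated radius rule does not land
   exactly on 7–8 for every spacing in circulation, so the radius is
   user-overridable.
3. **PCA on pixel intensities.** The N processed frames become columns
   of a D×N matrix X (D = pixels). After subtracting the per-pixel
   temporal mean (pixels are the variables, frames the observations),
   the first principal component e₁ of the D×D pixel covariance is
   obtained through the N×N Gram matrix XᵀX: if v₁ is its leading
   eigenvector, e₁ = Xv₁/‖Xv₁‖. The surrogate is the projection
   p = Xᵀe₁, one scalar per frame. With cardiac-moving structures
   removed, breathing is the dominant source of intensity variance, so
   p tracks the diaphragm.

`e₁` is unit-normalized rather than scaled by the inverse eigenvalue as
the lifting identity would give (that convention yields ‖e₁‖ = λ₁^(-1/2)
and, taken literally over all components, divides by the structurally
zero smallest eigenvalue that centering introduces). The two conventions
differ by a positive scalar on p, which is irrelevant for a
correlation-based surrogate.

**Sign.** A principal component's sign is arbitrary. The component entry
of largest magnitude is made positive for reproducibility, and all
evaluation uses the absolute correlation |r|. When the leading
eigenvalue gap (λ₁−λ₂)/λ₁ falls below 1e−6 the component is
ill-determined and a warning is emitted; the eigensolver's output is
accepted as is.

**Prospective mode.** For streaming use, all preprocessing parameters,
the training mean image and e₁ are frozen at fit time; each new frame is
preprocessed, centered with the *training* mean (never its own — a
streaming predictor cannot peek ahead) and projected. Scoring a frame is
a downsample, one closing, and one dot product.

**Biplane fusion.** Time-synchronized biplane pairs are fused by
stacking the two pixel-vector blocks of each frame into one column,
X = (X_A; X_B), giving a single projection vector for both views.

## Comparison variants

* `downsampled` — PCA on downsampled frames without closing.
* `with_mask` — PCA restricted to pixels selected by a multiscale
  Frangi vesselness filter for dark tubular structures (per-pixel max
  over the training frames, binarized at the 0.9 quantile; scales
  {1, 2, 3} px on the downsampled grid), i.e. the vessel-centric
  masked-PCA family adapted to emit the raw first-component projection.
  The original mask construction is described only in outline in the
  literature we follow, so these settings are package choices and fully
  configurable; no bit-equivalence is claimed.
* `inverted_mask` — PCA on the complement of that mask.

Masks are built on downsampled *unclosed* frames (closing would erase
the structures the mask selects), by default from the training frames of
the fit at hand.

## Evaluation

Agreement with ground truth (a manually labelled, or phantom-generated,
per-frame diaphragm position track) is the absolute Pearson correlation
|r|; positions and surrogates are compared shape-wise only, so no
spatial calibration of the track is needed. Methods are compared with a
one-tailed Wilcoxon rank-sum test. For combined sample sizes ≤ 12 the
exact permutation distribution of the rank sum is enumerated, using
midranks for ties and the mid-p convention p = P(S > s) + ½P(S = s);
mid-p makes identical samples give exactly 0.5 and swapping the groups
map p to 1 − p, at the cost of being half the classical inclusive tail
on extreme configurations. Larger samples use the tie-corrected normal
approximation without continuity correction (consistent with mid-p).
Residual cardiac content of a surrogate is quantified as the fraction of
its DC-free periodogram power within one frequency bin of the cardiac
frequency (`band_power_fraction`). In the phantom study this measure is
refined (`cardiac_contamination`): the breathing-explained part of the
surrogate — a polynomial in the known diaphragm displacement, which
captures the nonlinear pixel response including its harmonics and their
breath-to-breath modulation sidebands — is regressed out first, and the
band power of the residual is reported relative to the surrogate's total
power, restricted to the contrast segment (after the fade the vessels,
the only cardiac-moving structures, are gone). Without the regression,
the 4th–6th breathing harmonics routinely fall inside the cardiac band
and swamp the vessel signal in closed and unclosed variants alike,
turning the comparison into noise.

## Synthetic phantom

Clinical XA from the original evaluation is not redistributable, so all
end-to-end tests run on a seeded synthetic phantom (512×512, 120 frames
at 15 fps, 0.216 mm pixels by default):

* background ~200 (8-bit-like scale) with a random smooth gradient and
  low-frequency lung texture that shifts vertically with 0.3× the
  breathing displacement;
* a dark diaphragm (depth 80) under a parabolic border at
  y = apex + curvature·(x − apex_x)², the border itself carrying an
  extra Gaussian dip (depth 50, σ 1.5 px) as the projected dome edge
  does; the border position oscillates as A·sin(2πf_r t + φ);
* breathing: A = 30 px (~13 mm peak-to-peak diaphragm excursion — tidal
  breathing), f_r defaulting to 0.25 Hz, with 15% slow breath-to-breath
  amplitude modulation (real breathing is not perfectly periodic; this
  is also what makes prospective prediction genuinely harder than
  retrospective fitting);
* a randomly branched dark vessel tree (4 branches, ~3 mm projected
  caliber = 14 px, contrast depth 90) plus a ~2 mm catheter, displaced
  by the cardiac signal (amplitude 14 px ≈ 3 mm at 1.2 Hz) plus 0.7× the
  breathing displacement;
* vessel contrast decays as exp(−t/1 s) after frame 60 (contrast-agent
  washout); the catheter, being a device, does not fade;
* additive Gaussian noise, σ = 4.

Everything is deterministic given the seed. Biplane pairs share the
motion signals and truth track but have mirrored vessel layout,
independent background, texture and noise. What the phantom does *not*
emulate: physically accurate X-ray attenuation and scatter, gantry
geometry, table motion, irregular (non-sinusoidal) breathing waveforms,
and anatomy beyond one diaphragm dome — so passing tests demonstrate
correct mechanics and the expected qualitative method ranking, not
clinical-grade performance figures.

## Simulation study

`xasurrogate.benchmark.run_phantom_study` mirrors the clinical protocol
at desk scale: 20 seeded biplane replicates with per-replicate breathing
frequency drawn from 0.20–0.30 Hz and cardiac frequency from 1.0–1.5 Hz,
all four methods, retrospective (all 120 frames) and prospective (train
on the 60 contrast frames, predict the 60 faded ones) modes, monoplane
and biplane scopes. Cardiac residual power is measured on the contrast
segment of the surrogate, since after the fade the vessels — the only
cardiac-moving structures — are gone and there is nothing left to
suppress. The replicate count and frame count were chosen to keep the
full study in the minutes range on a single core.

## Numerical choices and degenerate inputs

* Eigenvalues of the Gram matrix are clipped at 0; centering forces the
  smallest to numerical zero.
* A (numerically) constant sequence has no variance direction and
  raises, as do empty vesselness masks (flat sequences) and
  zero-variance inputs to the correlation.
* Non-divisible frame sizes are edge-replicated up to the next multiple
  of the downsampling factor; the original size is recorded.
* Frames are stored as float32 in sequences; all linear algebra runs in
  float64.
* Track CSVs must cover every frame exactly once (the labelling
  protocol places one marker per frame); gaps and duplicates are
  rejected rather than interpolated.

## Known limitations

* The surrogate is relative: scale and sign carry no physical meaning,
  so downstream use must calibrate against an anchor (as the |r|-based
  evaluation does implicitly).
* Prospective accuracy depends on the training frames covering the
  breathing range; the package freezes all parameters at fit time and
  does not detect out-of-range drift.
* A fixed C-arm view is assumed; detector repositioning requires
  refitting.
* ROI selection for ground-truth labelling is manual by design; nothing
  automates it.
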