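# Methods

## Problem and approach

Myocardial scar is normally diagnosed with contrast-enhanced (late gadolinium
enhancement) CMR. Because fibrotic tissue alters the contractile behaviour of
the wall, scar presence can instead be inferred — without contrast agent —
from how the myocardium moves in an ordinary short-axis cine loop. This
package compresses the temporal information of a cine loop into single-frame
*parametric images* and classifies them with a residual CNN:

- **C** — the end-diastolic cine frame, masked to the myocardium (static
  appearance reference).
- **FA / FP** — first-harmonic Fourier amplitude and phase. Each pixel's
  intensity series f(t) over the T-frame cycle is modelled as
  `f(t) = A0 + A1 sin(wt + P1)` with `w = 2*pi/T`; the least-squares `A1` and
  `P1` become the pixel values. For uniformly sampled complete cycles this
  equals the DFT bin-1 coefficient (amplitude `2|X1|/T`, phase
  `angle(X1) + pi/2` folded to `(-pi, pi]`), which is how it is computed; the
  equivalence with an explicit normal-equations solve is a tested property.
  Hypokinetic (scarred) wall modulates its videointensity less, so FA drops.
- **MA / MP** — monogenic-signal amplitude and phase differences between the
  ED and ES frames. Frames are band-passed with an isotropic zero-DC
  log-Gabor filter (even part `w`); the Riesz transform supplies the odd
  quadrature pair `q1, q2`; local amplitude is `sqrt(w^2+q1^2+q2^2)` and
  local phase `atan2(sqrt(q1^2+q2^2), w)`. A wall segment that barely
  deforms between ED and ES changes its local structure little, so |MA| is
  small over scar.

Channels are combined into twelve fixed protocols P1–P12 (P1 = C only;
P2 = C+FA; …; P10 = all five). The classifier is a U-Net-encoder-style CNN:
conv(64)+BN+ReLU, three residual blocks (128/256/512 filters; two
conv+BN+ReLU stages and a 2x2 max-pool on the main path, 1x1 projection +
pool on the skip path, summed after pooling), flatten, FC(256) and FC(128)
blocks (dense+BN+dropout 0.2+ReLU), and a sigmoid output unit. He-uniform
initialisation throughout.

## Numerical engine

No deep-learning framework is part of the dependency set; the network runs
on a compact numpy engine (`cinescar.nn`) with hand-derived backward passes
(convolution as per-offset BLAS products, batch normalisation, max pooling
with argmax routing, inverted dropout, plain SGD). Gradients of the full
composed model are verified against central finite differences to 1e-6
(scaled error, float64). Probabilities from the sigmoid are clipped to
machine epsilon away from {0, 1} so probability-range contracts and
log-losses remain well defined.

## Synthetic phantom

The generator renders a bright-blood annulus (blood 200, myocardium 80,
background 20 gray levels by default) contracting over one exact cycle with
a raised-cosine law `r(t) = r_ed - a * r_ed * (1 - cos(2*pi*t/T))/2`; frame 0
is therefore end-diastole and frame T/2 end-systole by construction, and
each pixel's series is periodic at the fundamental the Fourier model
assumes — giving closed-form oracles. The wall is incompressible
(`r_epi = sqrt(r_endo^2 + const)`), so epicardial excursion is milder than
endocardial, as in a real ventricle. A "scar" is an angular sector whose
radial excursion is scaled by `kappa` in [0, 1] (0 = akinetic); the slice is
labelled SCAR iff the sector is present and non-empty, and a patient is SCAR
iff any slice is. Region fills are anti-aliased with a one-pixel linear
coverage ramp; noise is i.i.d. additive Gaussian.

What the phantom does *not* emulate: through-plane motion, breathing
artifacts, papillary muscles, trabeculation, Rician noise statistics,
scanner shading, or any appearance difference of scar in the static frame.
That last point is deliberate: in the phantom the scar is visible *only*
through motion, so a static-only protocol (P1) should sit near chance while
motion protocols (P2…) can succeed — passing tests demonstrate that the
pipeline extracts motion information, not that clinical accuracy transfers.

## Parameter choices

- Log-Gabor: wavelength 16 px, sigma_on_f 0.5, single scale, periodic (FFT)
  boundaries; conventional values for ~128–224 px cardiac frames, exposed in
  `PipelineConfig` (the 64 px reference study uses wavelength 8).
- Local phase uses the two-argument arctangent with range [0, pi]; the
  one-argument `literal-arctan` variant is available but discontinuous where
  w changes sign.
- Preprocessing: square LV bounding box from the ED epicardial mask with a
  4 px margin, per-channel per-sample zero-mean/unit-SD normalisation,
  bilinear resize to the network side. Only C is myocardium-masked
  (`mask_all_channels` flips this). Pixel-in-polygon uses the even-odd
  half-open ray-crossing rule on pixel centres.
- ED is the frame with the largest blood-pool area, ES the smallest (the ES
  rule is the symmetric extension of the ED rule); contour areas are used
  when every frame has contours, otherwise Otsu thresholding inside the
  epicardium.
- Splits: per-stratum shuffle, test = round(0.2 * stratum) (ties up), then
  validation = round(0.15 * remainder). On a 158/48 roster this yields
  164/42 and then 139/25 patients.
- Training: SGD (lr 0.001), BCE, batch 32, <= 200 epochs, early stop after
  16 epochs without strict validation-loss improvement, best-epoch weights
  restored, augmentation (flips p=0.5/axis, shifts +/-20% of the side,
  rotations +/-20 deg, zero fill, identical draw across channels) applied
  on the fly to training samples only. Decision threshold 0.5 with ">="
  counted positive.

## Reference study at desk scale

The bundled end-to-end study (`small_study_conditions`) runs on one CPU in a
few minutes: 32 scar + 20 control patients, 3 slices each, 64 px grids, 30
frames, kappa = 0.1, noise sigma 6 (blood-myocardium contrast 120), crop
side 32, and a reduced-width model (8 base filters, residual widths
16/32/64, FC 64/32). Two recipe constants are re-scaled with the problem:
the learning rate is 0.05 with a 100-epoch cap (a small model on a small
dataset needs larger steps to converge within the budget), and augmentation
magnitudes are reduced to 5% shifts and 10 deg rotations because a 20%
shift of a 32 px crop pushes the ventricle partially out of frame — a
distortion regime the full-size recipe never enters. Loss, batch size,
patience, early stopping, threshold and the patient-wise stratified split
are unchanged. Expected behaviour: P2 (C+FA) reaches >= 0.85 held-out slice
accuracy and >= 0.9 patient accuracy while P1 hovers near chance, since the
phantom's scar is encoded purely in motion.

## Numerical conventions and degenerate inputs

- Phase at (near-)zero first-harmonic amplitude is defined as 0.
- A constant channel normalises to all zeros; the SD floor is 1e-8.
- Constant images give identically zero monogenic components (zero-DC
  filter); their phase is reported as 0.
- MP differences are not unwrapped: per-frame phase lies in [0, pi], so the
  difference lies in [-pi, pi].
- Ties in ED/ES selection and in 2x2 max-pool gradient routing break to the
  smallest index; AUC on a single-class test set is reported as missing with
  a warning rather than a number.

## Known limitations

- The phantom's simplicity makes the classification task far easier than
  clinical data; reported synthetic accuracies say nothing about clinical
  performance.
- Single-scale monogenic analysis only; no local-orientation image, no
  optical flow, no multi-scale pyramid.
- One training run per protocol by default; neural-network training variance
  across seeds is real, which is why the end-to-end property is checked on
  three seeds.
- No scar segmentation or area quantification — presence/absence only.
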