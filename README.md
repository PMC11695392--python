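# cinescar

Gadolinium-free detection of myocardial scar from short-axis cine cardiac MR.

Scar tissue is normally diagnosed with contrast-enhanced (late gadolinium
enhancement) CMR, which is contraindicated in renal impairment and carries
concerns about gadolinium retention. Because fibrosis stiffens the wall,
scar also leaves a motion signature in the plain cine loop. `cinescar`
compresses that temporal signature into single-frame **parametric images**
and classifies scar presence with a residual CNN, at slice and patient
level:

- **FA, FP** — amplitude `A1` and phase `P1` of the first-harmonic fit
  `f(t) = A0 + A1 sin(wt + P1)`, `w = 2*pi/T`, to each pixel's
  videointensity series over the cardiac cycle (computed via the DFT bin-1
  closed form, which equals the least-squares solution for full cycles).
- **MA, MP** — differences of monogenic-signal local amplitude
  `A = sqrt(w^2 + q1^2 + q2^2)` and local phase
  `P = atan2(sqrt(q1^2 + q2^2), w)` between the end-diastolic and
  end-systolic frames, where `w` is the log-Gabor band-pass response and
  `q1, q2` its Riesz quadrature pair.
- **C** — the myocardium-masked end-diastolic frame (static reference).

Fixed channel combinations P1–P12 (P1 = C; P2 = C+FA; …; P10 = all five)
feed a U-Net-encoder-style CNN: conv(64)+BN+ReLU, three residual blocks
(128/256/512 filters, 1x1-projection skip paths), two fully connected
blocks (256/128, dropout 0.2), sigmoid output. The network runs on a small
bundled numpy engine with hand-verified gradients, so the package has no
deep-learning-framework dependency.

A seeded synthetic phantom generator (beating annulus with an optionally
hypokinetic angular sector) replaces clinical data, so the entire pipeline
is runnable and testable offline.

## Worked example

```bash
python examples/02_fourier_parametric_images.py
```

```
slice label:            SCAR
mean FA, scar sector:      2.065
mean FA, remote wall:     10.769
scar / remote ratio:       0.192
```

On a noise-free phantom whose scar sector contracts at 10% of the normal
excursion, the first-harmonic amplitude image is ~5x darker over the scar
than over remote myocardium — exactly the contrast the CNN learns.
`examples/04_train_and_evaluate_protocols.py` runs the full synthetic study
(52 patients, 156 slices, a few CPU-minutes) and prints slice/patient
metrics for P1 vs P2; the static-only P1 sits near chance while P2 reaches
slice accuracy >= 0.85 and patient accuracy >= 0.9, because the phantom's
scar is visible only through motion.

Other entry points: `examples/01_generate_phantom_cohort.py` (NIfTI + JSON
manifest output), `examples/03_monogenic_parametric_images.py`, and a thin
CLI (`cinescar simulate | param fourier | param monogenic | build | run |
model-summary`).

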