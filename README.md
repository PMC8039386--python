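# gastrolayer

Quantitative analysis of the gastric wall in oral contrast-enhanced
ultrasound. After a patient drinks an ultrasound contrast agent, the
filled stomach forms an acoustic window in which the wall appears as
five alternating echogenic bands (mucosa, muscularis mucosa, submucosa,
muscularis propria, serosa). Changes in the *relative thickness* of
those bands accompany gastric disease, so measuring them offers a
cheap, non-invasive screening signal for gastritis, ulcers and early
gastric cancer — settings where gastroscopy is poorly accepted or
unavailable.

`gastrolayer` implements the full measurement chain:

1. **Wall detection** — a compact U-net (four 2×2 max-pool stages with
   channel doubling, mirrored by four transposed-convolution stages
   with skip concatenation, softmax output) segments the wall and
   yields a rectangular ROI. The network is implemented in pure NumPy
   with hand-written backpropagation and runs on one CPU core.
2. **Speckle filtering** — speckle-reducing anisotropic diffusion
   (SRAD): ∂I/∂t = div[c(q)∇I] with zero-flux boundaries, where the
   instantaneous coefficient of variation
   q² = [½(|∇I|/I)² − (1/16)(∇²I/I)²] / [1 + ¼(∇²I/I)]²
   discriminates edges from speckle, and the diffusion coefficient
   c(q) ≈ 1 in homogeneous speckle (q ≈ q₀) and → 0 across edges. Both
   the reciprocal and exponential forms of c(q) are available.
3. **Stratification** — along sampled ROI columns, the four strongest
   interior peaks of the Sobel vertical gradient locate the inter-layer
   boundaries; consecutive differences give layer thicknesses,
   normalised into a proportion vector **x** ∈ Δ⁴ and averaged over
   columns.
4. **Screening** — the distance of **x** from the standard (normal
   average) vector **s** = (0.278, 0.133, 0.154, 0.154, 0.280),

   d = √[(x₁−s₁)² + (x₂−s₂)² + (x₃−s₃)² + (x₄−s₄)²],

   is thresholded: large d ⇒ abnormal wall. The threshold is fitted by
   maximising accuracy on a stratified 70/30 training split, and the
   test split is scored with ACC, SENS, SPEC, PPV, NPV, MCC, F1 and the
   ROC AUC of the d score. (The statistic is defined with only the
   first four layer proportions; it is kept exactly as defined, with an
   optional flag to include the fifth term.)

Clinical images of this kind are not publicly deposited, so the package
ships a **phantom generator**: five-band walls with known per-layer
proportions, optional bowing, unit-mean gamma speckle parameterised by
the number of looks, the three manual labelling styles (one rectangle,
two rectangles, full region), and labelled normal/abnormal cohorts in
which disease is emulated as a mucosal-thickening shift of the
proportion vector. Every stage is therefore testable end to end against
exact ground truth.

## Worked example

```sh
python examples/03_stratify_wall.py
```

```
recovered x: [0.279, 0.129, 0.159, 0.147, 0.287]
true      x: [0.278, 0.133, 0.154, 0.154, 0.28]
max component error: 0.0067
```

A 150-px-thick wall under 4-look speckle (coefficient of variation 0.5)
is SRAD-filtered and stratified; each recovered proportion is within
~one boundary pixel of the simulated truth. Screening a 50-phantom
cohort in which abnormal walls have a doubled mucosal fraction
(`examples/04_screen_cohort.py`) prints

```
standard vector s: [0.275, 0.128, 0.158, 0.15, 0.29]
fitted threshold on d: 0.0963
  test AUC: 1.000
  test ACC: 1.000
```

i.e. the d statistic separates the two classes completely when the
layer shift is large, while cohorts with no shift score near
chance (AUC ≈ 0.5). The other examples cover phantom simulation, SRAD
on a two-band fixture and U-net training.

A thin CLI mirrors the stages (`gastrolayer simulate|train|detect|srad|
stratify|screen|run`); `gastrolayer run --config cfg.yaml` executes a
reproducible simulate→evaluate chain whose artifacts record the seed
and config digest.

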