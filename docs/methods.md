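# Methods

## The ATV denoiser

Each slice is denoised independently in 2D. The objective is the
edge-weighted total variation R(V) = Σ_j w_j·D(V_j) with backward
differences D and 4-neighbour conduction weights w (see the README for
the formulas). Design points that the formulas alone do not fix:

* **Coordinates and boundary.** (x, y) = (column, row), 0-based; the
  out-of-range neighbour in a backward difference is replicated
  (V(−1,y) := V(0,y)), so border difference terms vanish.
* **Differentiability guard.** D uses sqrt(gx² + gy² + ε²) − ε with
  ε = `sqrt_epsilon` (default 10⁻³ HU). This keeps D = 0 on flat pixels
  exactly while making the square root smooth at zero; the objective
  gradient additionally zeroes the 0/0 case when ε = 0.
* **δ estimation.** δ is the `delta_quantile` (default 0.80) point of the
  empirical distribution of D over all pixels of the *input* slice
  (linear interpolation between order statistics), computed once, not
  re-estimated per iteration. `delta_floor` (default 10⁻⁶ HU) bounds it
  away from zero.
* **Degenerate input rule.** If δ collapses to `delta_floor`, at least
  80 % of pixels have exactly zero gradient — the image carries no
  measurable noise and the conduction model is degenerate (the
  diffusion-stops limit of a vanishing conduction threshold). The slice
  is returned unchanged. Without this rule the *normalised* update below
  would take full-length steps along a tiny, edge-concentrated gradient
  and erode clean contours. The rule never triggers on noisy input,
  where δ lands near the noise gradient scale.
* **Frozen-weight gradient.** w depends on V, but ∇R is evaluated
  treating w as constant (the lagged-diffusivity convention of the
  anisotropic-diffusion literature). The finite-difference oracle in the
  tests freezes w identically, so the two routes are comparable.
* **The update.** V ← V − λ·∇R/|∇R| with |∇R| the root-sum-square over
  all pixels and λ = `lambda_scale`·γ·sqrt(Σ V²). γ starts at
  `gamma_init` (1.0) and is multiplied by `gamma_decay` (0.8) after any
  iteration in which R increased; the step itself is retained. The loop
  runs `iterations` (20) updates, stopping early only at |∇R| = 0.
  R is recorded per iteration as a pure function of the current image
  (with the weights that configuration implies), so the γ schedule can
  be audited from the state object.

### Weight refresh and step scale in practice

Two settings interact strongly with the step magnitude:

* `weight_refresh="per_iteration"` (the constructor default) recomputes w
  from the current image each iteration. This makes the objective
  non-convex in a specific way: pixels pushed far from their neighbours
  acquire near-zero weights, so newly created large gradients stop being
  penalised. At small steps this is harmless; at the full printed step
  magnitude it lets the optimizer lower R while *adding* structure to
  flat regions. `weight_refresh="fixed_initial"` freezes the input-slice
  weights, making the weighted TV convex during descent.
* λ = γ·sqrt(Σ V²) scales with the L2 norm of the whole slice. On
  HU-valued thorax slices the sum is dominated by the ±700 HU lungs and
  bone, giving first steps whose length is comparable to the image norm
  itself; γ decay absorbs much of the overshoot, but some distortion of
  high-contrast structures survives. `lambda_scale` (default 1.0 —
  the step exactly as defined) rescales it globally.

The pipeline therefore applies `default_pipeline_denoiser()` =
`DenoiserConfig(weight_refresh="fixed_initial", lambda_scale=0.05)` to
whole CT slices. The 0.05 scale was chosen once on the σ = 40 HU phantom
as the largest setting that leaves high-contrast organs (lungs)
untouched while still shifting the residual-noise spectrum decisively
toward low frequencies; smaller scales under-smooth (the NPS barely
moves), larger ones erode the lungs. Small uniform patches are far less
sensitive and denoise well at any of these settings.

## NPS estimation

Square ROIs (the analysis protocol uses three, replicated over five
consecutive slices, giving fifteen patches) are detrended with a
least-squares 2D polynomial of total order 0–2 (default 2, removing mean,
ramp and slow shading) and averaged in the Fourier domain:
NPS = (Δx·Δy/N²)·mean|DFT₂(residual)|², zero-frequency centred, axes in
mm⁻¹ up to the Nyquist frequency 1/(2Δx). The integral of the NPS over
frequency equals the residual variance (Parseval), which the tests check
to 5 % on 100 seeded patches. The radial profile averages annular bins
whose default width is the smaller frequency-axis step; the DC sample is
excluded (its power is a detrending artefact) before reading off the
peak frequency (centre of the maximal bin) and the mean frequency
(power-weighted mean of bin centres). No window/taper is applied.

## Contour statistics

* DSC = 2|A∩B|/(|A|+|B|). Two empty masks raise instead of returning a
  value: 0/0 is undefined and silent success would hide an upstream
  segmentation failure.
* The Wilcoxon matched-pairs signed-rank test discards zero differences
  (the original convention), ranks |d| with midranks, and uses
  W = min(W⁺, W⁻). For n ≤ 25 effective pairs the two-sided p is exact:
  P(min(W⁺, W⁻) ≤ W) over all 2ⁿ sign assignments, evaluated by dynamic
  programming over doubled (integer) ranks so midrank ties are handled
  exactly; the tests verify it against full enumeration. Beyond that, a
  normal approximation with tie correction and continuity correction is
  used. All p-values are two-sided.
* The per-organ summary table reports both methods' means, the paired
  p-value (NaN when every difference is zero — "no test"), and an
  acceptability flag at mean DSC ≥ 0.80.

## The synthetic phantom

`thorax-default` is a 128×128×10 volume at 1×1 mm in-plane spacing and
3 mm slice thickness — desk-scale in-plane, but with the slice geometry
of a planning CT. Organs are analytic ellipsoids painted over a 30 HU
soft-tissue background in priority order (later organs carve earlier
ones): two lungs at −700/−680 HU, heart 45 HU, liver 55 HU, a 700 HU
vertebral ring (painted but not scored) with a 40 HU spinal cord carved
inside it, and a 35 HU esophagus — deliberately only 5 HU above
background, reproducing the poorly defined esophageal boundary on
non-contrast CT. The two lungs are given slightly different HU so each is
separable by an intensity window alone. Noise is additive: white
Gaussian, or white noise convolved in-plane with a Gaussian kernel
(FWHM in mm) and rescaled to the requested σ using the kernel's exact
impulse-response energy. Equal specs (including the seed) give
bit-identical bundles.

What the phantom does *not* emulate: beam hardening, scatter, detector
correlations (real CT noise is neither white nor Gaussian-kernel
correlated), anatomical shape variability, and partial-volume effects
beyond voxelised ellipsoid surfaces. Passing the phantom tests therefore
demonstrates the internal correctness and the *direction* of the
denoising effect on segmentation, not clinical-level DSC values.

## The pipeline

The two-arm design isolates denoising: the identical intensity-window
segmenter (HU window → 26-connected components → keep largest →
morphological closing, default ball radius 1) runs on the raw and on the
denoised volume, and each arm is scored against the exact masks. The
reference segmenter deliberately has no learning component; what it
shares with any fixed segmenter is that its input is the only thing the
two arms change. Windows for the preset bracket each organ mean and
exclude background and bone. On noise-free input, thresholding recovers
window-separable organs exactly; closing can only add boundary voxels on
the terraced digitised ellipsoids, so exactness holds at closing radius
0. NPS summaries use three 16-pixel ROIs inside the liver across slices
2–6.

Problem sizes used throughout the tests and the acceptance script:
8×8 slices for the gradient oracle, 32×32 patches for NPS work, the
64×64 σ = 20 HU patch for the descent regression, and 20 seeds of the
128×128×10 σ = 40 HU phantom for the two-arm comparison.

## Known limitations

* 2D slice-wise processing only; no 3D TV and no through-plane smoothing.
* The printed step magnitude at `lambda_scale=1.0` is aggressive on
  whole HU-range slices (see above); results at that setting depend
  strongly on the γ decay path.
* DICOM support covers single-frame CT image objects with rescale tags;
  RT-structure polygon contours are not parsed — masks are exchanged as
  rasters.
* The exact Wilcoxon path is O(n·Σranks) per call and capped at 25
  effective pairs by default.
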