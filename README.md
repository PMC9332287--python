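# atvseg

Anisotropic total-variation (ATV) denoising for CT, with the analysis
tools needed to quantify what denoising does to the image and to
downstream organ segmentation: a 2D noise-power-spectrum (NPS) estimator,
Dice/Wilcoxon contour-agreement statistics, a synthetic thorax phantom
with exact ground-truth masks, and a two-arm denoise → segment → score
pipeline.

## The problem

Radiotherapy planning on non-contrast CT requires delineating organs at
risk (heart, lungs, esophagus, spinal cord, liver), but image noise blurs
the already weak soft-tissue boundaries and degrades automatic
segmentation. An edge-preserving denoiser applied *before* segmentation
can recover some of that accuracy. This package implements such a
denoiser and everything needed to measure its effect — noise texture via
the NPS, and segmentation accuracy via the Dice similarity coefficient
(DSC) with paired Wilcoxon significance tests — on synthetic phantoms
where the ground truth is exact.

## The model

The denoiser minimises an edge-weighted total-variation objective over
each 2D slice V:

    R(V) = Σ_j  w_j · D(V_j)

    D(V(x,y)) = sqrt[ (V(x,y) − V(x−1,y))² + (V(x,y) − V(x,y−1))² ]

    w_j = Σ_{m ∈ N_j}  exp[ −((V_j − V_m)/δ)² ]

where `D` is the backward-difference gradient magnitude, `N_j` the four
first-order neighbours, and `w_j` a conduction-coefficient weight from
anisotropic diffusion filtering that vanishes across strong edges (so
they are preserved) and approaches 4 in flat regions (so noise is
smoothed). The threshold δ is set to the 80 % point of the cumulative
distribution of gradient magnitudes of the input slice.

R is minimised by 20 iterations of normalised steepest descent with an
adaptive step:

    V^{t+1} = V^t − λ ∇R(V^t)/|∇R(V^t)|,    λ = γ · sqrt(Σ_j (V_j^t)²)

γ starts at 1.0 and is multiplied by 0.8 whenever an iteration increased
R, so the schedule settles after overshoot. Weights are treated as
constants during differentiation (lagged diffusivity) and can be frozen
from the input slice or refreshed every iteration.

Segmentation agreement is scored with DSC = 2|A∩B| / (|A|+|B|), compared
between methods with the two-sided Wilcoxon matched-pairs signed-rank
test (exact by enumeration for small samples), with 0.80 as the
conventional acceptability level. Noise texture is summarised by the 2D
NPS of uniform-region ROIs, NPS(f) = (Δx·Δy/N²)·⟨|DFT₂(residual)|²⟩, and
the peak/mean spatial frequency of its radial profile.

## Worked example

`python examples/04_full_pipeline.py` builds the thorax phantom with
σ = 40 HU white noise (seed 1), runs the identical intensity-window
segmenter on the raw and on the ATV-denoised volume, and prints:

```
per-organ DSC vs ground truth (identical segmenter in both arms):
               raw  denoised
organ
lung_right   0.884     0.857
lung_left    0.879     0.962
esophagus    0.000     0.006
spinal_cord  0.000     0.000
heart        0.000     0.392
liver        0.120     0.788

liver-ROI noise power spectrum:
        raw: mean freq 0.395 mm^-1, peak freq 0.560 mm^-1, variance 1558 HU^2
   denoised: mean freq 0.185 mm^-1, peak freq 0.088 mm^-1, variance 4 HU^2
```

Read this as: the high-contrast lungs are segmentable either way; the
liver (25 HU of contrast against a σ = 40 HU noise floor) is destroyed in
the raw arm and recovered by denoising (DSC 0.12 → 0.79); the 5-HU
esophagus is unrecoverable in both arms; and the noise that denoising
leaves behind is weaker (variance 1558 → 4 HU²) and concentrated at low
spatial frequencies (mean NPS frequency 0.395 → 0.185 mm⁻¹) — the
characteristic smoothed texture.

The other examples exercise one capability each: `01_denoise_slice.py`
(the descent loop and γ schedule), `02_noise_power_spectrum.py` (Parseval
check, white vs correlated noise), `03_contour_agreement.py` (DSC tables
and Wilcoxon).

A thin CLI wraps the same functions: `atvseg phantom | denoise | nps |
dice | pipeline | convert` (see `--help` on each).

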