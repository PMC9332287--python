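"""Run the two-arm denoise/segment/score pipeline on a noisy phantom.

Generates the thorax-default phantom with sigma=40 HU white noise, runs
the identical intensity-window segmenter on the raw and the ATV-denoised
volume, and prints per-organ DSC for both arms plus the NPS summaries of
the liver ROIs.  Denoising should recover the soft-tissue organs the
noise destroyed (most visibly the liver) while the NPS mean frequency of
the denoised arm drops - noise power moves to low spatial frequencies.
"""

from dataclasses import replace

from atvseg import build_phantom, default_thorax_spec
from atvseg.phantom import NoiseSpec
from atvseg.pipeline import run_pipeline

spec = replace(default_thorax_spec(), noise=NoiseSpec("white", 40.0), seed=1)
bundle = build_phantom(spec)
report = run_pipeline(bundle)

print("per-organ DSC vs ground truth (identical segmenter in both arms):")
print(report.dsc_frame().round(3).to_string())

print("\nliver-ROI noise power spectrum:")
for arm in ("raw", "denoised"):
    s = report.nps[arm]
    print(f"  {arm:>9}: mean freq {s['mean_frequency_mm^-1']:.3f} mm^-1, "
          f"peak freq {s['peak_frequency_mm^-1']:.3f} mm^-1, "
          f"variance {s['variance_hu2']:.0f} HU^2")

d = report.denoiser_diagnostics[4]
print(f"\nmid-slice denoiser diagnostics: R {d['objective_initial']:.0f} -> "
      f"{d['objective_final']:.0f}, final gamma {d['gamma_final']:.3f}, "
      f"delta {d['delta']:.1f} HU")
print("(the liver DSC jump shows the segmentation benefit of denoising; "
      "the esophagus stays near zero in both arms - 5 HU of contrast is "
      "unrecoverable at this noise level)")
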