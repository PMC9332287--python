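"""Estimate the 2D NPS of white and correlated noise and summarise it.

Generates seeded uniform patches with white noise and with spatially
correlated noise (Gaussian kernel, 3 mm FWHM) at the same sigma, computes
the ensemble 2D NPS and its radial profile, and prints the integral
(which should recover sigma^2 - Parseval), the peak frequency and the
mean frequency.  Correlated noise concentrates power at low spatial
frequencies, so its peak/mean frequencies sit well below the white-noise
ones - the same signature that distinguishes denoised from raw CT noise.
"""

from atvseg import detrend, nps_2d, radial_profile, uniform_patch_stack
from atvseg.phantom import NoiseSpec

SIGMA = 25.0

for name, noise in [
    ("white", NoiseSpec("white", SIGMA)),
    ("correlated (3 mm FWHM)", NoiseSpec("correlated", SIGMA, kernel_fwhm=3.0)),
]:
    patches = uniform_patch_stack(32, 50.0, noise, seed=123, n=100)
    spectrum = nps_2d([detrend(p) for p in patches], spacing=(1.0, 1.0))
    profile = radial_profile(spectrum)
    print(f"{name} noise, sigma = {SIGMA} HU:")
    print(f"  NPS integral  : {spectrum.integral():8.1f} HU^2 "
          f"(sigma^2 = {SIGMA ** 2:.0f})")
    print(f"  peak frequency: {profile.peak_frequency:8.3f} mm^-1")
    print(f"  mean frequency: {profile.mean_frequency:8.3f} mm^-1")
print("(the NPS integral equals the noise variance; correlation shifts the "
      "peak and mean toward zero frequency)")
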