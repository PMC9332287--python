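"""Synthetic thorax CT phantoms with analytic ground-truth organ masks.

The generator emulates a non-contrast planning CT of the chest at desk
scale: ellipsoidal "organs" with tissue-typical HU means painted over a
soft-tissue background, plus additive noise that is either white or
spatially correlated (Gaussian-kernel-filtered white noise, variance
renormalised).  Because organs are analytic ellipsoids the ground-truth
masks are exact, so segmentation accuracy can be scored without any
manual contours.

The ``thorax-default`` preset contains the six organ-at-risk structures
scored in breast radiotherapy planning — heart, both lungs, esophagus,
spinal cord and liver — plus a vertebral bone ring (painted but not
scored).  The esophagus is deliberately low-contrast (5 HU above the
background), mimicking its poorly defined boundaries on non-contrast CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_core import BinaryMask, ImageVolume

__all__ = [
    "OrganSpec",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomBundle",
    "build_phantom",
    "uniform_patch_stack",
    "default_thorax_spec",
    "PRESETS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ: centre/semi-axes in voxel units, mean HU.

    Organs listed later in a PhantomSpec carve overlapping voxels out of
    earlier ones.  ``scored=False`` paints the structure into the image
    without exporting a ground-truth mask (used for bone).
    """

    label: str
    center: tuple[float, float, float]  # (x, y, z)
    axes: tuple[float, float, float]    # semi-axes (ax, ay, az)
    hu: float
    scored: bool = True


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: 'white' or 'correlated' with given sigma (HU).

    Correlated noise is white noise convolved in-plane with a Gaussian
    kernel of the given FWHM (mm) and rescaled so its standard deviation
    is exactly ``sigma`` again.
    """

    model: str = "white"
    sigma: float = 0.0
    kernel_fwhm: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("white", "correlated"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.model == "correlated" and (self.kernel_fwhm is None
                                           or self.kernel_fwhm <= 0):
            raise ValueError("correlated noise needs a positive kernel_fwhm")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]  # (nx, ny, nz)
    spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0
    organs: tuple[OrganSpec, ...] = ()
    background_hu: float = 30.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def with_noise(self, **kwargs) -> "PhantomSpec":
        return replace(self, noise=replace(self.noise, **kwargs))


@dataclass
class PhantomBundle:
    """A generated phantom: noisy volume, exact masks, noiseless volume."""

    volume: ImageVolume
    masks: dict[str, BinaryMask]
    noiseless: ImageVolume
    spec: PhantomSpec


def _ellipsoid_mask(shape_zyx, organ: OrganSpec) -> np.ndarray:
    nz, ny, nx = shape_zyx
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cx, cy, cz = organ.center
    ax, ay, az = organ.axes
    return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0


def _correlated_noise(rng: np.random.Generator, shape_zyx, sigma: float,
                      fwhm_mm: float, spacing) -> np.ndarray:
    """In-plane Gaussian-filtered white noise, renormalised to sigma."""
    dx, dy = spacing
    sig_pix = (fwhm_mm * _FWHM_TO_SIGMA / dy, fwhm_mm * _FWHM_TO_SIGMA / dx)
    white = rng.normal(0.0, 1.0, shape_zyx)
    filtered = np.stack([gaussian_filter(sl, sig_pix) for sl in white])
    # exact variance factor from the discrete impulse response
    nz, ny, nx = shape_zyx
    impulse = np.zeros((ny, nx))
    impulse[ny // 2, nx // 2] = 1.0
    kernel = gaussian_filter(impulse, sig_pix)
    energy = float((kernel ** 2).sum())
    return filtered * (sigma / np.sqrt(energy))


def build_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Paint organs in priority order, add seeded noise, return the bundle.

    The same spec (including seed) always produces a bit-identical bundle.
    An organ left with no voxels after later organs carve it raises.
    """
    nx, ny, nz = spec.shape
    shape_zyx = (nz, ny, nx)
    noiseless = np.full(shape_zyx, float(spec.background_hu))

    painted: dict[str, np.ndarray] = {}
    for organ in spec.organs:
        ell = _ellipsoid_mask(shape_zyx, organ)
        if not ell.any():
            raise ValueError(f"organ {organ.label!r} paints no voxels")
        for prev in painted.values():
            prev &= ~ell  # later organs carve earlier ones
        painted[organ.label] = ell
        noiseless[ell] = float(organ.hu)
    for organ in spec.organs:
        if not painted[organ.label].any():
            raise ValueError(
                f"organ {organ.label!r} is empty after later organs carved it"
            )

    rng = np.random.default_rng(spec.seed)
    if spec.noise.sigma == 0:
        noisy = noiseless.copy()
    elif spec.noise.model == "white":
        noisy = noiseless + rng.normal(0.0, spec.noise.sigma, shape_zyx)
    else:
        noisy = noiseless + _correlated_noise(
            rng, shape_zyx, spec.noise.sigma, spec.noise.kernel_fwhm, spec.spacing
        )

    metadata = {"kvp": 120.0, "phantom_seed": spec.seed}
    volume = ImageVolume.from_array(
        noisy, spacing=spec.spacing, slice_thickness=spec.slice_thickness,
        metadata=metadata,
    )
    clean = ImageVolume.from_array(
        noiseless, spacing=spec.spacing, slice_thickness=spec.slice_thickness,
        metadata=dict(metadata),
    )
    masks = {
        organ.label: BinaryMask(voxels=painted[organ.label], label=organ.label)
        for organ in spec.organs
        if organ.scored
    }
    return PhantomBundle(volume=volume, masks=masks, noiseless=clean, spec=spec)


def uniform_patch_stack(
    size: int,
    hu: float,
    noise: NoiseSpec,
    seed: int,
    n: int,
) -> list[np.ndarray]:
    """n independent seeded noisy patches of a uniform HU region.

    The workhorse input for NPS estimation tests: each patch is the given
    constant HU value plus one independent noise realisation.
    """
    if size < 8:
        raise ValueError("patch size must be at least 8 pixels")
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n):
        base = np.full((size, size), float(hu))
        if noise.sigma == 0:
            patches.append(base)
        elif noise.model == "white":
            patches.append(base + rng.normal(0.0, noise.sigma, (size, size)))
        else:
            field3d = _correlated_noise(
                rng, (1, size, size), noise.sigma, noise.kernel_fwhm, (1.0, 1.0)
            )
            patches.append(base + field3d[0])
    return patches


def _thorax_default() -> PhantomSpec:
    # 128 x 128 in-plane at 1 mm, 10 slices of 3 mm; HU values chosen at
    # tissue-typical levels with the esophagus only 5 HU above background.
    organs = (
        OrganSpec("lung_right", center=(38, 52, 4.5), axes=(22, 30, 5), hu=-700.0),
        OrganSpec("lung_left", center=(90, 52, 4.5), axes=(22, 30, 5), hu=-680.0),
        OrganSpec("heart", center=(64, 70, 4.5), axes=(18, 14, 4), hu=45.0),
        OrganSpec("liver", center=(40, 92, 4.5), axes=(22, 18, 5), hu=55.0),
        OrganSpec("vertebra", center=(64, 102, 4.5), axes=(11, 11, 5), hu=700.0,
                  scored=False),
        OrganSpec("spinal_cord", center=(64, 102, 4.5), axes=(3, 3, 5), hu=40.0),
        OrganSpec("esophagus", center=(64, 88, 4.5), axes=(4, 4, 5), hu=35.0),
    )
    return PhantomSpec(
        shape=(128, 128, 10),
        spacing=(1.0, 1.0),
        slice_thickness=3.0,
        organs=organs,
        background_hu=30.0,
        noise=NoiseSpec(model="white", sigma=0.0),
        seed=0,
    )


PRESETS = {"thorax-default": _thorax_default}


def default_thorax_spec(preset: str = "thorax-default") -> PhantomSpec:
    """Return a documented preset phantom spec; unknown names raise."""
    try:
        return PRESETS[preset]()
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        ) from None
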