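"""Two-dimensional noise-power-spectrum (NPS) estimation on uniform ROIs.

The 2D NPS of a CT image is estimated from square regions of interest
placed in a homogeneous area (the liver, in planning CT), detrended with a
low-order polynomial, and averaged over ROIs:

    NPS(fx, fy) = (dx * dy) / (Nx * Ny) * < |DFT2{ residual }|^2 >

with units HU^2 mm^2.  The radial 1D profile condenses the 2D spectrum
into annular averages over spatial frequency sqrt(fx^2 + fy^2), from which
two summary numbers are read: the peak frequency (location of the profile
maximum) and the mean frequency (power-weighted average frequency).
Noise-texture changes show up directly in these summaries: smoothing
shifts power, and hence both summaries, toward lower spatial frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import ImageVolume

__all__ = [
    "RoiSpec",
    "NPS2D",
    "NPSProfile",
    "extract_rois",
    "detrend",
    "nps_2d",
    "radial_profile",
]


@dataclass(frozen=True)
class RoiSpec:
    """A square ROI replicated over a consecutive slice range.

    ``center`` is the (x, y) pixel position of the ROI centre, ``size`` the
    side length in pixels, and ``slice_range`` the inclusive (first, last)
    slice indices.
    """

    center: tuple[int, int]
    size: int
    slice_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("ROI size must be at least 2 pixels")
        lo, hi = self.slice_range
        if hi < lo:
            raise ValueError(f"empty slice_range {self.slice_range}")

    @property
    def origin(self) -> tuple[int, int]:
        """Top-left (x0, y0) pixel of the ROI."""
        cx, cy = self.center
        return (cx - self.size // 2, cy - self.size // 2)


@dataclass
class NPS2D:
    """2D noise power spectrum in HU^2 mm^2 with frequency axes in mm^-1."""

    values: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray
    n_rois_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("NPS values must be a 2D grid")

    @property
    def frequency_step(self) -> tuple[float, float]:
        return (float(self.freq_x[1] - self.freq_x[0]),
                float(self.freq_y[1] - self.freq_y[0]))

    def integral(self) -> float:
        """Sum of NPS times the frequency-bin area: the noise variance."""
        dfx, dfy = self.frequency_step
        return float(self.values.sum() * dfx * dfy)


@dataclass
class NPSProfile:
    """Radial 1D NPS profile with peak/mean spatial-frequency summaries."""

    freq_bins: np.ndarray
    values: np.ndarray
    peak_frequency: float
    peak_value: float
    mean_frequency: float


def extract_rois(volume: ImageVolume, specs: list[RoiSpec]) -> list[np.ndarray]:
    """Cut one raw-HU patch per (spec, slice) pair.

    With the protocol of three ROIs over five consecutive slices this
    yields fifteen patches.  A spec that reaches outside the image bounds
    on any of its slices raises, naming the spec and the slice.
    """
    nz, ny, nx = volume.shape
    patches: list[np.ndarray] = []
    for spec in specs:
        x0, y0 = spec.origin
        lo, hi = spec.slice_range
        for k in range(lo, hi + 1):
            if not 0 <= k < nz:
                raise ValueError(f"ROI {spec} uses slice {k}, outside [0, {nz - 1}]")
            if x0 < 0 or y0 < 0 or x0 + spec.size > nx or y0 + spec.size > ny:
                raise ValueError(
                    f"ROI {spec} at slice {k} exceeds image bounds ({nx} x {ny})"
                )
            patch = volume.slices[k].pixels[y0:y0 + spec.size, x0:x0 + spec.size]
            patches.append(np.array(patch, dtype=np.float64))
    return patches


def detrend(patch: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract a least-squares 2D polynomial of the given total order.

    Order 0 removes the mean, order 1 a planar ramp, order 2 (the default)
    additionally removes slow quadratic shading, leaving a zero-trend noise
    residual.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2D, got shape {patch.shape}")
    if not 0 <= order <= 2:
        raise ValueError("detrending order must be 0, 1 or 2")
    n = patch.shape[0]
    # centred, scaled coordinates keep the Vandermonde well conditioned
    c = np.linspace(-1.0, 1.0, n)
    X, Y = np.meshgrid(c, c)
    cols = [np.ones(n * n)]
    if order >= 1:
        cols += [X.ravel(), Y.ravel()]
    if order >= 2:
        cols += [(X * X).ravel(), (X * Y).ravel(), (Y * Y).ravel()]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    return patch - (A @ coef).reshape(patch.shape)


def nps_2d(patches: list[np.ndarray], spacing: tuple[float, float]) -> NPS2D:
    """Ensemble NPS estimate from detrended patches.

    NPS = (dx * dy) / N^2 * mean over patches of |DFT2(residual)|^2, with
    the zero-frequency bin shifted to the centre of the grid.
    """
    if not patches:
        raise ValueError("need at least one patch")
    n = patches[0].shape[0]
    for p in patches:
        if p.shape != (n, n):
            raise ValueError(
                f"patch size mismatch: expected {(n, n)}, got {p.shape}"
            )
    dx, dy = (float(s) for s in spacing)
    acc = np.zeros((n, n))
    for p in patches:
        spectrum = np.fft.fftshift(np.fft.fft2(np.asarray(p, dtype=np.float64)))
        acc += np.abs(spectrum) ** 2
    values = acc / len(patches) * (dx * dy) / (n * n)
    freq_x = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    freq_y = np.fft.fftshift(np.fft.fftfreq(n, d=dy))
    return NPS2D(values=values, freq_x=freq_x, freq_y=freq_y,
                 n_rois_averaged=len(patches))


def radial_profile(nps: NPS2D, n_bins: int | None = None) -> NPSProfile:
    """Average the 2D NPS over annular radial-frequency bins.

    The DC sample is excluded (its residual power is a detrending
    artefact).  ``peak_frequency`` is the centre of the maximal bin and
    ``mean_frequency`` the power-weighted mean of the bin centres.  The
    default number of bins uses the smaller frequency-axis step as the
    radial bin width.
    """
    FX, FY = np.meshgrid(nps.freq_x, nps.freq_y)
    radius = np.hypot(FX, FY)
    r_max = float(radius.max())
    dfx, dfy = nps.frequency_step
    if n_bins is None:
        n_bins = int(np.ceil(r_max / min(dfx, dfy)))
    if n_bins < 2:
        raise ValueError("need at least 2 radial bins")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    keep = radius > 0  # exclude DC
    r = radius[keep]
    v = nps.values[keep]
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    values = np.zeros(n_bins)
    values[occupied] = sums[occupied] / counts[occupied]

    freq_bins = centers[occupied]
    prof = values[occupied]
    k_peak = int(np.argmax(prof))
    total = prof.sum()
    mean_frequency = float((freq_bins * prof).sum() / total) if total > 0 else 0.0
    return NPSProfile(
        freq_bins=freq_bins,
        values=prof,
        peak_frequency=float(freq_bins[k_peak]),
        peak_value=float(prof[k_peak]),
        mean_frequency=mean_frequency,
    )
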