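"""Spectral-domain OCT reconstruction.

Converts raw per-A-line interference spectra into depth-resolved intensity
B-scans and 3D volumes. The processing chain is the conventional SD-OCT one:
background (DC) subtraction, resampling from the spectrometer's uniform
wavelength grid to a uniform wavenumber grid, apodization, Fourier transform
along wavenumber, and magnitude extraction of the non-negative-depth half.

Units: wavelengths in nm, wavenumbers in rad/um, depths and voxel spacings
in um. Depth z and wavenumber k are Fourier conjugates through the fringe
term cos(2 k z); the depth pixel after an N-point transform over wavenumber
spacing dk is pi / (N dk).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrometerSpec",
    "RawSpectralScan",
    "KSpaceScan",
    "BScan",
    "OCTVolume",
    "subtract_background",
    "resample_to_wavenumber",
    "reconstruct_alines",
    "average_repeats",
    "assemble_volume",
]


@dataclass(frozen=True)
class SpectrometerSpec:
    """Spectrometer and light-source description.

    Defaults model a broadband visible-light source spanning 450-650 nm with
    a Gaussian spectral envelope of 89 nm FWHM centered at 550 nm, sampled at
    0.1 nm (2001 samples, endpoints inclusive). The sample count is
    configurable because camera pixel count and quoted spectral resolution
    need not coincide.
    """

    lambda_min_nm: float = 450.0
    lambda_max_nm: float = 650.0
    n_samples: int = 2001
    center_nm: float = 550.0
    fwhm_nm: float = 89.0
    line_rate_hz: float = 10e3  # informational
    exposure_us: float = 98.0  # informational

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min_nm < self.lambda_max_nm):
            raise ValueError("require 0 < lambda_min < lambda_max")
        if self.n_samples < 8:
            raise ValueError("need at least 8 spectral samples")

    @property
    def wavelength_nm(self) -> np.ndarray:
        """Uniform wavelength grid, ascending, endpoints inclusive."""
        return np.linspace(self.lambda_min_nm, self.lambda_max_nm, self.n_samples)

    @property
    def wavenumber_um(self) -> np.ndarray:
        """k = 2*pi/lambda in rad/um on the wavelength grid (descending)."""
        return 2.0 * np.pi / (self.wavelength_nm * 1e-3)

    @property
    def k_uniform_um(self) -> np.ndarray:
        """Uniform wavenumber target grid (ascending), same sample count."""
        k = self.wavenumber_um
        return np.linspace(k.min(), k.max(), self.n_samples)

    @property
    def depth_pixel_um(self) -> float:
        """Axial pixel size of the k-space DFT, pi / (N * dk)."""
        k = self.k_uniform_um
        dk = k[1] - k[0]
        return float(np.pi / (self.n_samples * dk))

    @property
    def max_depth_um(self) -> float:
        """Unambiguous single-sided imaging depth, pi / (2 dk)."""
        k = self.k_uniform_um
        return float(np.pi / (2.0 * (k[1] - k[0])))

    def source_envelope(self) -> np.ndarray:
        """Gaussian source spectrum on the wavelength grid (peak 1)."""
        sigma = self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        lam = self.wavelength_nm
        return np.exp(-0.5 * ((lam - self.center_nm) / sigma) ** 2)


@dataclass
class RawSpectralScan:
    """Per-A-line interference spectra on the spectrometer wavelength grid.

    ``spectra`` has shape (n_alines, n_samples) in arbitrary detector units.
    """

    spectra: np.ndarray
    spectrometer: SpectrometerSpec
    x_positions_um: np.ndarray | None = None
    repeat_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2D (n_alines, n_samples)")
        if self.spectra.shape[1] != self.spectrometer.n_samples:
            raise ValueError(
                f"spectral sample count {self.spectra.shape[1]} does not match "
                f"spectrometer grid ({self.spectrometer.n_samples})"
            )
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_alines(self) -> int:
        return self.spectra.shape[0]


@dataclass
class KSpaceScan:
    """Spectra resampled onto a uniform wavenumber grid (ascending rad/um)."""

    spectra: np.ndarray
    k_um: np.ndarray
    spectrometer: SpectrometerSpec
    meta: dict = field(default_factory=dict)


@dataclass
class BScan:
    """Depth-resolved magnitude image, shape (n_alines, depth_pixels)."""

    intensity: np.ndarray
    depth_pixel_um: float
    meta: dict = field(default_factory=dict)


@dataclass
class OCTVolume:
    """Reconstructed 3D intensity volume.

    ``intensity`` is ordered (x, y, z) with z increasing into the chip.
    ``voxel_spacing`` is (dx, dy, dz) in um. With the default acquisition
    geometry (2.5 x 2.5 x 0.9 mm over 384 x 384 x 1024 voxels) the spacing is
    approximately (6.51, 6.51, 0.879) um.
    """

    intensity: np.ndarray
    voxel_spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (x, y, z)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def subtract_background(scan: RawSpectralScan) -> RawSpectralScan:
    """Remove the per-sample mean spectrum (DC/background) from every A-line.

    The background is estimated by averaging all raw spectra of the dataset
    and subtracting it from each measurement; afterwards the A-line average
    of the output is the zero spectrum by construction.
    """
    if scan.n_alines < 2:
        raise ValueError(
            "background estimation needs at least 2 A-lines "
            "(background is the mean over A-lines)"
        )
    background = scan.spectra.mean(axis=0)
    out = replace(scan, spectra=scan.spectra - background)
    out.meta = dict(scan.meta, background_subtracted=True)
    return out


def resample_to_wavenumber(
    scan: RawSpectralScan, interpolation: str = "cubic"
) -> KSpaceScan:
    """Linearize spectra from the wavelength grid to a uniform wavenumber grid.

    The target grid is uniform in k = 2*pi/lambda between the extreme
    wavenumbers of the source grid, with the same sample count; endpoints are
    preserved exactly. ``interpolation`` is "cubic" (natural cubic spline,
    default) or "linear".
    """
    lam = scan.spectrometer.wavelength_nm
    if not np.all(np.diff(lam) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    k_src = scan.spectrometer.wavenumber_um  # descending with lambda ascending
    k_target = scan.spectrometer.k_uniform_um
    # sort source ascending in k for the interpolators
    k_asc = k_src[::-1]
    vals = scan.spectra[:, ::-1]
    if interpolation == "cubic":
        spl = CubicSpline(k_asc, vals, axis=1)
        out = spl(k_target)
    elif interpolation == "linear":
        out = np.stack([np.interp(k_target, k_asc, v) for v in vals])
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return KSpaceScan(
        spectra=out,
        k_um=k_target,
        spectrometer=scan.spectrometer,
        meta=dict(scan.meta, interpolation=interpolation),
    )


def reconstruct_alines(
    kscan: KSpaceScan,
    window: str = "hann",
    depth_pixels: int | None = 1024,
) -> BScan:
    """Fourier-transform k-space spectra into depth-resolved A-lines.

    Each A-line is apodized (``window``: "hann" or "none"), discrete-Fourier
    transformed along wavenumber, and reduced to the magnitude of the
    non-negative-depth half, cropped or zero-padded to ``depth_pixels``
    (``None`` keeps the full transform length, for energy checks). The depth
    pixel size pi/(N dk) is recorded on the result.
    """
    k = np.asarray(kscan.k_um)
    dk = np.diff(k)
    if not np.allclose(dk, dk[0], rtol=1e-8):
        raise ValueError("k grid must be uniform; run resample_to_wavenumber first")
    n = k.size
    if window == "hann":
        win = np.hanning(n)
    elif window == "none":
        win = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = kscan.spectra * win
    transform = np.fft.fft(spec, axis=1)
    mag = np.abs(transform)
    if depth_pixels is None:
        out = mag
    else:
        half = mag[:, : n // 2 + 1]
        if half.shape[1] >= depth_pixels:
            out = half[:, :depth_pixels]
        else:
            out = np.zeros((mag.shape[0], depth_pixels))
            out[:, : half.shape[1]] = half
    dz = np.pi / (n * float(dk[0]))
    return BScan(
        intensity=out,
        depth_pixel_um=dz,
        meta=dict(kscan.meta, window=window, depth_pixels=depth_pixels),
    )


def average_repeats(bscans: list[BScan] | list[np.ndarray], n: int | None = None) -> BScan:
    """Element-wise arithmetic mean of repeated magnitude B-scans.

    Magnitude (not complex) images are averaged; this is recorded in the
    provenance metadata.
    """
    if len(bscans) == 0:
        raise ValueError("no B-scans to average")
    if n is not None and n != len(bscans):
        raise ValueError(f"expected {n} repeats, got {len(bscans)}")
    arrays = [b.intensity if isinstance(b, BScan) else np.asarray(b) for b in bscans]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("B-scan shapes differ; cannot average")
    mean = np.mean(arrays, axis=0)
    dz = bscans[0].depth_pixel_um if isinstance(bscans[0], BScan) else float("nan")
    meta = dict(getattr(bscans[0], "meta", {}))
    meta.update(n_averages=len(bscans), averaging="magnitude")
    return BScan(intensity=mean, depth_pixel_um=dz, meta=meta)


def assemble_volume(
    bscans: list[BScan] | list[np.ndarray],
    voxel_spacing: tuple[float, float, float],
) -> OCTVolume:
    """Stack B-scans acquired along y into an (x, y, z) volume."""
    if len(bscans) == 0:
        raise ValueError("no B-scans to assemble")
    arrays = [b.intensity if isinstance(b, BScan) else np.asarray(b) for b in bscans]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("inconsistent B-scan shapes")
    if len(arrays) == 1:
        warnings.warn("assembling a single-slice volume", stacklevel=2)
    vol = np.stack(arrays, axis=1)  # (x, y, z)
    meta = dict(getattr(bscans[0], "meta", {}))
    meta["n_bscans"] = len(arrays)
    logger.info("assembled volume %s, spacing %s um", vol.shape, voxel_spacing)
    return OCTVolume(intensity=vol, voxel_spacing=tuple(voxel_spacing), meta=meta)
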