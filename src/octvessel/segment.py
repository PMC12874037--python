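"""Vessel lumen segmentation from OCT intensity volumes.

Vessels on the chip appear *dark*: the culture medium filling the lumen lacks
scattering particles, while the surrounding hydrogel suspension scatters and
therefore backscatters more light. Segmentation is intensity thresholding on
a depth band of the volume: select the 150 um slab containing the vascular
bed, (optionally) form a minimum-intensity projection for display, estimate a
global threshold separating the dark lumen class from the bright hydrogel
class, binarize, and remove small speckle components.

Threshold estimation works on log-intensities by default. Fully developed
speckle has exponential (or, after R-fold frame averaging, Gamma(R))
intensity statistics whose log is nearly symmetric, so a two-component
Gaussian EM split in the log domain separates the two classes reliably even
when the lumen occupies only a few percent of the voxels. The returned
threshold is the midpoint of the two class medians in the estimation domain
(the geometric midpoint of the lumen and hydrogel median intensities for the
log domain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DepthBand",
    "ProjectionImage",
    "VesselMask",
    "ThresholdEstimate",
    "NoVesselContrastError",
    "select_depth_band",
    "min_intensity_projection",
    "estimate_threshold",
    "binarize",
    "clean_mask",
    "dice_coefficient",
]


class NoVesselContrastError(ValueError):
    """Raised when the intensity data shows no lumen/hydrogel contrast."""


@dataclass(frozen=True)
class DepthBand:
    """Axial slab used for all vascular metrics.

    ``mode`` is "fixed" (use ``z_start_um``) or "auto" (place the band where
    the total intensity is minimal, since the vascular bed is dark).
    """

    z_extent_um: float = 150.0
    z_start_um: float = 0.0
    mode: str = "auto"

    def __post_init__(self) -> None:
        if self.z_extent_um <= 0:
            raise ValueError("band extent must be positive")
        if self.mode not in ("auto", "fixed"):
            raise ValueError("band mode must be 'auto' or 'fixed'")


@dataclass
class ProjectionImage:
    """Min-intensity projection over a depth band, min-max normalized to [0, 1]."""

    values: np.ndarray  # (nx, ny)
    band_indices: tuple[int, int]
    norm_min: float
    norm_max: float


@dataclass
class VesselMask:
    """Boolean vessel/lumen labeling (True = lumen) with voxel spacing in um.

    3D masks (band subvolume) are canonical for all metrics; 2D masks of a
    projection are display/fallback only.
    """

    mask: np.ndarray
    voxel_spacing: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if len(self.voxel_spacing) != self.mask.ndim:
            raise ValueError("voxel_spacing length must match mask dimensionality")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def vessel_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class ThresholdEstimate:
    """Result of global lumen/hydrogel threshold estimation.

    ``threshold`` is on the original intensity scale; ``split_threshold`` is
    the raw class-split boundary (EM decision point or Otsu threshold),
    exposed for comparison. Medians are reported on the original scale.
    """

    threshold: float
    lumen_median: float
    hydrogel_median: float
    split_threshold: float
    domain: str
    split: str


def select_depth_band(volume, band: DepthBand):
    """Extract the contiguous axial slab defined by ``band`` from a volume.

    Returns a new volume of the same type with ``meta['band_indices']``
    recording the half-open z index range. In "auto" mode the band is placed
    to minimize total intensity (vessels are dark); in "fixed" mode it starts
    at ``band.z_start_um``.
    """
    from .recon import OCTVolume  # local import to avoid cycle at module load

    dz = volume.voxel_spacing[2]
    nz = volume.intensity.shape[2]
    n_slices = int(round(band.z_extent_um / dz))
    n_slices = max(1, n_slices)
    if n_slices > nz:
        raise ValueError(
            f"band of {band.z_extent_um} um ({n_slices} slices) exceeds volume depth "
            f"({nz} slices of {dz:.3g} um)"
        )
    if band.mode == "fixed":
        z0 = int(round(band.z_start_um / dz))
        if z0 < 0 or z0 + n_slices > nz:
            raise ValueError(
                f"band [{band.z_start_um}, {band.z_start_um + band.z_extent_um}] um "
                f"lies outside the volume depth range"
            )
    else:
        profile = volume.intensity.sum(axis=(0, 1))
        sums = np.convolve(profile, np.ones(n_slices), mode="valid")
        z0 = int(np.argmin(sums))
    slab = volume.intensity[:, :, z0 : z0 + n_slices]
    meta = dict(volume.meta, band_indices=(z0, z0 + n_slices), band_extent_um=band.z_extent_um)
    logger.info("selected depth band z=[%d, %d) (%d slices)", z0, z0 + n_slices, n_slices)
    return OCTVolume(intensity=slab, voxel_spacing=volume.voxel_spacing, meta=meta)


def min_intensity_projection(subvolume) -> ProjectionImage:
    """Per-(x, y) column minimum over z, min-max normalized to [0, 1]."""
    data = subvolume.intensity if hasattr(subvolume, "intensity") else np.asarray(subvolume)
    if data.ndim != 3 or data.size == 0:
        raise ValueError("projection needs a non-empty 3D slab")
    proj = data.min(axis=2)
    lo, hi = float(proj.min()), float(proj.max())
    if hi == lo:
        raise ValueError("zero dynamic range: slab is constant, cannot normalize")
    band = getattr(subvolume, "meta", {}).get("band_indices", (0, data.shape[2]))
    return ProjectionImage(values=(proj - lo) / (hi - lo), band_indices=tuple(band), norm_min=lo, norm_max=hi)


def _em_two_gaussians(
    w: np.ndarray, n_iter: int = 40, tied: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-component 1D Gaussian EM, best of several deterministic inits.

    ``tied=True`` (default) shares one variance between the components. For
    speckle this is the physically correct model: lumen and hydrogel
    intensities are the same R-averaged speckle law up to a scale factor, so
    their log-intensity distributions are identical up to a shift. Tying the
    variance also prevents the classic imbalance pathology where one broad
    component swallows a sub-percent dark class together with the bright
    class's tail. The dark class fraction is unknown a priori, so EM starts
    from several low-quantile initializations and the highest-likelihood fit
    wins; no random restarts, fully deterministic. Returns (means, sds,
    weights) sorted by mean.
    """
    best = None
    best_ll = -np.inf
    for q_low, pi_low in ((0.002, 0.02), (0.02, 0.1), (0.3, 0.5)):
        mu = np.quantile(w, [q_low, 0.60])
        if mu[0] == mu[1]:
            mu = np.array([w.min(), w.max()])
        sd = np.full(2, max(w.std() / 2.0, 1e-9))
        pi = np.array([pi_low, 1.0 - pi_low])
        for _ in range(n_iter):
            mu_prev = mu.copy()
            logp = -0.5 * ((w[:, None] - mu) / sd) ** 2 - np.log(sd) + np.log(pi)
            m = logp.max(axis=1, keepdims=True)
            r = np.exp(logp - m)
            r /= r.sum(axis=1, keepdims=True)
            nk = r.sum(axis=0) + 1e-12
            pi = nk / len(w)
            mu = (r * w[:, None]).sum(axis=0) / nk
            var = (r * (w[:, None] - mu) ** 2).sum(axis=0) / nk
            if tied:
                pooled = float((var * nk).sum() / nk.sum())
                sd = np.full(2, np.sqrt(pooled) + 1e-9)
            else:
                sd = np.sqrt(var) + 1e-9
            if np.abs(mu - mu_prev).max() < 1e-7:
                break
        logp = -0.5 * ((w[:, None] - mu) / sd) ** 2 - np.log(sd) + np.log(pi)
        m = logp.max(axis=1, keepdims=True)
        ll = float((m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True))).sum())
        if ll > best_ll:
            best_ll = ll
            best = (mu, sd, pi)
    mu, sd, pi = best
    order = np.argsort(mu)
    return mu[order], sd[order], pi[order]


def _gaussian_crossing(mu, sd, pi) -> float:
    """Decision boundary between two weighted 1D Gaussians, taken in [mu0, mu1]."""
    a = 1.0 / (2 * sd[1] ** 2) - 1.0 / (2 * sd[0] ** 2)
    b = mu[0] / sd[0] ** 2 - mu[1] / sd[1] ** 2
    c = (
        mu[1] ** 2 / (2 * sd[1] ** 2)
        - mu[0] ** 2 / (2 * sd[0] ** 2)
        + np.log((pi[0] * sd[1]) / (pi[1] * sd[0]))
    )
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return 0.5 * (mu[0] + mu[1])
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0.5 * (mu[0] + mu[1])
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= mu[0]) & (roots <= mu[1])]
    if inside.size:
        return float(inside[0])
    return 0.5 * (mu[0] + mu[1])


def estimate_threshold(
    intensities: np.ndarray,
    domain: str = "log",
    split: str = "em",
    min_separation_sigmas: float = 3.5,
    max_points: int = 12000,
) -> ThresholdEstimate:
    """Estimate the global lumen/hydrogel intensity threshold.

    The data is first split into a dark (lumen) and a bright (hydrogel) class
    -- by a two-component Gaussian EM fit (``split="em"``, default, robust to
    extreme class imbalance) or by Otsu's between-class-variance criterion
    (``split="otsu"``) -- in ``domain`` ("log", default, or "linear"). The
    returned threshold is the midpoint of the two class medians in that
    domain, mapped back to the intensity scale.

    Raises :class:`NoVesselContrastError` when the class medians are closer
    than ``min_separation_sigmas`` within-class standard deviations: splitting
    a single speckle mode yields a separation of about 2.5-3 sigma, while a
    genuine dark lumen class at the working contrast (mean ratio ~0.1) sits
    beyond 5 sigma, so 3.5 cleanly rejects contrast-free volumes (detection
    limit around mean ratio 0.35). Deterministic: the EM fit uses a strided
    subsample of at most ``max_points`` values.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 16:
        raise ValueError("too few intensity samples for threshold estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities contain non-finite values")
    lo = float(x.min())
    span = float(x.max()) - lo
    if span == 0:
        raise NoVesselContrastError("constant intensities: no vessel contrast")
    delta = 1e-6 * span
    shifted = x - lo + delta  # strictly positive support
    w = np.log(shifted) if domain == "log" else shifted
    if domain not in ("log", "linear"):
        raise ValueError("domain must be 'log' or 'linear'")

    step = max(1, w.size // max_points)
    sub = w[::step]
    if split == "em":
        mu, sd, pi = _em_two_gaussians(sub)
        cut = _gaussian_crossing(mu, sd, pi)
        sigma = float(sd[0])
    elif split == "otsu":
        from skimage.filters import threshold_otsu

        cut = float(threshold_otsu(sub))
        sigma = None
    else:
        raise ValueError("split must be 'em' or 'otsu'")

    low = w[w < cut]
    high = w[w >= cut]
    if low.size == 0 or high.size == 0:
        raise NoVesselContrastError("class split degenerate: no vessel contrast")
    m1, m2 = float(np.median(low)), float(np.median(high))

    if sigma is None:  # pooled within-class spread for the Otsu split
        sigma = float(
            np.sqrt((low.size * low.var() + high.size * high.var()) / w.size)
        )
    if (m2 - m1) < min_separation_sigmas * max(sigma, 1e-12):
        raise NoVesselContrastError(
            f"no vessel contrast: class medians separated by "
            f"{(m2 - m1) / max(sigma, 1e-12):.2f} sigma "
            f"< required {min_separation_sigmas}"
        )

    mid = 0.5 * (m1 + m2)
    to_orig = (lambda v: np.exp(v) + lo - delta) if domain == "log" else (lambda v: v + lo - delta)
    return ThresholdEstimate(
        threshold=float(to_orig(mid)),
        lumen_median=float(to_orig(m1)),
        hydrogel_median=float(to_orig(m2)),
        split_threshold=float(to_orig(cut)),
        domain=domain,
        split=split,
    )


def binarize(data, threshold: float, voxel_spacing=None) -> VesselMask:
    """Label voxels strictly below ``threshold`` as vessel lumen.

    Ties go to hydrogel (strict inequality). Works on the 3D band subvolume
    (canonical) or a 2D projection. ``data`` may be an OCTVolume, a
    ProjectionImage, or a bare array (then ``voxel_spacing`` is required).
    """
    if hasattr(data, "intensity"):
        arr = data.intensity
        spacing = data.voxel_spacing
        meta = dict(data.meta)
    elif isinstance(data, ProjectionImage):
        arr = data.values
        spacing = voxel_spacing if voxel_spacing is not None else (1.0, 1.0)
        meta = {"band_indices": data.band_indices}
    else:
        arr = np.asarray(data)
        if voxel_spacing is None:
            voxel_spacing = (1.0,) * arr.ndim
        spacing = voxel_spacing
        meta = {}
    meta["threshold"] = float(threshold)
    return VesselMask(mask=arr < threshold, voxel_spacing=tuple(spacing), meta=meta)


def clean_mask(
    mask: VesselMask,
    min_component_voxels: int = 27,
    closing_radius: int = 0,
) -> VesselMask:
    """Remove small speckle components; optionally close small gaps.

    Connected components (26-connectivity in 3D, 8 in 2D) smaller than
    ``min_component_voxels`` are discarded. ``closing_radius > 0`` applies a
    ball/disk morphological closing first.
    """
    m = mask.mask
    if closing_radius > 0:
        from skimage.morphology import ball, disk

        selem = ball(closing_radius) if m.ndim == 3 else disk(closing_radius)
        m = ndimage.binary_closing(m, structure=selem)
    if min_component_voxels > 0:
        structure = np.ones((3,) * m.ndim, dtype=bool)
        labels, n = ndimage.label(m, structure=structure)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_component_voxels
            keep[0] = False
            m = keep[labels]
    meta = dict(mask.meta, min_component_voxels=min_component_voxels, closing_radius=closing_radius)
    return VesselMask(mask=m, voxel_spacing=mask.voxel_spacing, meta=meta)


def dice_coefficient(a: np.ndarray | VesselMask, b: np.ndarray | VesselMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    am = a.mask if isinstance(a, VesselMask) else np.asarray(a, bool)
    bm = b.mask if isinstance(b, VesselMask) else np.asarray(b, bool)
    if am.shape != bm.shape:
        raise ValueError("mask shapes differ")
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(am, bm).sum() / denom)
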