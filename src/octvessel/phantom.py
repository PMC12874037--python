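"""Synthetic vascular phantoms and OCT forward simulation.

The package's downstream stages (reconstruction, segmentation, morphometry)
are validated against phantoms with exactly known ground truth:

* a stochastic branched network of straight capsule segments (cylinders with
  hemispherical caps) grown inside the chip volume, with exact analytic
  centerline graph, bifurcation count, and length;
* a voxelization of that network (truth mask);
* an intensity volume with fully developed speckle -- exponential intensity
  statistics, mean low inside the lumen (no scatterers in the culture medium)
  and high in the hydrogel (scattering suspension), optionally averaged over
  R independent realizations to emulate R-fold B-scan averaging;
* optionally, raw spectral interferograms from point reflectors, for testing
  the reconstruction chain end to end.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .recon import OCTVolume, RawSpectralScan, SpectrometerSpec
from .segment import VesselMask

logger = logging.getLogger(__name__)

__all__ = [
    "VesselSegment",
    "VesselNetworkSpec",
    "NetworkTruth",
    "ReflectorSet",
    "generate_network",
    "evolve_network",
    "rasterize",
    "capsule_volume_fraction",
    "render_volume",
    "simulate_raw_scan",
    "make_y_segments",
]


@dataclass(frozen=True)
class VesselSegment:
    """Straight capsule segment: axis from start to end (um), radius (um)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_um: float
    parent: int | None = None
    generation: int = 0

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))


@dataclass(frozen=True)
class VesselNetworkSpec:
    """Parameters of the stochastic branched-network generator.

    Defaults describe a chip-scale network in the default field of view
    (2500 x 2500 x 900 um at 384 x 384 x 1024 voxels): a handful of seed
    vessels of 15-40 um radius, segments of 150-350 um, branching with
    probability 0.45 per segment, radii shrinking by ``radius_decay`` per
    generation, daughters kept at least ``min_branch_separation_um`` apart
    (axis-to-axis, on top of the sum of radii). Vessels run predominantly in
    the chip plane; ``z_direction_scale`` sets the out-of-plane component.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (384, 384, 1024)
    voxel_spacing: tuple[float, float, float] = (2500 / 384, 2500 / 384, 900 / 1024)
    n_seed_vessels: int = 3
    branching_prob: float = 0.45
    radius_range_um: tuple[float, float] = (15.0, 40.0)
    radius_decay: float = 0.82
    min_branch_separation_um: float = 30.0
    segment_length_range_um: tuple[float, float] = (150.0, 350.0)
    max_generations: int = 4  # branching depth: daughters advance one generation
    max_path_segments: int = 6  # straight-growth segments per branch before the tip rests
    max_segments: int = 200
    branch_angle_deg: tuple[float, float] = (50.0, 90.0)
    direction_jitter_deg: float = 12.0
    z_direction_scale: float = 0.15
    z_band_um: tuple[float, float] | None = None  # confine axes to this z range
    min_segments: int = 1  # regenerate (deterministically) below this richness
    #: optional chip quality band: accept only draws whose analytic length
    #: (over generations <= target_length_generations, or all) falls inside;
    #: emulates the seeding-density consistency of real chip batches
    target_length_range_um: tuple[float, float] | None = None
    target_length_generations: int | None = None

    def physical_size_um(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing)


@dataclass
class NetworkTruth:
    """Exact ground truth for a generated network.

    ``graph`` is the analytic centerline graph (nodes at segment endpoints,
    positions in um, edges with ``length_um``); ``n_bifurcations`` counts
    nodes of degree >= 3; ``total_length_um`` sums segment lengths.
    """

    segments: list[VesselSegment]
    graph: nx.Graph
    n_bifurcations: int
    total_length_um: float
    max_radius_um: float
    spec: VesselNetworkSpec | None = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReflectorSet:
    """Point reflectors for the raw-signal forward model.

    ``reflectors`` is a list of (depth_um, reflectivity in [0, 1]).
    """

    reflectors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for z, r in self.reflectors:
            if z < 0:
                raise ValueError("reflector depth must be >= 0")
            if not (0.0 <= r <= 1.0):
                raise ValueError("reflectivity must be in [0, 1]")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v around a unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2 (3D, clamped)."""
    p1, q1, p2, q2 = (np.asarray(a, float) for a in (p1, q1, p2, q2))
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def _adjacent(i: int, j: int, segments: list[VesselSegment]) -> bool:
    """Segments that share a tree endpoint (parent/child/sibling)."""
    si, sj = segments[i], segments[j]
    return (
        si.parent == j
        or sj.parent == i
        or (si.parent is not None and si.parent == sj.parent)
        or (
            si.parent is not None
            and sj.parent is not None
            and (si.parent == segments[sj.parent].parent or sj.parent == segments[si.parent].parent)
        )
    )


def _clearance_ok(
    cand_start, cand_end, cand_radius, cand_parent, segments, spec
) -> bool:
    for j, other in enumerate(segments):
        if cand_parent is not None and j == cand_parent:
            continue  # the parent legitimately touches at the junction
        if cand_parent is not None and other.parent == cand_parent:
            # sibling: shares the junction point; require clearance between
            # the outer halves so the daughters actually diverge
            a = np.asarray(cand_start, float)
            b = np.asarray(cand_end, float)
            oa = np.asarray(other.start, float)
            ob = np.asarray(other.end, float)
            d = _segment_distance(a + 0.45 * (b - a), b, oa + 0.45 * (ob - oa), ob)
            if d < cand_radius + other.radius_um + 0.5 * spec.min_branch_separation_um:
                return False
            continue
        d = _segment_distance(cand_start, cand_end, other.start, other.end)
        if d < cand_radius + other.radius_um + spec.min_branch_separation_um:
            return False
    return True


def _inside(point: np.ndarray, spec: VesselNetworkSpec, margin: float) -> bool:
    size = spec.physical_size_um()
    if not np.all((point >= margin) & (point <= size - margin)):
        return False
    if spec.z_band_um is not None:
        z0, z1 = spec.z_band_um
        if not (z0 + margin <= point[2] <= z1 - margin):
            return False
    return True


def _random_direction(rng: np.random.Generator, spec: VesselNetworkSpec) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    return _unit(np.array([np.cos(theta), np.sin(theta), rng.normal(0, spec.z_direction_scale)]))


def _jitter_axis(rng: np.random.Generator, direction: np.ndarray, spec: VesselNetworkSpec) -> np.ndarray:
    """Rotation axis for direction jitter; pure z when the network is planar."""
    if spec.z_direction_scale == 0:
        return np.array([0.0, 0.0, 1.0])
    return _unit(np.cross(direction, _random_direction(rng, spec) + 1e-9))


def generate_network(spec: VesselNetworkSpec) -> NetworkTruth:
    """Grow a seeded stochastic branched capsule network.

    Each seed vessel grows segment by segment; at each step the tip either
    bifurcates (probability ``branching_prob``) into two daughters separated
    by a random branch angle, with radii scaled by ``radius_decay``, or
    continues with a small direction jitter. Candidate segments must stay
    inside the volume (with a margin of their radius) and keep the configured
    axis-to-axis clearance from all non-adjacent segments; candidates are
    re-drawn a bounded number of times, after which the tip terminates.

    Identical spec (including seed) reproduces an identical segment list.
    A crowded draw can terminate early; if fewer than ``min_segments``
    segments grow, the network is regrown from a deterministically derived
    seed, so reproducibility is preserved.
    """
    def gauge_length(t: NetworkTruth) -> float:
        gens = spec.target_length_generations
        if gens is None:
            return t.total_length_um
        return float(
            sum(s.length_um for s in t.segments if s.generation <= gens)
        )

    truth = None
    best = None
    best_dev = np.inf
    for attempt in range(40):
        sub = spec if attempt == 0 else replace(spec, seed=(spec.seed + 1000003 * attempt) % (2**31))
        truth = _generate_network_once(sub)
        if len(truth.segments) < spec.min_segments:
            continue
        if spec.target_length_range_um is None:
            best = truth
            break
        lo, hi = spec.target_length_range_um
        length = gauge_length(truth)
        dev = max(lo - length, length - hi, 0.0)
        if dev == 0.0:
            best = truth
            break
        if dev < best_dev:
            best, best_dev = truth, dev
    truth = best if best is not None else truth
    truth.spec = spec
    return truth


def _generate_network_once(spec: VesselNetworkSpec) -> NetworkTruth:
    lo, hi = spec.radius_range_um
    if lo <= 0:
        raise ValueError("segment radii must be positive")
    min_resolvable = max(spec.voxel_spacing)
    if lo < min_resolvable:
        raise ValueError(
            f"minimum radius {lo} um is below one voxel spacing "
            f"({min_resolvable:.3g} um) and cannot be resolved on this grid"
        )
    rng = np.random.default_rng(spec.seed)
    segments: list[VesselSegment] = []
    n_bifurcations = 0
    # tips: (position, direction, radius, generation, parent index, path steps)
    tips: list[tuple[np.ndarray, np.ndarray, float, int, int | None, int]] = []

    for _ in range(spec.n_seed_vessels):
        for _attempt in range(50):
            radius = rng.uniform(*spec.radius_range_um)
            margin = radius + min_resolvable
            size = spec.physical_size_um()
            if spec.z_band_um is not None:
                z = rng.uniform(spec.z_band_um[0] + margin, spec.z_band_um[1] - margin)
            else:
                z = rng.uniform(margin, size[2] - margin)
            pos = np.array(
                [rng.uniform(margin, size[0] - margin), rng.uniform(margin, size[1] - margin), z]
            )
            direction = _random_direction(rng, spec)
            tips.append((pos, direction, radius, 0, None, 0))
            break

    while tips and len(segments) < spec.max_segments:
        pos, direction, radius, gen, parent, steps = tips.pop(0)
        if radius < min_resolvable:
            continue
        placed = None
        for _attempt in range(20):
            length = rng.uniform(*spec.segment_length_range_um)
            if parent is None and _attempt > 0:
                # a root tip is free to restart in any direction
                d = _random_direction(rng, spec)
            else:
                # widen the jitter with each failed attempt so growth deflects
                # away from walls and neighboring vessels, but never so far
                # that a vessel doubles back onto the path it came from
                sd = min(spec.direction_jitter_deg * (1 + _attempt), 30.0)
                jitter = np.deg2rad(rng.normal(0, sd))
                axis = _jitter_axis(rng, direction, spec)
                d = _unit(_rotate(direction, axis, jitter))
                if np.dot(d, direction) < np.cos(np.deg2rad(60.0)):
                    continue
            end = pos + d * length
            if not _inside(end, spec, radius + min_resolvable):
                continue
            if not _clearance_ok(pos, end, radius, parent, segments, spec):
                continue
            placed = (end, d, length)
            break
        if placed is None:
            continue
        end, d, length = placed
        idx = len(segments)
        segments.append(
            VesselSegment(tuple(pos), tuple(end), radius, parent=parent, generation=gen)
        )
        if gen < spec.max_generations and rng.random() < spec.branching_prob:
            angle = np.deg2rad(rng.uniform(*spec.branch_angle_deg))
            rot_axis = _unit(
                np.array([0.0, 0.0, 1.0]) + rng.normal(0, spec.z_direction_scale, 3)
            )
            d1 = _unit(_rotate(d, rot_axis, angle / 2))
            d2 = _unit(_rotate(d, rot_axis, -angle / 2))
            child_r = radius * spec.radius_decay
            tips.append((end, d1, child_r, gen + 1, idx, 0))
            tips.append((end, d2, child_r, gen + 1, idx, 0))
            n_bifurcations += 1
        elif steps + 1 < spec.max_path_segments:
            tips.append((end, d, radius, gen, idx, steps + 1))

    truth = _truth_from_segments(segments, spec)
    logger.info(
        "generated network: %d segments, %d bifurcations, %.0f um total",
        len(segments),
        truth.n_bifurcations,
        truth.total_length_um,
    )
    return truth


def _truth_from_segments(
    segments: list[VesselSegment], spec: VesselNetworkSpec | None = None
) -> NetworkTruth:
    """Build the analytic centerline graph and summary stats from segments."""
    g = nx.Graph()

    def node_key(p):
        return tuple(np.round(np.asarray(p, float), 6))

    for i, s in enumerate(segments):
        a, b = node_key(s.start), node_key(s.end)
        g.add_node(a, pos=np.asarray(s.start))
        g.add_node(b, pos=np.asarray(s.end))
        g.add_edge(a, b, length_um=s.length_um, radius_um=s.radius_um, segment=i)
    n_bif = sum(1 for _, deg in g.degree if deg >= 3)
    total = float(sum(s.length_um for s in segments))
    max_r = float(max((s.radius_um for s in segments), default=0.0))
    return NetworkTruth(
        segments=segments,
        graph=g,
        n_bifurcations=n_bif,
        total_length_um=total,
        max_radius_um=max_r,
        spec=spec,
    )


# --- treatment-course evolution -------------------------------------------

#: Per-condition evolution rules, applied per day after ``onset_day``.
#: control: static network. high_glucose: vessel regression -- radii shrink
#: and terminal branches progressively die off. vegf: growth -- radii
#: inflate and one deeper branch generation appears each day.
COURSE_RULES = {
    "control": {},
    "high_glucose": {"radius_factor_per_day": 0.85, "leaf_survival_per_day": 0.55},
    "vegf": {"radius_factor_per_day": 1.22, "generations_gained_per_day": 1},
}

ONSET_DAY = 3  # effects begin after this day
BASELINE_GENERATIONS = 2  # generations visible at baseline (days <= onset)


def evolve_network(
    truth: NetworkTruth,
    condition: str,
    day: int,
    rules: dict | None = None,
    baseline_generations: int = BASELINE_GENERATIONS,
    onset_day: int = ONSET_DAY,
) -> NetworkTruth:
    """Deterministic per-day view of a chip's network under a treatment rule.

    The chip's master tree (generated once, deeper than the baseline) is
    filtered and rescaled: the control sees the baseline subtree unchanged on
    every day; under the regression rule the deepest visible generation is
    dropped and radii shrink per day after onset; under the growth rule a
    deeper generation becomes visible and radii inflate per day after onset.
    """
    all_rules = rules if rules is not None else COURSE_RULES
    rule = all_rules[condition]
    days_on = max(0, day - onset_day)
    vis_gen = baseline_generations + rule.get("generations_gained_per_day", 0) * days_on
    factor = rule.get("radius_factor_per_day", 1.0) ** days_on

    keep = {i for i, s in enumerate(truth.segments) if s.generation <= vis_gen}
    survival = rule.get("leaf_survival_per_day")
    if survival is not None and days_on > 0:
        # progressive terminal die-back: each segment carries a fixed uniform
        # draw (chip-seeded, so removals are nested across days); terminal
        # branches whose draw falls below the growing death threshold are
        # removed, iterating so exposed parents can die the same day
        seed = truth.spec.seed if truth.spec is not None else 0
        u = np.random.default_rng(int(seed) ^ 0x5EED).random(len(truth.segments))
        death = 1.0 - survival**days_on
        while True:
            children: dict[int, int] = {}
            for i in keep:
                p = truth.segments[i].parent
                if p is not None and p in keep:
                    children[p] = children.get(p, 0) + 1
            doomed = {
                i
                for i in keep
                if children.get(i, 0) == 0
                and truth.segments[i].generation > 0  # root vessels persist
                and u[i] < death
            }
            if not doomed:
                break
            keep -= doomed
    # keep the tree closed under parents so it stays connected
    index_map: dict[int, int] = {}
    new_segments: list[VesselSegment] = []
    for i, s in enumerate(truth.segments):
        if i not in keep:
            continue
        parent = index_map.get(s.parent) if s.parent is not None else None
        index_map[i] = len(new_segments)
        new_segments.append(replace(s, radius_um=s.radius_um * factor, parent=parent))
    out = _truth_from_segments(new_segments, truth.spec)
    out.meta = dict(condition=condition, day=day, radius_factor=factor, visible_generations=vis_gen)
    return out


def make_y_segments(
    center=(32.0, 32.0, 32.0),
    stem_length: float = 30.0,
    arm_length: float = 25.0,
    radius: float = 3.0,
    arm_angle_deg: float = 35.0,
) -> list[VesselSegment]:
    """Minimal 'Y' fixture: a stem splitting into two arms at one junction."""
    c = np.asarray(center, float)
    stem_start = c - np.array([stem_length, 0, 0])
    a = np.deg2rad(arm_angle_deg)
    arm1 = c + arm_length * np.array([np.cos(a), np.sin(a), 0.0])
    arm2 = c + arm_length * np.array([np.cos(a), -np.sin(a), 0.0])
    return [
        VesselSegment(tuple(stem_start), tuple(c), radius, parent=None, generation=0),
        VesselSegment(tuple(c), tuple(arm1), radius, parent=0, generation=1),
        VesselSegment(tuple(c), tuple(arm2), radius, parent=0, generation=1),
    ]


def rasterize(
    segments: list[VesselSegment] | NetworkTruth,
    grid_shape: tuple[int, int, int],
    voxel_spacing: tuple[float, float, float],
) -> VesselMask:
    """Voxelize capsule segments: a voxel is lumen iff its center lies within
    the segment radius of the segment axis.

    Voxel centers sit at ``(i + 0.5) * spacing``. Deterministic. Radii below
    one voxel spacing are rejected as unresolvable; segment endpoints must lie
    inside the physical volume.
    """
    if isinstance(segments, NetworkTruth):
        segments = segments.segments
    spacing = np.asarray(voxel_spacing, float)
    shape = tuple(int(n) for n in grid_shape)
    size = np.asarray(shape) * spacing
    mask = np.zeros(shape, dtype=bool)
    min_resolvable = float(spacing.max())
    for s in segments:
        if s.radius_um <= 0:
            raise ValueError("segment radius must be positive")
        if s.radius_um < min_resolvable:
            raise ValueError(
                f"segment radius {s.radius_um} um is below one voxel spacing "
                f"({min_resolvable:.3g} um): unresolvable on this grid"
            )
        for p in (s.start, s.end):
            if np.any(np.asarray(p) < -1e-9) or np.any(np.asarray(p) > size + 1e-9):
                raise ValueError(f"segment endpoint {p} outside the physical volume {size}")
        a = np.asarray(s.start, float)
        b = np.asarray(s.end, float)
        r = s.radius_um
        lo_idx = np.maximum(np.floor((np.minimum(a, b) - r) / spacing - 0.5).astype(int), 0)
        hi_idx = np.minimum(
            np.ceil((np.maximum(a, b) + r) / spacing - 0.5).astype(int) + 1, np.asarray(shape)
        )
        if np.any(lo_idx >= hi_idx):
            continue
        grids = [
            (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * spacing[d] for d in range(3)
        ]
        X, Y, Z = np.meshgrid(*grids, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-12:
            dist = np.linalg.norm(pts - a, axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            dist = np.linalg.norm(pts - proj, axis=-1)
        sub = dist <= r
        mask[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]] |= sub
    return VesselMask(mask=mask, voxel_spacing=tuple(voxel_spacing))


def capsule_volume_fraction(
    segments: list[VesselSegment] | NetworkTruth,
    grid_shape: tuple[int, int, int],
    voxel_spacing: tuple[float, float, float],
    supersample: int = 3,
) -> float:
    """Capsule-union volume fraction estimated on a ``supersample``-times
    finer grid (handles junction overlaps exactly in the limit)."""
    if isinstance(segments, NetworkTruth):
        segments = segments.segments
    fine_shape = tuple(int(n) * supersample for n in grid_shape)
    fine_spacing = tuple(s / supersample for s in voxel_spacing)
    fine = rasterize(segments, fine_shape, fine_spacing)
    return float(fine.mask.mean())


def render_volume(
    mask: VesselMask,
    hydrogel_mean: float = 1.0,
    lumen_mean: float = 0.1,
    n_averages: int = 6,
    seed: int | None = None,
) -> OCTVolume:
    """Render a speckled intensity volume from a truth mask.

    Voxel intensities are independent fully-developed-speckle draws:
    exponential with mean ``lumen_mean`` inside vessels and ``hydrogel_mean``
    outside. ``n_averages`` emulates R-fold B-scan averaging; the mean of R
    i.i.d. exponentials is drawn directly as Gamma(R, mean/R), which is the
    identical law.
    """
    if hydrogel_mean <= 0 or lumen_mean <= 0:
        raise ValueError("intensity means must be positive")
    if lumen_mean >= hydrogel_mean:
        raise ValueError(
            "lumen mean must be below hydrogel mean (vessels are dark: the "
            "lumen lacks scatterers)"
        )
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.where(mask.mask, lumen_mean, hydrogel_mean)
    intensity = rng.gamma(shape=n_averages, scale=means / n_averages)
    return OCTVolume(
        intensity=intensity,
        voxel_spacing=tuple(mask.voxel_spacing),
        meta={
            "hydrogel_mean": hydrogel_mean,
            "lumen_mean": lumen_mean,
            "speckle": "exponential",
            "n_averages": n_averages,
            "seed": seed,
        },
    )


def simulate_raw_scan(
    reflectors: ReflectorSet | list[ReflectorSet],
    spectro: SpectrometerSpec | None = None,
    seed: int | None = None,
    noise_std: float = 0.0,
) -> RawSpectralScan:
    """Forward-model raw interference spectra from point reflectors.

    Each A-line i (one ReflectorSet) is
    ``S_i(lambda) = E(lambda) * (1 + sum_j 2 sqrt(r_j) cos(2 k z_j))`` with
    ``k = 2 pi / lambda`` and the Gaussian source envelope E, plus optional
    additive white noise. The grid is uniform in wavelength, hence
    deliberately non-uniform in wavenumber.
    """
    spectro = spectro or SpectrometerSpec()
    sets = [reflectors] if isinstance(reflectors, ReflectorSet) else list(reflectors)
    k = spectro.wavenumber_um  # rad/um on the wavelength grid
    env = spectro.source_envelope()
    zmax = spectro.max_depth_um
    rows = []
    for rs in sets:
        fringes = np.zeros_like(k)
        for z_um, refl in rs.reflectors:
            if z_um >= zmax:
                raise ValueError(
                    f"reflector at {z_um} um beyond the unambiguous depth "
                    f"({zmax:.1f} um) of this spectral sampling"
                )
            fringes += 2.0 * np.sqrt(refl) * np.cos(2.0 * k * z_um)
        rows.append(env * (1.0 + fringes))
    spectra = np.stack(rows)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra + rng.normal(0.0, noise_std, spectra.shape)
    return RawSpectralScan(
        spectra=spectra,
        spectrometer=spectro,
        meta={"simulated": True, "noise_std": noise_std, "seed": seed},
    )
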