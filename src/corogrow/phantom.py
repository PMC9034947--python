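"""Synthetic CTA-like vascular phantoms with exact ground truth.

The generator emulates, at desk scale, the geometry a coronary-CTA
segmentation pipeline has to cope with: a bright, near-cylindrical ascending
aorta; a branching coronary tree of sub-voxel to few-voxel radius attached to
the aorta surface; soft-tissue background; optionally a high-attenuation stent
ring with luminal narrowing; and additive Gaussian noise.  All intensities
are in Hounsfield units inside the 0–600 HU working window (the stent ring is
the deliberate exception), so windowing and vesselness behave non-degenerately.

Coordinates are 0-based ``(z, y, x)`` voxel indices throughout the package.
Phantoms are deterministic: an identical config (including ``rng_seed``)
produces a bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

Coord = tuple[int, int, int]


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    aorta_radius: float = 8.0
    aorta_hu: float = 450.0
    vessel_radii: tuple[float, ...] = (2.5, 1.5, 1.5)
    vessel_hu: float = 400.0
    background_hu: float = 50.0
    stent_enabled: bool = False
    stent_hu: float = 800.0
    stenosis_fraction: float = 0.0
    noise_sigma: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ConfigurationError(f"shape must be a triple of ints >= 8, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")
        bound = min(self.shape) / 4.0
        radii = (self.aorta_radius, *self.vessel_radii)
        if any(r <= 0 or r >= bound for r in radii):
            raise ConfigurationError(
                f"all radii must be in (0, min(shape)/4={bound}), got {radii}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not (0.0 <= self.stenosis_fraction < 1.0):
            raise ConfigurationError("stenosis_fraction must be in [0, 1)")


@dataclass
class PhantomSample:
    """A generated volume and its exact ground truth."""

    volume: np.ndarray
    aorta_mask: np.ndarray
    vessel_mask: np.ndarray
    centerline: list[Coord]
    junction: Coord
    config: PhantomConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from each point to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def _grid(shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def _rasterize_tube(
    shape: tuple[int, int, int], polyline: list[np.ndarray], radius: float
) -> tuple[np.ndarray, list[Coord]]:
    """Voxelize a tube around a polyline; returns (mask, rounded centerline)."""
    pts = _grid(shape)
    mask = np.zeros(shape, dtype=bool)
    centerline: list[Coord] = []
    for a, b in zip(polyline[:-1], polyline[1:]):
        mask |= _segment_distance(pts, a, b) <= radius
        n = max(2, int(np.ceil(np.linalg.norm(b - a))) + 1)
        for t in np.linspace(0.0, 1.0, n):
            p = np.rint(a + t * (b - a)).astype(int)
            if all(0 <= p[i] < shape[i] for i in range(3)):
                c = (int(p[0]), int(p[1]), int(p[2]))
                if c not in centerline:
                    centerline.append(c)
    # thin tubes (radius < voxel diagonal/2) may miss their own rounded
    # centerline voxels after rasterization; force-include them
    for c in centerline:
        mask[c] = True
    return mask, centerline


def _coronary_polylines(config: PhantomConfig) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """Main branch leaving the aorta plus up to two children at fixed angles."""
    nz, ny, nx = config.shape
    ay, ax = ny / 2.0, nx / 4.0
    junction = np.array([nz / 2.0, ay, ax + config.aorta_radius])
    reach = min(nz, ny, nx) * 0.55
    main_dir = np.array([-0.25, 0.0, 1.0])
    main_dir /= np.linalg.norm(main_dir)
    mid = junction + main_dir * (reach * 0.5)
    end = junction + main_dir * reach
    branches = [[junction, mid, end]]
    # children leave the midpoint at +/-35 degrees in the y-x plane
    for sign, r in zip((1.0, -1.0), config.vessel_radii[1:3]):
        ang = np.deg2rad(35.0)
        child_dir = np.array(
            [main_dir[0], sign * np.sin(ang), main_dir[2] * np.cos(ang)]
        )
        child_dir /= np.linalg.norm(child_dir)
        branches.append([mid, mid + child_dir * (reach * 0.45)])
    return branches[: len(config.vessel_radii)], junction


def generate_phantom(config: PhantomConfig | None = None) -> PhantomSample:
    """Build a deterministic CTA phantom with aorta, coronary tree and noise.

    Noiseless voxels take exactly ``background_hu`` / ``vessel_hu`` /
    ``aorta_hu`` (plus ``stent_hu`` on the stent ring when enabled); Gaussian
    noise of sd ``noise_sigma`` is added afterwards.
    """
    if config is None:
        config = PhantomConfig()
    config.validate()
    nz, ny, nx = config.shape
    pts = _grid(config.shape)

    # ascending aorta: cylinder along z
    ay, ax = ny / 2.0, nx / 4.0
    aorta_mask = (pts[..., 1] - ay) ** 2 + (pts[..., 2] - ax) ** 2 <= config.aorta_radius**2

    branches, junction_f = _coronary_polylines(config)
    vessel_mask = np.zeros(config.shape, dtype=bool)
    centerline: list[Coord] = []
    for poly, radius in zip(branches, config.vessel_radii):
        m, cl = _rasterize_tube(config.shape, poly, radius)
        vessel_mask |= m
        for c in cl:
            if c not in centerline:
                centerline.append(c)

    junction = tuple(int(v) for v in np.rint(junction_f))

    volume = np.full(config.shape, config.background_hu, dtype=np.float64)

    stent_ring = np.zeros(config.shape, dtype=bool)
    if config.stent_enabled:
        # 1-voxel-thick ring around a short section of the main branch,
        # with the lumen narrowed by stenosis_fraction inside it
        a, mid, _ = branches[0][0], branches[0][1], branches[0][-1]
        s0 = a + 0.55 * (mid - a)
        s1 = a + 0.80 * (mid - a)
        r = config.vessel_radii[0]
        d = _segment_distance(pts, s0, s1)
        stent_ring = (d > r) & (d <= r + 1.0)
        narrowed = r * (1.0 - config.stenosis_fraction)
        plaque = (d > narrowed) & (d <= r)
        vessel_mask &= ~plaque
        centerline = [c for c in centerline if vessel_mask[c]]

    # overlap with the aorta allowed only within 1 voxel of the junction
    near_junction = np.linalg.norm(pts - junction_f, axis=-1) <= 1.5
    vessel_mask &= ~aorta_mask | near_junction
    centerline = [c for c in centerline if vessel_mask[c]]

    volume[vessel_mask] = config.vessel_hu
    volume[aorta_mask] = config.aorta_hu
    if config.stent_enabled:
        stent_ring &= ~(vessel_mask | aorta_mask)
        volume[stent_ring] = config.stent_hu

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.rng_seed)
        volume = volume + rng.normal(0.0, config.noise_sigma, size=config.shape)

    return PhantomSample(
        volume=volume,
        aorta_mask=aorta_mask,
        vessel_mask=vessel_mask,
        centerline=centerline,
        junction=junction,
        config=config,
    )


def generate_training_pairs(
    config: PhantomConfig, n_slices: int, rng_seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Axial slices with exact aorta cross-section labels for segmenter training.

    Each slice shows an aorta disk of randomized center and radius, a few
    vessel-HU distractor dots, soft-tissue background, and Gaussian noise of
    the configured sigma.  The label is the exact disk mask.
    """
    config.validate()
    if n_slices < 1:
        raise ConfigurationError(f"n_slices must be >= 1, got {n_slices}")
    rng = np.random.default_rng(rng_seed)
    ny, nx = config.shape[1], config.shape[2]
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_slices):
        r = rng.uniform(0.6, 1.1) * config.aorta_radius
        cy = rng.uniform(r + 2, ny - r - 2)
        cx = rng.uniform(r + 2, nx - r - 2)
        label = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2)
        img = np.full((ny, nx), config.background_hu, dtype=np.float64)
        # small distractor vessels outside the aorta
        for _ in range(rng.integers(0, 3)):
            vr = rng.uniform(1.0, 3.0)
            vy, vx = rng.uniform(2, ny - 2), rng.uniform(2, nx - 2)
            dot = ((yy - vy) ** 2 + (xx - vx) ** 2 <= vr**2) & ~label
            img[dot] = config.vessel_hu
        img[label] = config.aorta_hu
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        pairs.append((img, label.astype(np.uint8)))
    return pairs


def straight_tube_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    radius: float = 3.0,
    vessel_hu: float = 400.0,
    background_hu: float = 50.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    axis: int = 2,
) -> PhantomSample:
    """A single straight tube along a grid axis — the simplest growth target."""
    center = np.array(shape, dtype=float) / 2.0
    a, b = center.copy(), center.copy()
    a[axis], b[axis] = 2.0, shape[axis] - 3.0
    mask, centerline = _rasterize_tube(shape, [a, b], radius)
    volume = np.full(shape, background_hu, dtype=np.float64)
    volume[mask] = vessel_hu
    if noise_sigma > 0:
        volume = volume + np.random.default_rng(rng_seed).normal(0, noise_sigma, shape)
    return PhantomSample(
        volume=volume,
        aorta_mask=np.zeros(shape, dtype=bool),
        vessel_mask=mask,
        centerline=centerline,
        junction=tuple(int(v) for v in np.rint(a)),
        config=None,
    )


def leakage_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    radius: float = 2.5,
    vessel_hu: float = 400.0,
    background_hu: float = 50.0,
    noise_sigma: float = 5.0,
    rng_seed: int = 0,
) -> tuple[PhantomSample, np.ndarray]:
    """A tube touching an equal-intensity blob: the classic region-growing trap.

    Intensity-only growth leaks from the tube into the blob; vesselness-gated
    growth should not.  Returns the sample (vessel_mask = tube only) and the
    blob mask separately.
    """
    center = np.array(shape, dtype=float) / 2.0
    a, b = center.copy(), center.copy()
    a[2], b[2] = 2.0, shape[2] - 3.0
    tube, centerline = _rasterize_tube(shape, [a, b], radius)
    # blob tangent to the tube midway along it
    blob_r = min(shape) / 5.0
    bc = center.copy()
    bc[1] += radius + blob_r  # touching in y
    pts = _grid(shape)
    blob = np.linalg.norm(pts - bc, axis=-1) <= blob_r
    blob &= ~tube
    volume = np.full(shape, background_hu, dtype=np.float64)
    volume[tube | blob] = vessel_hu
    if noise_sigma > 0:
        volume = volume + np.random.default_rng(rng_seed).normal(0, noise_sigma, shape)
    sample = PhantomSample(
        volume=volume,
        aorta_mask=np.zeros(shape, dtype=bool),
        vessel_mask=tube,
        centerline=centerline,
        junction=tuple(int(v) for v in np.rint(a)),
        config=None,
    )
    return sample, blob
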