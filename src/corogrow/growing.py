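"""Seeded region growing, vesselness-gated (improved) and intensity-only (traditional).

Growth is a breadth-first expansion from a seed voxel.  A candidate voxel is
accepted iff

    vesselness >= tau_v   AND   |enhanced - mu_seed| <= tau_i

where ``mu_seed`` is the mean enhanced intensity over the seed and its
immediately accepted neighbors, frozen after initialization.  Because the
acceptance test depends only on frozen statistics, the result set is
independent of frontier processing order; rejected voxels are marked once and
never re-tested, so every voxel is evaluated at most once and growth always
terminates.  The traditional baseline is the identical algorithm with the
vesselness gate removed (tau_v = 0).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InputError, ParameterError

Coord = tuple[int, int, int]


class Termination(str, Enum):
    EXHAUSTED = "exhausted"
    MAX_VOXELS = "max_voxels"


@dataclass(frozen=True)
class GrowthParams:
    vesselness_threshold: float = 0.05
    intensity_tolerance: float = 60.0
    connectivity: int = 26
    max_voxels: int | None = None  # None = grid size

    def validate(self) -> None:
        if not (0.0 <= self.vesselness_threshold <= 1.0):
            raise ParameterError("vesselness_threshold must be in [0, 1]")
        if self.intensity_tolerance < 0:
            raise ParameterError("intensity_tolerance must be >= 0")
        if self.connectivity not in (6, 26):
            raise ParameterError("connectivity must be 6 or 26")
        if self.max_voxels is not None and self.max_voxels < 1:
            raise ParameterError("max_voxels must be >= 1")


@dataclass
class GrowthResult:
    mask: np.ndarray
    n_accepted: int
    n_rejected: int
    terminated_by: Termination
    seed_mean: float


def _offsets(connectivity: int) -> np.ndarray:
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    if connectivity == 6:
        offs = [o for o in offs if sum(abs(v) for v in o) == 1]
    return np.array(offs, dtype=np.intp)


def region_grow(
    enhanced: np.ndarray,
    vesselness: np.ndarray,
    seed: Coord,
    params: GrowthParams | None = None,
) -> GrowthResult:
    """Vesselness-gated seeded region growing.

    ``enhanced`` and ``vesselness`` must be aligned arrays of equal shape; the
    seed is a 0-based (z, y, x) voxel index inside the grid.
    """
    if params is None:
        params = GrowthParams()
    params.validate()
    enhanced = np.asarray(enhanced, dtype=np.float64)
    vesselness = np.asarray(vesselness, dtype=np.float64)
    if enhanced.shape != vesselness.shape:
        raise InputError(
            f"enhanced {enhanced.shape} and vesselness {vesselness.shape} are misaligned"
        )
    shape = enhanced.shape
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(not (0 <= seed[i] < shape[i]) for i in range(3)):
        raise InputError(f"seed {seed} outside grid {shape}")

    tau_v = params.vesselness_threshold
    tau_i = params.intensity_tolerance
    cap = params.max_voxels if params.max_voxels is not None else int(np.prod(shape))
    offs = _offsets(params.connectivity)

    # initialization: mu_seed is frozen from the seed and those immediate
    # neighbors that pass the vesselness gate and resemble the seed itself
    seed_val = enhanced[seed]
    init_vals = [seed_val]
    sarr = np.array(seed, dtype=np.intp)
    for off in offs:
        p = sarr + off
        if np.any(p < 0) or np.any(p >= shape):
            continue
        t = tuple(p)
        if vesselness[t] >= tau_v and abs(enhanced[t] - seed_val) <= tau_i:
            init_vals.append(enhanced[t])
    mu_seed = float(np.mean(init_vals))

    accepted = np.zeros(shape, dtype=bool)
    visited = np.zeros(shape, dtype=bool)
    n_rejected = 0

    def passes(t: Coord) -> bool:
        return vesselness[t] >= tau_v and abs(enhanced[t] - mu_seed) <= tau_i

    visited[seed] = True
    if not passes(seed):
        warnings.warn("seed voxel fails the growth condition; returning {seed only}")
        accepted[seed] = True
        return GrowthResult(accepted, 1, 0, Termination.EXHAUSTED, mu_seed)

    accepted[seed] = True
    n_accepted = 1
    frontier: deque[Coord] = deque([seed])
    terminated_by = Termination.EXHAUSTED
    while frontier:
        cur = np.array(frontier.popleft(), dtype=np.intp)
        for off in offs:
            p = cur + off
            if np.any(p < 0) or np.any(p >= shape):
                continue
            t = (int(p[0]), int(p[1]), int(p[2]))
            if visited[t]:
                continue
            visited[t] = True
            if passes(t):
                if n_accepted >= cap:  # a further voxel qualifies but the cap is hit
                    terminated_by = Termination.MAX_VOXELS
                    frontier.clear()
                    break
                accepted[t] = True
                n_accepted += 1
                frontier.append(t)
            else:
                n_rejected += 1

    return GrowthResult(accepted, n_accepted, n_rejected, terminated_by, mu_seed)


def region_grow_traditional(
    volume: np.ndarray,
    seed: Coord,
    intensity_threshold: float,
    connectivity: int = 26,
    max_voxels: int | None = None,
) -> GrowthResult:
    """Intensity-only baseline: same algorithm with the vesselness gate removed."""
    params = GrowthParams(
        vesselness_threshold=0.0,
        intensity_tolerance=intensity_threshold,
        connectivity=connectivity,
        max_voxels=max_voxels,
    )
    vol = np.asarray(volume, dtype=np.float64)
    return region_grow(vol, np.ones_like(vol), seed, params)
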