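"""Multiscale Hessian vesselness filtering.

Per-voxel tubularity is computed in Gaussian scale space.  At each scale
``alpha`` (the Gaussian sd, in voxels) the image is convolved with Gaussian
second-derivative kernels to obtain the symmetric 3x3 Hessian; its eigenvalues
``b1, b2, b3``, ordered by ascending magnitude ``|b1| <= |b2| <= |b3|``,
characterize the local shape.  Inside a bright tube ``b1 ~ 0`` (axial) while
``b2 ~ b3 << 0`` (radial).  The vesselness score combines three geometric
ratios:

    R_A = |b2| / |b3|                 (plate vs. line)
    R_B = |b1| / sqrt(|b2 * b3|)      (blob vs. line)
    S   = sqrt(b1^2 + b2^2 + b3^2)    (structure strength, Frobenius norm)

    U1 = exp(-R_A^2 / (2 eps^2))
    U2 = exp(-R_B^2 / (2 phi^2))
    U3 = exp(-S^2   / (2 str^2))

    V = (1 - U1) * U2 * (1 - U3)  when the brightness sign test passes,
    V = 0                         otherwise (b2 > 0 or b3 > 0 for bright tubes)

V lies in [0, 1]; it is maximal for bright tubes, zero for plates (R_A -> 0),
suppressed for blobs (R_B -> 1) and for low-contrast noise (small S).  Scales
are fused by voxelwise maximum; gamma-normalization (multiplying Hessian
components by alpha^2) makes responses comparable across scales so the
maximum picks the scale matching each vessel's radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class ScaleSpaceParams:
    """Gaussian scales (sd in voxels) and gamma-normalization switch."""

    scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    gamma_normalize: bool = True

    def validate(self) -> None:
        if len(self.scales) == 0:
            raise ParameterError("scales must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ParameterError(f"all scales must be > 0, got {self.scales}")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ParameterError(f"scales must be strictly increasing, got {self.scales}")


@dataclass(frozen=True)
class VesselnessParams:
    """Discriminant scales of the vesselness functional.

    ``eps`` and ``phi`` control the line filters on the plate and blob ratios
    (0.5 each by default); ``structure_scale`` controls sensitivity to overall
    contrast and is gray-level dependent — when None it is set per volume and
    scale to half the maximum Frobenius norm of the Hessian.
    """

    eps: float = 0.5
    phi: float = 0.5
    structure_scale: float | None = None
    bright_vessels: bool = True

    def validate(self) -> None:
        if self.eps <= 0 or self.phi <= 0:
            raise ParameterError("eps and phi must be > 0")
        if self.structure_scale is not None and self.structure_scale <= 0:
            raise ParameterError("structure_scale must be > 0 when given")


@dataclass
class HessianField:
    """The six unique second derivatives at one scale; symmetric by construction."""

    alpha: float
    ixx: np.ndarray
    ixy: np.ndarray
    ixz: np.ndarray
    iyy: np.ndarray
    iyz: np.ndarray
    izz: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Stack into an (..., 3, 3) array of symmetric matrices (z, y, x axes)."""
        h = np.empty(self.ixx.shape + (3, 3), dtype=np.float64)
        h[..., 0, 0] = self.izz
        h[..., 1, 1] = self.iyy
        h[..., 2, 2] = self.ixx
        h[..., 0, 1] = h[..., 1, 0] = self.iyz
        h[..., 0, 2] = h[..., 2, 0] = self.ixz
        h[..., 1, 2] = h[..., 2, 1] = self.ixy
        return h


@dataclass
class EigenField:
    """Per-voxel eigenvalues sorted by |.| ascending, with eigenvectors."""

    eigenvalues: np.ndarray  # (..., 3)
    eigenvectors: np.ndarray  # (..., 3, 3), column q is the vector of eigenvalue q


def gaussian_kernel_value(x: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """The 3D isotropic Gaussian kernel value at radial offset ``x``."""
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    x = np.asarray(x, dtype=np.float64)
    out = (2.0 * np.pi * alpha**2) ** (-1.5) * np.exp(-(x**2) / (2.0 * alpha**2))
    return float(out) if out.ndim == 0 else out


def gaussian_smooth(volume: np.ndarray, alpha: float) -> np.ndarray:
    """Convolve with the 3D Gaussian of sd ``alpha`` (reflect boundaries)."""
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    v = np.asarray(volume, dtype=np.float64)
    return ndimage.gaussian_filter(v, sigma=alpha, mode="reflect")


# (name, derivative orders along (z, y, x))
_COMPONENTS = (
    ("ixx", (0, 0, 2)),
    ("ixy", (0, 1, 1)),
    ("ixz", (1, 0, 1)),
    ("iyy", (0, 2, 0)),
    ("iyz", (1, 1, 0)),
    ("izz", (2, 0, 0)),
)


def hessian_field(
    volume: np.ndarray, alpha: float, params: ScaleSpaceParams | None = None
) -> HessianField:
    """Gaussian-derivative Hessian at scale ``alpha``.

    Smoothing and differentiation are fused into Gaussian-derivative kernels.
    With gamma-normalization each component is multiplied by ``alpha**2`` so
    magnitudes are comparable across scales.
    """
    if params is None:
        params = ScaleSpaceParams()
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise InputError(f"expected a 3D volume, got ndim={v.ndim}")
    if any(s < 4 for s in v.shape):
        raise InputError(f"volume {v.shape} smaller than the derivative stencil")
    gamma = alpha**2 if params.gamma_normalize else 1.0
    comps = {
        name: gamma * ndimage.gaussian_filter(v, sigma=alpha, order=order, mode="reflect")
        for name, order in _COMPONENTS
    }
    return HessianField(alpha=alpha, **comps)


def eigen_decompose(h: HessianField) -> EigenField:
    """Eigen-decompose the symmetric Hessian at every voxel.

    Eigenvalues are sorted by ascending absolute value, so index 0 is the
    near-zero axial eigenvalue inside a tube and index 2 the strongest radial
    one.  Eigenvectors are unit-norm and mutually orthogonal.
    """
    mats = h.as_matrices()
    if not np.all(np.isfinite(mats)):
        raise InputError("Hessian field contains non-finite entries")
    w, v = np.linalg.eigh(mats)  # ascending by value
    order = np.argsort(np.abs(w), axis=-1, kind="stable")
    w = np.take_along_axis(w, order, axis=-1)
    v = np.take_along_axis(v, order[..., None, :], axis=-1)
    return EigenField(eigenvalues=w, eigenvectors=v)


def vesselness_single_scale(
    e: EigenField, params: VesselnessParams | None = None
) -> np.ndarray:
    """Vesselness score in [0, 1] from |.|-ordered eigenvalues."""
    if params is None:
        params = VesselnessParams()
    params.validate()
    b1 = e.eigenvalues[..., 0]
    b2 = e.eigenvalues[..., 1]
    b3 = e.eigenvalues[..., 2]

    ab1, ab2, ab3 = np.abs(b1), np.abs(b2), np.abs(b3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(ab3 > 0, ab2 / np.where(ab3 > 0, ab3, 1.0), 0.0)
        rb = np.where(ab2 * ab3 > 0, ab1 / np.sqrt(np.where(ab2 * ab3 > 0, ab2 * ab3, 1.0)), 0.0)
    s = np.sqrt(b1**2 + b2**2 + b3**2)

    phi_s = params.structure_scale
    if phi_s is None:
        smax = float(s.max()) if s.size else 0.0
        phi_s = smax / 2.0 if smax > 0 else 1.0

    u1 = np.exp(-(ra**2) / (2.0 * params.eps**2))
    u2 = np.exp(-(rb**2) / (2.0 * params.phi**2))
    u3 = np.exp(-(s**2) / (2.0 * phi_s**2))
    v = (1.0 - u1) * u2 * (1.0 - u3)

    if params.bright_vessels:
        v = np.where((b2 > 0) | (b3 > 0), 0.0, v)
    else:
        v = np.where((b2 < 0) | (b3 < 0), 0.0, v)
    v = np.where(ab3 == 0, 0.0, v)
    return np.clip(v, 0.0, 1.0)


def vesselness_at_scale(
    volume: np.ndarray,
    alpha: float,
    sp: ScaleSpaceParams | None = None,
    vp: VesselnessParams | None = None,
) -> np.ndarray:
    """Single-scale vesselness of a volume (Hessian + eigen + functional)."""
    return vesselness_single_scale(eigen_decompose(hessian_field(volume, alpha, sp)), vp)


def vesselness_multiscale(
    volume: np.ndarray,
    sp: ScaleSpaceParams | None = None,
    vp: VesselnessParams | None = None,
) -> np.ndarray:
    """Fused vesselness: voxelwise maximum of the single-scale responses."""
    if sp is None:
        sp = ScaleSpaceParams()
    sp.validate()
    fused: np.ndarray | None = None
    for alpha in sp.scales:
        v = vesselness_at_scale(volume, alpha, sp, vp)
        fused = v if fused is None else np.maximum(fused, v)
    assert fused is not None
    return fused
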