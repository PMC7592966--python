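"""Data preparation for the two-stage cascade.

Liver stage: HU windowing to the -50..250 diagnostic range followed by 2D
median filtering per axial slice.  Tumor stage: the liver region of
interest is cropped out of the windowed volume and smoothed with 3D
edge-enhancing anisotropic diffusion (EED), which homogenises parenchyma
and lesion interiors while preserving the contrast across their shared
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_ct import BinaryMask, CTVolume

__all__ = [
    "WindowSpec",
    "EEDParams",
    "CropRecord",
    "hu_window",
    "median_filter",
    "eed_filter",
    "crop_liver_roi",
    "uncrop_mask",
    "NoLiverFoundError",
]


class NoLiverFoundError(RuntimeError):
    """Raised when the cascade has no liver voxels to hand to the tumor stage."""


@dataclass
class WindowSpec:
    """Clip-and-rescale window in Hounsfield units.

    The default -50..250 window spans the liver/tumor intensity range
    while excluding air, lung and most bone.
    """

    lo: float = -50.0
    hi: float = 250.0
    rescale: bool = True

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window lo must be < hi, got [{self.lo}, {self.hi}]")


@dataclass
class EEDParams:
    """Edge-enhancing diffusion parameters.

    sigma : Gaussian scale (px) for the gradient used to steer the tensor.
    rho : scale (px) over which gradient components are averaged before
        the edge orientation is taken; regularises the steering direction.
    lambda_c : contrast parameter in windowed-intensity units; gradients
        well above it are treated as edges and diffusion across them is
        suppressed.
    tau : explicit time step; must respect the stability bound
        ``tau <= 1 / (2 * sum(1/h_i^2))`` for voxel sizes ``h_i``.
    m, cm : exponent and normalising constant of the Weickert diffusivity
        ``g(s) = 1 - exp(-cm / (s/lambda_c^2)^m)`` (g(0) = 1, cm chosen so
        the flux is maximal at s = lambda_c^2).
    """

    sigma: float = 1.0
    rho: float = 2.0
    lambda_c: float = 0.05
    tau: float = 0.1
    n_steps: int = 10
    m: float = 4.0
    cm: float = 3.31488

    def __post_init__(self) -> None:
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class CropRecord:
    """Axis-aligned crop box; enough to place a cropped grid back."""

    source_shape: tuple[int, int, int]
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))


def hu_window(img, w: WindowSpec | None = None):
    """Clip to [w.lo, w.hi] and (by default) rescale onto [0, 1].

    Accepts a bare 2D/3D array or a :class:`CTVolume`; returns the same
    kind.  Monotone non-decreasing in the input.
    """
    w = w or WindowSpec()
    if isinstance(img, CTVolume):
        out = hu_window(img.voxels, w)
        return CTVolume(out, spacing=img.spacing, affine=img.affine,
                        axial_axis=img.axial_axis)
    arr = np.asarray(img, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite intensities")
    out = np.clip(arr, w.lo, w.hi)
    if w.rescale:
        out = (out - w.lo) / (w.hi - w.lo)
    return out


def median_filter(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """2D median filter with reflect edge handling."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    return ndimage.median_filter(np.asarray(img), size=kernel, mode="reflect")


def _diffusivity(s: np.ndarray, p: EEDParams) -> np.ndarray:
    """Weickert diffusivity on squared gradient magnitude s; g(0) = 1."""
    g = np.ones_like(s)
    pos = s > 0
    ratio = s[pos] / (p.lambda_c**2)
    with np.errstate(divide="ignore", over="ignore"):
        # ratio**m underflows for near-zero gradients; the limit g -> 1 is
        # exactly what exp(-inf) = 0 delivers
        g[pos] = 1.0 - np.exp(-p.cm / ratio**p.m)
    return g


def eed_stability_limit(spacing: tuple[float, float, float]) -> float:
    """Largest explicit time step for a diffusion tensor with eigenvalues <= 1."""
    return 1.0 / (2.0 * sum(1.0 / h**2 for h in spacing))


def _gradient(u: np.ndarray, spacing) -> list[np.ndarray]:
    return list(np.gradient(u, *spacing, edge_order=1))


def eed_filter(vol: CTVolume | np.ndarray, p: EEDParams | None = None,
               spacing: tuple[float, float, float] | None = None):
    """3D edge-enhancing anisotropic diffusion.

    The diffusion tensor has eigenvalue ``g(|grad u_sigma|^2)`` along the
    (rho-averaged) gradient direction and 1 on the orthogonal complement,
    so smoothing proceeds freely along edges and within homogeneous
    regions but is inhibited across edges.  The update is an explicit
    flux-form step with zero-flux boundaries (mean-preserving); a monotone
    limiter clamps every update to the 3x3x3 neighbourhood range of the
    previous iterate so no new extrema are created.
    """
    p = p or EEDParams()
    if isinstance(vol, CTVolume):
        out = eed_filter(vol.voxels, p, spacing=vol.spacing)
        return CTVolume(out, spacing=vol.spacing, affine=vol.affine,
                        axial_axis=vol.axial_axis)
    u = np.asarray(vol, dtype=np.float64)
    if u.ndim != 3 or min(u.shape) < 8:
        raise ValueError("eed_filter expects a 3D volume with >= 8 voxels per axis")
    h = tuple(float(s) for s in (spacing or (1.0, 1.0, 1.0)))
    limit = eed_stability_limit(h)
    if p.tau > limit:
        raise ValueError(
            f"tau={p.tau} exceeds the explicit stability limit {limit:.4g} "
            f"for spacing {h}"
        )

    for _ in range(p.n_steps):
        # steering direction from the sigma-smoothed gradient, components
        # averaged at scale rho
        us = ndimage.gaussian_filter(u, p.sigma, mode="nearest")
        grad = _gradient(us, h)
        if p.rho > 0:
            grad = [ndimage.gaussian_filter(g, p.rho, mode="nearest") for g in grad]
        s = grad[0] ** 2 + grad[1] ** 2 + grad[2] ** 2
        g = _diffusivity(s, p)
        norm = np.sqrt(np.maximum(s, 1e-30))
        w = [gi / norm for gi in grad]  # unit edge direction (arbitrary where s ~ 0)
        # D = I + (g - 1) w w^T  (eigenvalue g across the edge, 1 along it)
        a = g - 1.0
        D = [[None] * 3 for _ in range(3)]
        for i in range(3):
            for j in range(i, 3):
                Dij = a * w[i] * w[j]
                if i == j:
                    Dij = Dij + 1.0
                D[i][j] = Dij
                D[j][i] = Dij

        du = _gradient(u, h)
        flux = [sum(D[i][j] * du[j] for j in range(3)) for i in range(3)]
        # conservative divergence: difference of face fluxes, zero at the boundary
        div = np.zeros_like(u)
        for ax in range(3):
            f = flux[ax]
            face = 0.5 * (np.take(f, range(0, f.shape[ax] - 1), axis=ax)
                          + np.take(f, range(1, f.shape[ax]), axis=ax))
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            face = np.pad(face, pad)  # zero-flux at both ends
            div += np.diff(face, axis=ax) / h[ax]
        u_new = u + p.tau * div
        # monotone limiter: no voxel may leave its local 3x3x3 range
        lo = ndimage.minimum_filter(u, size=3, mode="nearest")
        hi = ndimage.maximum_filter(u, size=3, mode="nearest")
        u = np.clip(u_new, lo, hi)
    return u.astype(np.float32)


def crop_liver_roi(
    vol: CTVolume, liver: BinaryMask, margin: int = 5
) -> tuple[CTVolume, CropRecord]:
    """Crop the liver bounding box (dilated by ``margin``) and zero the
    background so the tumor network sees the liver envelope only."""
    mask = liver.voxels.astype(bool)
    if not mask.any():
        raise NoLiverFoundError("no liver found: empty liver mask")
    if mask.shape != vol.shape:
        raise ValueError(f"liver mask shape {mask.shape} != volume shape {vol.shape}")
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, vol.shape)
    rec = CropRecord(source_shape=tuple(vol.shape), lo=tuple(int(v) for v in lo),
                     hi=tuple(int(v) for v in hi))
    sl = rec.slices
    out = np.where(mask[sl], vol.voxels[sl], 0.0).astype(np.float32)
    return (
        CTVolume(out, spacing=vol.spacing, affine=vol.affine, axial_axis=vol.axial_axis),
        rec,
    )


def uncrop_mask(mask: np.ndarray, rec: CropRecord) -> np.ndarray:
    """Place a cropped-grid mask back onto the source grid (zeros outside)."""
    out = np.zeros(rec.source_shape, dtype=np.uint8)
    out[rec.slices] = mask
    return out
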