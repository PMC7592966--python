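"""Synthetic abdominal CT phantoms with ground-truth liver and tumor masks.

The generator emulates the intensity regime a portal-venous-phase liver CT
presents to the segmentation cascade: a large bright quasi-ellipsoidal
liver (HU ~ 120) with a perturbed smooth boundary, darker blob lesions
inside it (HU ~ 45), a soft-tissue body (HU ~ 40) surrounded by air
(HU -1000) with bright bone arcs (HU ~ 500), and additive Gaussian noise.
All HU choices are synthetic conventions chosen inside the -50..250
working window, with tumors darker than parenchyma; they are not
measurements of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_ct import BinaryMask, CTVolume, write_mask, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_corpus"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic CT case.

    Geometry is in voxels on the (x, y, z) grid; intensities in HU.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    # liver ellipsoid
    liver_center_frac: tuple[float, float, float] = (0.42, 0.45, 0.5)
    liver_semiaxes_frac: tuple[float, float, float] = (0.26, 0.22, 0.36)
    boundary_perturb: float = 0.15  # relative amplitude of the smooth radial perturbation
    liver_hu_mean: float = 120.0
    liver_hu_sd: float = 15.0
    # tumors
    tumor_count: int = 2
    tumor_radius_range: tuple[float, float] = (4.0, 14.0)
    tumor_hu_mean: float = 45.0
    tumor_hu_sd: float = 10.0
    tumor_margin: float = 2.0  # min distance (px) from tumor surface to liver surface
    # surroundings
    body_hu: float = 40.0
    air_hu: float = -1000.0
    bone_hu: float = 500.0
    noise_sd: float = 10.0
    seed: int = 0


def _smooth_noise(shape, rng, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f /= max(f.std(), 1e-12)
    return f


def _ellipsoid_field(shape, center, semiaxes):
    grids = np.ogrid[[slice(0, n) for n in shape]]
    q = np.zeros(shape, dtype=np.float32)
    for g, c, a in zip(grids, center, semiaxes):
        q = q + ((g - c) / a) ** 2
    return q  # <= 1 inside


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, BinaryMask, BinaryMask]:
    """Render one phantom; deterministic given ``spec.seed``.

    Returns (volume, liver mask, tumor mask) with tumor ⊆ liver and every
    tumor at least ``spec.tumor_margin`` voxels inside the liver surface.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nx, ny, nz = shape

    # body: elliptic cylinder of soft tissue in air
    body_q = _ellipsoid_field(
        (nx, ny, 1), (nx * 0.5, ny * 0.5, 0.0), (nx * 0.45, ny * 0.42, 1.0)
    )
    body = np.broadcast_to(body_q <= 1.0, shape)

    # liver: perturbed ellipsoid, strictly inside the body
    center = tuple(f * n for f, n in zip(spec.liver_center_frac, shape))
    semi = tuple(f * n for f, n in zip(spec.liver_semiaxes_frac, shape))
    q = _ellipsoid_field(shape, center, semi)
    perturb = _smooth_noise(shape, rng, sigma=(8, 8, 4)) * spec.boundary_perturb
    liver = ((q + perturb) <= 1.0) & body
    liver = ndimage.binary_opening(liver, iterations=1)
    # keep the largest component in case the perturbation pinches one off
    lab, n = ndimage.label(liver)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        liver = lab == (1 + int(np.argmax(sizes)))
    if liver.sum() < 100:
        raise ValueError("infeasible phantom spec: liver region degenerate")

    # tumors: spheres planted where the liver is deep enough
    depth = ndimage.distance_transform_edt(liver)
    tumor = np.zeros(shape, dtype=bool)
    radii: list[float] = []
    for _ in range(spec.tumor_count):
        r = rng.uniform(*spec.tumor_radius_range)
        feasible = np.argwhere(depth >= r + spec.tumor_margin)
        if feasible.size == 0:
            # shrink until it fits; below the minimum radius the spec is infeasible
            r_max = float(depth.max()) - spec.tumor_margin
            if r_max < spec.tumor_radius_range[0]:
                raise ValueError(
                    "infeasible phantom spec: tumor radius exceeds liver depth"
                )
            r = rng.uniform(spec.tumor_radius_range[0], r_max)
            feasible = np.argwhere(depth >= r + spec.tumor_margin)
        c = feasible[rng.integers(len(feasible))]
        ball = _ellipsoid_field(shape, tuple(c), (r, r, r)) <= 1.0
        tumor |= ball
        radii.append(r)

    # paint intensities
    vox = np.full(shape, spec.air_hu, dtype=np.float32)
    vox[body] = spec.body_hu
    # bone arcs: two lateral rib-like arcs at the body boundary
    body2d = body_q[..., 0] <= 1.0
    shell = body2d & ~ndimage.binary_erosion(body2d, iterations=3)
    xs = np.arange(nx)[:, None]
    arcs = shell & ((xs < nx * 0.25) | (xs > nx * 0.75))
    vox[np.broadcast_to(arcs[..., None], shape)] = spec.bone_hu
    # liver texture: mean + low-frequency variation at the stated sd
    tex_l = _smooth_noise(shape, rng, sigma=(4, 4, 2)) * spec.liver_hu_sd
    vox[liver] = spec.liver_hu_mean + tex_l[liver]
    tex_t = _smooth_noise(shape, rng, sigma=(3, 3, 2)) * spec.tumor_hu_sd
    vox[tumor] = spec.tumor_hu_mean + tex_t[tumor]
    vox += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    affine = np.diag((*spec.spacing, 1.0))
    volume = CTVolume(vox.astype(np.float32), spacing=spec.spacing, affine=affine)
    liver_mask = BinaryMask(liver.astype(np.uint8), spacing=spec.spacing, affine=affine)
    tumor_mask = BinaryMask(tumor.astype(np.uint8), spacing=spec.spacing, affine=affine)
    return volume, liver_mask, tumor_mask


@dataclass
class CorpusRanges:
    """Per-case sampling ranges for :func:`generate_corpus`."""

    tumor_count: tuple[int, int] = (0, 4)
    tumor_radius: tuple[float, float] = (4.0, 14.0)
    liver_scale: tuple[float, float] = (0.85, 1.1)  # multiplies the semi-axes
    noise_sd: tuple[float, float] = (8.0, 12.0)


def generate_corpus(
    n: int,
    seed: int,
    base: PhantomSpec | None = None,
    ranges: CorpusRanges | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[CTVolume, BinaryMask, BinaryMask]], pd.DataFrame]:
    """Generate ``n`` phantoms with per-case parameters drawn from ranges.

    The manifest records every drawn parameter plus the per-case seed, so a
    corpus can be regenerated case by case.  When ``out_dir`` is given each
    case is written as ``case_XXXX/{volume,liver,tumor}.nii.gz`` alongside
    ``manifest.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or PhantomSpec()
    ranges = ranges or CorpusRanges()
    master = np.random.default_rng(seed)
    cases = []
    rows = []
    for i in range(n):
        case_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(case_seed)
        scale = rng.uniform(*ranges.liver_scale)
        spec = PhantomSpec(
            shape=base.shape,
            spacing=base.spacing,
            liver_semiaxes_frac=tuple(f * scale for f in base.liver_semiaxes_frac),
            boundary_perturb=base.boundary_perturb,
            liver_hu_mean=base.liver_hu_mean,
            liver_hu_sd=base.liver_hu_sd,
            tumor_count=int(rng.integers(ranges.tumor_count[0], ranges.tumor_count[1] + 1)),
            tumor_radius_range=ranges.tumor_radius,
            tumor_hu_mean=base.tumor_hu_mean,
            tumor_hu_sd=base.tumor_hu_sd,
            noise_sd=float(rng.uniform(*ranges.noise_sd)),
            seed=case_seed,
        )
        triple = generate_phantom(spec)
        cases.append(triple)
        row = {"case_id": f"case_{i:04d}", "seed": case_seed}
        row.update(
            {
                k: v
                for k, v in asdict(spec).items()
                if k not in ("shape", "spacing")
            }
        )
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, (vol, liver, tumor) in zip(rows, cases):
            d = out_dir / row["case_id"]
            d.mkdir(exist_ok=True)
            write_volume(vol, d / "volume.nii.gz")
            write_mask(liver, vol, d / "liver.nii.gz")
            write_mask(tumor, vol, d / "tumor.nii.gz")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return cases, manifest
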