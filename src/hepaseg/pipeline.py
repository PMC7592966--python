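"""Two-stage cascade: liver first, then tumors inside the liver envelope.

Stage 1 windows and median-filters the volume, runs the liver U-Net on
each resized axial slice, keeps the largest 3D connected component of the
thresholded prediction, and refines each slice with the localized level
set (interior statistics gated to the bright side of an Otsu cut).
Stage 2 crops the liver region of interest, enhances it with 3D EED,
runs the tumor U-Net, refines with the level set gated to the dark side
of the Otsu cut, and maps everything back to the original grid with the
tumor mask confined to the liver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .io_ct import (
    BinaryMask,
    CTVolume,
    extract_slices,
    resize_image,
    stack_slices,
)
from .levelset import LevelSetParams, NothingToRefineError, evolve, otsu_threshold
from .preprocess import (
    EEDParams,
    NoLiverFoundError,
    WindowSpec,
    crop_liver_roi,
    eed_filter,
    hu_window,
    median_filter,
    uncrop_mask,
)
from .unet import UNet, UNetConfig, binarize, load_model, predict_volume

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "segment_liver",
    "segment_tumors",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    median_kernel: int = 3
    eed: EEDParams = field(default_factory=EEDParams)
    unet_liver: UNetConfig = field(default_factory=UNetConfig)
    unet_tumor: UNetConfig = field(default_factory=UNetConfig)
    liver_checkpoint: str | None = None
    tumor_checkpoint: str | None = None
    levelset_liver: LevelSetParams = field(default_factory=lambda: LevelSetParams(max_iters=200))
    levelset_tumor: LevelSetParams = field(default_factory=lambda: LevelSetParams(max_iters=100))
    threshold: float = 0.5
    roi_margin: int = 5
    use_levelset_liver: bool = True
    use_levelset_tumor: bool = True
    use_otsu_gate: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        kw = dict(raw)
        for key, sub in (
            ("window", WindowSpec),
            ("eed", EEDParams),
            ("unet_liver", UNetConfig),
            ("unet_tumor", UNetConfig),
            ("levelset_liver", LevelSetParams),
            ("levelset_tumor", LevelSetParams),
        ):
            if key in kw and isinstance(kw[key], dict):
                if "input_size" in kw[key]:
                    kw[key]["input_size"] = tuple(kw[key]["input_size"])
                kw[key] = sub(**kw[key])
        return cls(**kw)

    def to_provenance(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationResult:
    liver: BinaryMask
    tumor: BinaryMask
    liver_unet: BinaryMask
    tumor_unet: BinaryMask
    provenance: dict


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return (lab == 1 + int(np.argmax(sizes))).astype(np.uint8)


def _fill_holes_per_slice(stack: np.ndarray) -> np.ndarray:
    """Close interior holes slice-wise: the liver envelope includes the
    (darker) lesions inside it, which intensity-driven steps carve out."""
    out = np.empty_like(stack)
    for k in range(len(stack)):
        out[k] = ndimage.binary_fill_holes(stack[k])
    return out


def _gate_from_otsu(img: np.ndarray, mask: np.ndarray, radius: int,
                    side: str) -> tuple[float, float] | None:
    """Otsu cut over the mask's neighbourhood; gate the requested side."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        return None
    lo = np.maximum(idx.min(axis=0) - 2 * radius, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + 2 * radius, mask.shape)
    region = img[lo[0]:hi[0], lo[1]:hi[1]]
    try:
        t = otsu_threshold(region)
    except ValueError:  # constant region
        return None
    return (t, float(region.max())) if side == "bright" else (float(region.min()), t)


def _refine_stack(imgs: np.ndarray, masks: np.ndarray, p: LevelSetParams,
                  gate_side: str | None) -> np.ndarray:
    out = np.zeros_like(masks)
    for k in range(len(masks)):
        if masks[k].sum() == 0:
            continue
        gate = (
            _gate_from_otsu(imgs[k], masks[k], p.radius, gate_side)
            if gate_side
            else None
        )
        try:
            out[k] = evolve(imgs[k], masks[k], p, gate=gate)
        except NothingToRefineError:
            out[k] = masks[k]
    return out


def segment_liver(vol: CTVolume, model: UNet, cfg: PipelineConfig
                  ) -> tuple[BinaryMask, BinaryMask]:
    """Whole-abdomen liver segmentation; returns (U-Net mask, refined mask)
    on the original grid."""
    input_size = tuple(model.cfg.input_size)
    win = hu_window(vol, cfg.window)
    slices = extract_slices(win)
    pre = np.stack(
        [resize_image(median_filter(s.pixels, cfg.median_kernel), input_size, 1)
         for s in slices]
    )
    net_vol = np.moveaxis(pre, 0, 2)
    maps = predict_volume(model, CTVolume(net_vol, vol.spacing, vol.affine))
    raw = binarize(maps, cfg.threshold)
    if raw.sum() == 0:
        raise NoLiverFoundError("no liver found: network predicted nothing")
    unet_stack = _fill_holes_per_slice(
        np.moveaxis(_largest_component(np.moveaxis(raw, 0, 2)), 2, 0)
    )
    if cfg.use_levelset_liver:
        refined_stack = _fill_holes_per_slice(
            _refine_stack(
                pre, unet_stack, cfg.levelset_liver,
                "bright" if cfg.use_otsu_gate else None,
            )
        )
    else:
        refined_stack = unet_stack

    def back(stack):
        native = [
            resize_image(m, vol.shape[:2], order=0) for m in stack
        ]
        return BinaryMask(stack_slices(native, vol.axial_axis),
                          spacing=vol.spacing, affine=vol.affine)

    return back(unet_stack), back(refined_stack)


def segment_tumors(vol: CTVolume, liver: BinaryMask, model: UNet,
                   cfg: PipelineConfig) -> tuple[BinaryMask, BinaryMask]:
    """Tumor segmentation inside the liver envelope; returns (U-Net mask,
    refined mask) on the original grid, both confined to the liver."""
    input_size = tuple(model.cfg.input_size)
    win = hu_window(vol, cfg.window)
    roi, rec = crop_liver_roi(win, liver, margin=cfg.roi_margin)
    enhanced = eed_filter(roi, cfg.eed)
    roi_shape = enhanced.shape
    pre = np.stack(
        [resize_image(s.pixels, input_size, 1) for s in extract_slices(enhanced)]
    )
    maps = predict_volume(model, CTVolume(np.moveaxis(pre, 0, 2),
                                          vol.spacing, vol.affine))
    unet_stack = binarize(maps, cfg.threshold)
    if cfg.use_levelset_tumor:
        refined_stack = _refine_stack(
            pre, unet_stack, cfg.levelset_tumor,
            "dark" if cfg.use_otsu_gate else None,
        )
    else:
        refined_stack = unet_stack

    def back(stack):
        roi_slices = [resize_image(m, roi_shape[:2], order=0) for m in stack]
        full = uncrop_mask(stack_slices(roi_slices, axial_axis=2), rec)
        full &= liver.voxels  # tumors live inside the liver envelope
        return BinaryMask(full, spacing=vol.spacing, affine=vol.affine)

    return back(unet_stack), back(refined_stack)


def run_pipeline(vol: CTVolume, cfg: PipelineConfig,
                 liver_model: UNet | None = None,
                 tumor_model: UNet | None = None) -> SegmentationResult:
    """Full cascade; deterministic given checkpoints and config."""
    if liver_model is None:
        if not cfg.liver_checkpoint or not Path(cfg.liver_checkpoint).exists():
            raise FileNotFoundError(f"liver checkpoint not found: {cfg.liver_checkpoint}")
        liver_model = load_model(cfg.liver_checkpoint)
    if tumor_model is None:
        if not cfg.tumor_checkpoint or not Path(cfg.tumor_checkpoint).exists():
            raise FileNotFoundError(f"tumor checkpoint not found: {cfg.tumor_checkpoint}")
        tumor_model = load_model(cfg.tumor_checkpoint)
    try:
        liver_unet, liver_refined = segment_liver(vol, liver_model, cfg)
    except (NoLiverFoundError, NothingToRefineError) as e:
        raise NoLiverFoundError(f"liver stage: {e}") from e
    tumor_unet, tumor_refined = segment_tumors(vol, liver_refined, tumor_model, cfg)
    return SegmentationResult(
        liver=liver_refined,
        tumor=tumor_refined,
        liver_unet=liver_unet,
        tumor_unet=tumor_unet,
        provenance={"config": cfg.to_provenance(), "volume_shape": vol.shape},
    )
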