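"""2D U-Net FCNs for the liver/tumor cascade.

Architecture: a contracting path of ``depth`` levels with
``conv_per_block`` 3x3 conv+ReLU layers per level (channels doubling,
2x2 max-pooling between levels), a two-conv bottleneck, and an expanding
path that upsamples with 2x2 stride-2 transposed convolutions,
concatenates the matching skip connection and fuses it with one 3x3
conv+ReLU.  A dropout layer (0.5) sits before the final 1x1 convolution,
whose sigmoid emits a per-pixel probability of liver (or tumor) versus
background.  At the defaults (depth 4, base 32, 2 convs per contracting
block) the network comprises exactly 19 convolutional layers — 8
contracting + 2 bottleneck + 4 transposed + 4 fusion + 1 output.

Training minimises the soft Dice loss with Adam (lr 0.001), reducing the
learning rate by a factor of 0.1 when the monitored loss fails to
improve for 5 epochs.  Slices whose target mask is empty are excluded
from training, and for the tumor stage whole volumes without any tumor
annotation are excluded, so every batch contains foreground.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io_ct import BinaryMask, CTVolume, extract_slices, resize_image
from .nn.layers import dropout_backward, dropout_forward
from .preprocess import (
    EEDParams,
    WindowSpec,
    crop_liver_roi,
    eed_filter,
    hu_window,
    median_filter,
)

__all__ = [
    "UNetConfig",
    "TrainingConfig",
    "SliceDataset",
    "UNet",
    "build_unet",
    "soft_dice_loss",
    "select_training_slices",
    "train",
    "predict_volume",
    "binarize",
    "save_model",
    "load_model",
    "EmptyDatasetError",
]


class EmptyDatasetError(RuntimeError):
    """No qualifying training slices."""


@dataclass
class UNetConfig:
    input_size: tuple[int, int] = (256, 256)
    depth: int = 4
    base_filters: int = 32
    conv_per_block: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )

    @property
    def conv_layer_count(self) -> int:
        """Convolutional layers counting transposed and 1x1 output convs."""
        enc = self.depth * self.conv_per_block
        bottleneck = self.conv_per_block
        dec = self.depth * 2  # transposed + fusion conv per level
        return enc + bottleneck + dec + 1


@dataclass
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 32
    lr0: float = 1e-3
    lr_factor: float = 0.1
    lr_patience_epochs: int = 5
    seed: int = 0
    validation_fraction: float = 0.1
    eps: float = 1.0  # soft-dice smoothing
    min_delta: float = 1e-4  # improvement below this counts as a plateau
    min_lr: float = 1e-5  # plateau reductions never go below this


@dataclass
class SliceDataset:
    """Paired inputs/targets for one cascade stage, NHWC float32."""

    x: np.ndarray  # (N,H,W,1) in [0,1]
    y: np.ndarray  # (N,H,W,1) in {0,1}
    stage: str = "liver"

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("input/target shape mismatch")
        if len(self.x) and not (self.y.reshape(len(self.y), -1).sum(axis=1) > 0).all():
            raise ValueError("every training slice must contain foreground")

    def __len__(self) -> int:
        return len(self.x)


class UNet:
    """NumPy U-Net; parameters live in ``self.params`` (name -> array).

    Activations are NHWC (batch, height, width, channels)."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        ch = lambda l: cfg.base_filters * (2**l)

        def add_conv(name, cin, cout, k=3):
            std = np.sqrt(2.0 / (cin * k * k))
            self.params[f"{name}_w"] = rng.normal(0, std, (k, k, cin, cout)).astype(
                np.float32
            )
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        def add_convt(name, cin, cout):
            std = np.sqrt(2.0 / (cin * 4))
            self.params[f"{name}_w"] = rng.normal(0, std, (2, 2, cin, cout)).astype(
                np.float32
            )
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        cin = 1
        for l in range(cfg.depth):
            for c in range(cfg.conv_per_block):
                add_conv(f"enc{l}_{c}", cin, ch(l))
                cin = ch(l)
        for c in range(cfg.conv_per_block):
            add_conv(f"mid_{c}", cin, ch(cfg.depth))
            cin = ch(cfg.depth)
        for l in reversed(range(cfg.depth)):
            add_convt(f"up{l}", cin, ch(l))
            add_conv(f"dec{l}", 2 * ch(l), ch(l))
            cin = ch(l)
        add_conv("out", cin, 1, k=1)

    @property
    def conv_layer_count(self) -> int:
        return self.cfg.conv_layer_count

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (probabilities, cache-for-backward)."""
        cfg, P = self.cfg, self.params
        caches: dict = {}
        skips = {}
        h = x.astype(np.float32)
        for l in range(cfg.depth):
            for c in range(cfg.conv_per_block):
                h, caches[f"enc{l}_{c}"] = nn.conv2d_forward(
                    h, P[f"enc{l}_{c}_w"], P[f"enc{l}_{c}_b"]
                )
                h, caches[f"enc{l}_{c}_r"] = nn.relu_forward(h)
            skips[l] = h
            h, caches[f"pool{l}"] = nn.maxpool2_forward(h)
        for c in range(cfg.conv_per_block):
            h, caches[f"mid_{c}"] = nn.conv2d_forward(h, P[f"mid_{c}_w"], P[f"mid_{c}_b"])
            h, caches[f"mid_{c}_r"] = nn.relu_forward(h)
        for l in reversed(range(cfg.depth)):
            h, caches[f"up{l}"] = nn.convt2_forward(h, P[f"up{l}_w"], P[f"up{l}_b"])
            h = np.concatenate([skips[l], h], axis=-1)
            h, caches[f"dec{l}"] = nn.conv2d_forward(h, P[f"dec{l}_w"], P[f"dec{l}_b"])
            h, caches[f"dec{l}_r"] = nn.relu_forward(h)
        h, caches["drop"] = dropout_forward(
            h, cfg.dropout_rate, rng or np.random.default_rng(), train
        )
        logits, caches["out"] = nn.conv2d_forward(h, P["out_w"], P["out_b"])
        prob = nn.sigmoid(logits)
        caches["prob"] = prob
        return prob, caches

    def backward(self, dprob_times_sig: np.ndarray, caches: dict) -> dict:
        """Backprop from d(loss)/d(logits); returns gradients per parameter."""
        cfg, P = self.cfg, self.params
        g: dict[str, np.ndarray] = {}
        dh, g["out_w"], g["out_b"] = nn.conv2d_backward(
            dprob_times_sig, caches["out"], P["out_w"]
        )
        dh = dropout_backward(dh, caches["drop"])
        for l in range(cfg.depth):
            dh = nn.relu_backward(dh, caches[f"dec{l}_r"])
            dh, g[f"dec{l}_w"], g[f"dec{l}_b"] = nn.conv2d_backward(
                dh, caches[f"dec{l}"], P[f"dec{l}_w"]
            )
            csk = self.cfg.base_filters * (2**l)
            dskip, dup = dh[..., :csk], dh[..., csk:]
            dh, g[f"up{l}_w"], g[f"up{l}_b"] = nn.convt2_backward(
                dup, caches[f"up{l}"], P[f"up{l}_w"]
            )
            caches.setdefault("_dskip", {})[l] = dskip
        for c in reversed(range(cfg.conv_per_block)):
            dh = nn.relu_backward(dh, caches[f"mid_{c}_r"])
            dh, g[f"mid_{c}_w"], g[f"mid_{c}_b"] = nn.conv2d_backward(
                dh, caches[f"mid_{c}"], P[f"mid_{c}_w"]
            )
        for l in reversed(range(cfg.depth)):
            dh = nn.maxpool2_backward(dh, caches[f"pool{l}"])
            dh = dh + caches["_dskip"][l]
            for c in reversed(range(cfg.conv_per_block)):
                dh = nn.relu_backward(dh, caches[f"enc{l}_{c}_r"])
                dh, g[f"enc{l}_{c}_w"], g[f"enc{l}_{c}_b"] = nn.conv2d_backward(
                    dh, caches[f"enc{l}_{c}"], P[f"enc{l}_{c}_w"]
                )
        return g


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a U-Net; the default audits to 19 convolutional layers."""
    return UNet(cfg or UNetConfig(), seed=seed)


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """1 - (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps), per sample, batch-averaged."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
    n = pred.shape[0]
    p = pred.reshape(n, -1)
    t = target.reshape(n, -1)
    num = 2.0 * (p * t).sum(axis=1) + eps
    den = p.sum(axis=1) + t.sum(axis=1) + eps
    return float(np.mean(1.0 - num / den))


def _soft_dice_grad(pred: np.ndarray, target: np.ndarray, eps: float) -> np.ndarray:
    """d(batch-mean soft dice loss)/d(pred)."""
    n = pred.shape[0]
    p = pred.reshape(n, -1).astype(np.float64)
    t = target.reshape(n, -1).astype(np.float64)
    num = 2.0 * (p * t).sum(axis=1, keepdims=True) + eps
    den = p.sum(axis=1, keepdims=True) + t.sum(axis=1, keepdims=True) + eps
    grad = -(2.0 * t * den - num) / den**2 / n
    return grad.reshape(pred.shape).astype(np.float32)


def _liver_stage_slices(vol: CTVolume, window: WindowSpec, median_kernel: int,
                        input_size: tuple[int, int]):
    win = hu_window(vol, window)
    for s in extract_slices(win):
        filt = median_filter(s.pixels, median_kernel)
        yield s.index, resize_image(filt, input_size, order=1)


def _tumor_stage_slices(vol: CTVolume, liver: BinaryMask, window: WindowSpec,
                        eed: EEDParams, roi_margin: int,
                        input_size: tuple[int, int]):
    win = hu_window(vol, window)
    roi, rec = crop_liver_roi(win, liver, margin=roi_margin)
    enhanced = eed_filter(roi, eed)
    for s in extract_slices(enhanced):
        yield s.index, resize_image(s.pixels, input_size, order=1), rec


def select_training_slices(
    volumes: list[CTVolume],
    liver_masks: list[BinaryMask],
    tumor_masks: list[BinaryMask] | None,
    stage: str,
    window: WindowSpec | None = None,
    median_kernel: int = 3,
    eed: EEDParams | None = None,
    input_size: tuple[int, int] = (256, 256),
    roi_margin: int = 5,
    max_slices: int | None = None,
    seed: int = 0,
) -> SliceDataset:
    """Build the training set for one stage, excluding empty-target slices.

    Liver stage: whole-abdomen windowed + median-filtered slices whose
    liver mask is nonempty.  Tumor stage: EED-enhanced liver-ROI slices
    whose tumor mask is nonempty; volumes with no tumor annotation at all
    contribute nothing.  ``max_slices`` (optional) subsamples the result
    uniformly at random to bound CPU training time.
    """
    if stage not in ("liver", "tumor"):
        raise ValueError(f"unknown stage {stage!r}")
    window = window or WindowSpec()
    eed = eed or EEDParams()
    xs, ys = [], []
    if stage == "liver":
        for vol, liver in zip(volumes, liver_masks):
            mask_slices = {s.index: s.pixels for s in extract_slices(
                CTVolume(liver.voxels.astype(np.float32), vol.spacing, vol.affine))}
            for idx, pix in _liver_stage_slices(vol, window, median_kernel, input_size):
                target = mask_slices[idx]
                if target.sum() == 0:
                    continue
                xs.append(pix)
                ys.append(resize_image(target.astype(np.uint8), input_size, order=0))
    else:
        if tumor_masks is None:
            raise ValueError("tumor stage requires tumor masks")
        for vol, liver, tumor in zip(volumes, liver_masks, tumor_masks):
            if tumor.sum() == 0:
                continue  # unannotated/tumor-free volume: excluded entirely
            roi_probe = None
            for idx, pix, rec in _tumor_stage_slices(
                vol, liver, window, eed, roi_margin, input_size
            ):
                roi_probe = rec
                target = tumor.voxels[rec.slices][:, :, idx]
                if target.sum() == 0:
                    continue
                xs.append(pix)
                ys.append(resize_image(target.astype(np.uint8), input_size, order=0))
    if not xs:
        raise EmptyDatasetError(f"no qualifying slices for stage={stage}")
    x = np.stack(xs)[..., None].astype(np.float32)
    y = np.stack(ys)[..., None].astype(np.float32)
    if max_slices is not None and len(x) > max_slices:
        keep = np.random.default_rng(seed).choice(len(x), max_slices, replace=False)
        keep.sort()
        x, y = x[keep], y[keep]
    return SliceDataset(x=x, y=y, stage=stage)


def train(model: UNet, ds: SliceDataset, tc: TrainingConfig | None = None):
    """Train with Adam + soft-dice loss and reduce-on-plateau LR schedule.

    Returns ``(model, history)`` where history is one dict per epoch with
    keys epoch, loss, val_loss, val_dice, lr.
    """
    tc = tc or TrainingConfig()
    if tc.epochs == 0:
        return model, []
    if len(ds) == 0:
        raise EmptyDatasetError("empty dataset")
    rng = np.random.default_rng(tc.seed)
    n_val = int(round(len(ds) * tc.validation_fraction))
    order = rng.permutation(len(ds))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = order, order[:0]
    xtr, ytr = ds.x[tr_idx], ds.y[tr_idx]
    xval, yval = ds.x[val_idx], ds.y[val_idx]

    opt = nn.Adam(model.params, lr=tc.lr0)
    history = []
    best = np.inf
    since_best = 0
    for epoch in range(tc.epochs):
        perm = rng.permutation(len(xtr))
        losses = []
        for start in range(0, len(xtr), tc.batch_size):
            sel = perm[start : start + tc.batch_size]
            xb, yb = xtr[sel], ytr[sel]
            prob, caches = model.forward(xb, train=True, rng=rng)
            losses.append(soft_dice_loss(prob, yb, tc.eps))
            dprob = _soft_dice_grad(prob, yb, tc.eps)
            dlogits = dprob * prob * (1.0 - prob)
            grads = model.backward(dlogits, caches)
            opt.step(model.params, grads)
        loss = float(np.mean(losses))
        if len(xval):
            pv, _ = model.forward(xval, train=False)
            val_loss = soft_dice_loss(pv, yval, tc.eps)
            val_dice = 1.0 - soft_dice_loss((pv >= 0.5).astype(np.float32), yval, 1e-7)
            monitor = val_loss
        else:
            val_loss, val_dice = float("nan"), float("nan")
            # no validation split: monitor the train loss in inference mode
            # (dropout off) on a bounded subset, so plateau detection is not
            # driven by dropout noise
            nmon = min(len(xtr), 2 * tc.batch_size)
            pm, _ = model.forward(xtr[:nmon], train=False)
            monitor = soft_dice_loss(pm, ytr[:nmon], tc.eps)
        if monitor < best - tc.min_delta:
            best = monitor
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.lr_patience_epochs:
                opt.lr = max(opt.lr * tc.lr_factor, tc.min_lr)
                since_best = 0
        history.append(
            dict(epoch=epoch, loss=loss, val_loss=val_loss, val_dice=val_dice,
                 lr=opt.lr)
        )
    return model, history


def predict_volume(model: UNet, vol: np.ndarray | CTVolume,
                   batch_size: int = 16) -> np.ndarray:
    """Probability map per axial slice of a preprocessed volume.

    ``vol`` must already be windowed and resized so each axial slice
    matches the model input size; returns an array (n_slices, H, W) in
    [0, 1], slice order preserved.
    """
    voxels = vol.voxels if isinstance(vol, CTVolume) else np.asarray(vol)
    axial = vol.axial_axis if isinstance(vol, CTVolume) else 2
    stack = np.moveaxis(voxels, axial, 0).astype(np.float32)
    if stack.shape[1:] != tuple(model.cfg.input_size):
        raise ValueError(
            f"slice shape {stack.shape[1:]} != model input {model.cfg.input_size}"
        )
    maps = []
    for start in range(0, len(stack), batch_size):
        xb = stack[start : start + batch_size][..., None]
        prob, _ = model.forward(xb, train=False)
        maps.append(prob[..., 0])
    return np.concatenate(maps, axis=0)


def binarize(maps: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-pixel cut at ``threshold`` (>= keeps ties as foreground)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    maps = np.asarray(maps)
    if maps.min() < 0 or maps.max() > 1:
        raise ValueError("probability maps must lie in [0,1]")
    return (maps >= threshold).astype(np.uint8)


def save_model(model: UNet, path: str | Path) -> None:
    """Single-file .npz checkpoint: config JSON + parameter arrays."""
    cfg = json.dumps(asdict(model.cfg))
    np.savez_compressed(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                        **model.params)


def load_model(path: str | Path) -> UNet:
    with np.load(path) as z:
        cfg_d = json.loads(bytes(z["__config__"].tobytes()).decode())
        cfg_d["input_size"] = tuple(cfg_d["input_size"])
        model = UNet(UNetConfig(**cfg_d))
        for k in model.params:
            model.params[k] = z[k]
    return model
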