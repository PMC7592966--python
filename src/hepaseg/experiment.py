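"""Self-contained synthetic end-to-end experiment.

Trains both cascade stages on a phantom corpus and evaluates on held-out
phantoms, mirroring the real study design (train, predict, refine,
Dice per case, U-Net-only vs U-Net + level set ablation) at a size a
single CPU handles.  The experiment preset uses the U-Net family at
input 128x128, depth 3 and 8 base filters, a bounded number of training
slices, and per-stage epoch counts (the small-lesion stage needs more
optimisation steps than the large, high-contrast liver); phantoms keep
the generator defaults (128x128x48 grid, 40 training / 10 evaluation
cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import evaluate_cases
from .phantom import CorpusRanges, PhantomSpec, generate_corpus
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import EEDParams, NoLiverFoundError
from .unet import (
    TrainingConfig,
    UNetConfig,
    build_unet,
    select_training_slices,
    train,
)

__all__ = ["ExperimentConfig", "run_synthetic_experiment"]


@dataclass
class ExperimentConfig:
    n_train: int = 40
    n_eval: int = 10
    seed: int = 0
    net: UNetConfig = field(
        default_factory=lambda: UNetConfig(input_size=(128, 128), depth=3,
                                           base_filters=8)
    )
    epochs_liver: int = 12
    epochs_tumor: int = 30
    batch_size: int = 16
    max_liver_slices: int = 320
    max_tumor_slices: int = 240
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    ranges: CorpusRanges = field(
        default_factory=lambda: CorpusRanges(tumor_count=(0, 4))
    )


def run_synthetic_experiment(cfg: ExperimentConfig | None = None,
                             verbose: bool = False) -> dict:
    """Train both stages on phantoms, evaluate on held-out phantoms.

    Returns a dict with ``means`` (mean Dice per metric over evaluation
    cases), ``table`` (per-case DataFrame), ``histories`` (per-stage
    training history) and the trained models.
    """
    cfg = cfg or ExperimentConfig()
    rng_seed = int(cfg.seed)

    train_cases, _ = generate_corpus(
        cfg.n_train, seed=rng_seed, base=cfg.phantom, ranges=cfg.ranges
    )
    eval_cases, _ = generate_corpus(
        cfg.n_eval, seed=rng_seed + 10_000, base=cfg.phantom, ranges=cfg.ranges
    )
    vols = [c[0] for c in train_cases]
    livers = [c[1] for c in train_cases]
    tumors = [c[2] for c in train_cases]

    input_size = tuple(cfg.net.input_size)
    eed = EEDParams()
    ds_liver = select_training_slices(
        vols, livers, tumors, "liver", input_size=input_size,
        max_slices=cfg.max_liver_slices, seed=rng_seed,
    )
    ds_tumor = select_training_slices(
        vols, livers, tumors, "tumor", input_size=input_size, eed=eed,
        max_slices=cfg.max_tumor_slices, seed=rng_seed,
    )
    tc_liver = TrainingConfig(epochs=cfg.epochs_liver,
                              batch_size=cfg.batch_size, seed=rng_seed)
    tc_tumor = TrainingConfig(epochs=cfg.epochs_tumor,
                              batch_size=cfg.batch_size, seed=rng_seed)
    liver_model = build_unet(cfg.net, seed=rng_seed)
    liver_model, hist_liver = train(liver_model, ds_liver, tc_liver)
    tumor_model = build_unet(cfg.net, seed=rng_seed + 1)
    tumor_model, hist_tumor = train(tumor_model, ds_tumor, tc_tumor)
    if verbose:
        print(f"liver stage: {len(ds_liver)} slices, "
              f"final loss {hist_liver[-1]['loss']:.4f}")
        print(f"tumor stage: {len(ds_tumor)} slices, "
              f"final loss {hist_tumor[-1]['loss']:.4f}")

    pcfg = PipelineConfig(unet_liver=cfg.net, unet_tumor=cfg.net, eed=eed)
    preds, truths = {}, {}
    for i, (vol, liver, tumor) in enumerate(eval_cases):
        cid = f"case_{i:04d}"
        try:
            res = run_pipeline(vol, pcfg, liver_model=liver_model,
                               tumor_model=tumor_model)
            preds[cid] = {
                "liver": res.liver, "tumor": res.tumor,
                "liver_unet": res.liver_unet, "tumor_unet": res.tumor_unet,
            }
        except NoLiverFoundError:
            z = np.zeros(vol.shape, dtype=np.uint8)
            preds[cid] = {"liver": z, "tumor": z, "liver_unet": z,
                          "tumor_unet": z}
        truths[cid] = {"liver": liver, "tumor": tumor}
        if verbose:
            from .evaluation import dice
            print(f"{cid}: liver {dice(preds[cid]['liver'], liver):.3f} "
                  f"(unet {dice(preds[cid]['liver_unet'], liver):.3f}), "
                  f"tumor {dice(preds[cid]['tumor'], tumor):.3f} "
                  f"(unet {dice(preds[cid]['tumor_unet'], tumor):.3f})")

    scores, means, table = evaluate_cases(preds, truths)
    fp = [int(np.logical_and(np.asarray(preds[c]["tumor"].voxels if hasattr(preds[c]["tumor"], "voxels") else preds[c]["tumor"]).astype(bool),
                             ~truths[c]["tumor"].voxels.astype(bool)).sum())
          for c in sorted(preds)]
    table = table.assign(tumor_fp_voxels=fp)
    return {
        "means": means,
        "table": table,
        "scores": scores,
        "histories": {"liver": hist_liver, "tumor": hist_tumor},
        "models": {"liver": liver_model, "tumor": tumor_model},
        "config": cfg,
    }
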