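"""Per-case Dice evaluation and ablation reporting.

Dice(A, B) = 2|A ∩ B| / (|A| + |B|) compares a predicted mask A with the
ground truth B over a whole volume ("Dice per case").  Conventions, both
configurable: two empty masks score 1.0, and cases whose ground truth has
no tumor are excluded from the tumor mean (they are still listed, with a
``tumor_free`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_ct import BinaryMask

__all__ = ["CaseScore", "dice", "evaluate_cases"]


def _arr(m) -> np.ndarray:
    return m.voxels if isinstance(m, BinaryMask) else np.asarray(m)


def dice(a, b, empty_value: float = 1.0) -> float:
    """Overlap 2|A∩B|/(|A|+|B|) in [0,1]; both-empty returns ``empty_value``."""
    a, b = _arr(a).astype(bool), _arr(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return empty_value
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class CaseScore:
    case_id: str
    liver_dice: float
    tumor_dice: float
    liver_dice_unet: float = float("nan")
    tumor_dice_unet: float = float("nan")
    tumor_free: bool = False


def evaluate_cases(
    preds: Mapping[str, Mapping[str, object]],
    truths: Mapping[str, Mapping[str, object]],
    empty_value: float = 1.0,
    exclude_tumor_free: bool = True,
) -> tuple[list[CaseScore], dict[str, float], pd.DataFrame]:
    """Score matched cases and average per metric.

    ``preds[case_id]`` maps mask names (``liver``, ``tumor``, optionally
    ``liver_unet``/``tumor_unet``) to masks; ``truths[case_id]`` provides
    ``liver`` and ``tumor``.  Returns (per-case scores, means, CSV-ready
    table).  Tumor-free truth cases are flagged and, by default, excluded
    from the tumor means.
    """
    missing = sorted(set(preds) ^ set(truths))
    if missing:
        raise ValueError(f"unmatched case ids: {missing}")
    scores: list[CaseScore] = []
    for cid in sorted(preds):
        p, t = preds[cid], truths[cid]
        tumor_free = _arr(t["tumor"]).sum() == 0
        s = CaseScore(
            case_id=cid,
            liver_dice=dice(p["liver"], t["liver"], empty_value),
            tumor_dice=dice(p["tumor"], t["tumor"], empty_value),
            tumor_free=bool(tumor_free),
        )
        if "liver_unet" in p:
            s.liver_dice_unet = dice(p["liver_unet"], t["liver"], empty_value)
        if "tumor_unet" in p:
            s.tumor_dice_unet = dice(p["tumor_unet"], t["tumor"], empty_value)
        scores.append(s)
    df = pd.DataFrame([vars(s) for s in scores])
    means: dict[str, float] = {"liver_dice": float(df["liver_dice"].mean())}
    if df["liver_dice_unet"].notna().any():
        means["liver_dice_unet"] = float(df["liver_dice_unet"].mean())
    tdf = df[~df["tumor_free"]] if exclude_tumor_free else df
    means["tumor_dice"] = float(tdf["tumor_dice"].mean()) if len(tdf) else float("nan")
    if tdf["tumor_dice_unet"].notna().any():
        means["tumor_dice_unet"] = float(tdf["tumor_dice_unet"].mean())
    means["n_cases"] = float(len(df))
    means["n_tumor_free"] = float(df["tumor_free"].sum())
    return scores, means, df
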