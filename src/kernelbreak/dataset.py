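"""Tabular container joining shape features, class labels and kernel weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

CLASSES = ("unbroken", "broken")


@dataclass
class KernelDataset:
    """Feature table with class label, ground-truth weight and a
    calibration/prediction split.

    The frame has columns ``kernel_id, class, true_weight_g, S, C, R_a,
    L_ab, L_cd, e, R_r, split`` with ``split`` in {"calibration",
    "prediction"}.  Both splits are non-empty, disjoint by construction, and
    class proportions in each split stay within 5 points of the overall mix.
    """

    frame: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"class", "true_weight_g", "split", *FEATURE_NAMES}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns: {sorted(missing)}")
        splits = set(self.frame["split"])
        if splits - {"calibration", "prediction"}:
            raise ValueError(f"unknown split labels: {splits}")
        for s in ("calibration", "prediction"):
            if not (self.frame["split"] == s).any():
                raise ValueError(f"{s} split is empty")
        overall = (self.frame["class"] == "broken").mean()
        for s in ("calibration", "prediction"):
            frac = (self.subset(s)["class"] == "broken").mean()
            if abs(frac - overall) > 0.05:
                raise ValueError(
                    f"class proportions in {s} split ({frac:.3f}) deviate from "
                    f"overall ({overall:.3f}) by more than 5 points"
                )

    def subset(self, split: str, class_label: str | None = None) -> pd.DataFrame:
        sel = self.frame["split"] == split
        if class_label is not None:
            sel &= self.frame["class"] == class_label
        return self.frame.loc[sel]

    def xy(self, split: str, target: str, class_label: str | None = None):
        """(X, y) arrays for a split; ``target`` is ``"weight"`` or ``"class"``."""
        sub = self.subset(split, class_label)
        X = sub.loc[:, list(FEATURE_NAMES)]
        y = sub["true_weight_g"].to_numpy() if target == "weight" else sub["class"].to_numpy()
        return X, y

    def __len__(self) -> int:
        return len(self.frame)
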