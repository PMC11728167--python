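"""Evaluation metrics and summaries for the weight and defect models.

The correlation statistic ``r`` used throughout this package is the
coefficient-of-determination form

    r = 1 - sum (y_actual - y_pred)^2 / sum (y_actual - y_mean)^2,

reported under that (field-customary) name; a true Pearson correlation is
computed alongside.  ``SD`` is the population standard deviation of the
predictions and ``RMSE`` uses an N-1 denominator (an N-denominator variant
is available behind a flag).  Classification quality is summarized by a 2x2
confusion matrix, per-class recall and the broken-kernel misjudgment rate
(1 - precision of the broken class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CLASSES
from .features import FEATURE_NAMES


@dataclass(frozen=True)
class RegressionReport:
    r: float
    SD: float
    RMSE: float
    pearson_r: float
    N: int

    def as_dict(self) -> dict:
        return {"r": self.r, "SD": self.SD, "RMSE": self.RMSE,
                "pearson_r": self.pearson_r, "N": self.N}


@dataclass(frozen=True)
class ClassificationReport:
    confusion: np.ndarray  # rows actual, cols predicted, order CLASSES
    accuracy: float
    recall: dict[str, float]
    misjudgment_rate: float
    N: int

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "classes": list(CLASSES),
            "accuracy": self.accuracy,
            "recall": dict(self.recall),
            "misjudgment_rate": self.misjudgment_rate,
            "N": self.N,
        }


def regression_report(actual, predicted, rmse_denominator: str = "n-1") -> RegressionReport:
    """Fit-quality report (r, SD, RMSE, Pearson r) for predicted weights."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two observations")
    sst = float(((a - a.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("actual series is constant; r is undefined")
    sse = float(((a - p) ** 2).sum())
    r = 1.0 - sse / sst
    sd = float(np.sqrt(((p - p.mean()) ** 2).sum() / n))
    if rmse_denominator == "n-1":
        rmse = float(np.sqrt(sse / (n - 1)))
    elif rmse_denominator == "n":
        rmse = float(np.sqrt(sse / n))
    else:
        raise ValueError("rmse_denominator must be 'n-1' or 'n'")
    if p.std() == 0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(a, p)[0, 1])
    return RegressionReport(r=r, SD=sd, RMSE=rmse, pearson_r=pearson, N=n)


def classification_report(actual, predicted) -> ClassificationReport:
    """2x2 confusion statistics over the {unbroken, broken} labels."""
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    unknown = set(np.unique(np.concatenate([a, p]))) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    confusion = np.zeros((2, 2), dtype=int)
    for i, ca in enumerate(CLASSES):
        for j, cp in enumerate(CLASSES):
            confusion[i, j] = int(np.sum((a == ca) & (p == cp)))
    n = int(confusion.sum())
    accuracy = float(np.trace(confusion)) / n
    recall = {}
    for i, c in enumerate(CLASSES):
        row = confusion[i].sum()
        recall[c] = float(confusion[i, i]) / row if row else float("nan")
    jb = CLASSES.index("broken")
    predicted_broken = confusion[:, jb].sum()
    misjudgment = (
        float(predicted_broken - confusion[jb, jb]) / predicted_broken
        if predicted_broken
        else 0.0
    )
    return ClassificationReport(
        confusion=confusion, accuracy=accuracy, recall=recall,
        misjudgment_rate=misjudgment, N=n,
    )


def taylor_summary(reports: list[tuple[str, RegressionReport]]) -> pd.DataFrame:
    """Tidy (model, r, SD, RMSE, pearson_r) table for a Taylor-style comparison."""
    if not reports:
        raise ValueError("need at least one report")
    rows = [
        {"model": name, "r": rep.r, "SD": rep.SD, "RMSE": rep.RMSE, "pearson_r": rep.pearson_r}
        for name, rep in reports
    ]
    return pd.DataFrame(rows, columns=["model", "r", "SD", "RMSE", "pearson_r"])


def plot_taylor(reports, actual, ax=None):
    """Polar Taylor diagram: angle = arccos(Pearson r), radius = prediction SD.

    The observation point sits on the horizontal axis at the actual-series
    SD; distance from a model point to it reflects the centered RMS error.
    """
    import matplotlib.pyplot as plt

    actual = np.asarray(actual, dtype=float)
    obs_sd = float(actual.std())
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(111, projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    ax.plot([0], [obs_sd], "k*", markersize=12, label="Obs")
    for name, rep in reports:
        angle = float(np.arccos(np.clip(rep.pearson_r, -1, 1)))
        ax.plot([angle], [rep.SD], "o", label=name)
    ax.legend(loc="upper right", fontsize="small")
    return ax


def quadratic_feature_fit(feature, weights) -> tuple[np.ndarray, float]:
    """Least-squares quadratic fit w ~ a f^2 + b f + c and its r statistic.

    Used to rank individual descriptors by how well each alone explains
    kernel weight.
    """
    f = np.asarray(feature, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.size != w.size or f.size < 4:
        raise ValueError("need matched series of length >= 4")
    if np.ptp(f) == 0:
        raise ValueError("constant feature; quadratic fit is degenerate")
    coeffs = np.polyfit(f, w, 2)
    fitted = np.polyval(coeffs, f)
    rep = regression_report(w, fitted)
    return coeffs, rep.r


def rank_features_by_quadratic_fit(frame: pd.DataFrame, weight_col: str = "true_weight_g") -> pd.DataFrame:
    """Order the seven descriptors by single-feature quadratic r, descending."""
    rows = []
    for name in FEATURE_NAMES:
        _, r = quadratic_feature_fit(frame[name], frame[weight_col])
        rows.append({"feature": name, "r": r})
    out = pd.DataFrame(rows).sort_values(["r", "feature"], ascending=[False, True])
    return out.reset_index(drop=True)
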