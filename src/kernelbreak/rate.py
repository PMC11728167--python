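"""Broken-rate estimation: classifier + class-specific weight regressors
fused into Z_s = m_s / M_i x 100 (percent by mass), and the bench-validation
protocol over synthetic mixtures of known broken rate."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, features_table
from .models import TrainedModel
from .segment import segment_scene

#: predicted weights are floored here (grams) before summing
WEIGHT_FLOOR = 0.01


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class BrokenRateResult:
    """Broken-rate estimate for one scene or batch.

    ``m_s`` is the (predicted) broken mass, ``M_i`` the total mass, both in
    grams, and ``Z_s = m_s / M_i * 100`` exactly.  ``per_kernel`` lists each
    kernel's predicted class and weight.
    """

    m_s: float
    M_i: float
    Z_s: float
    per_kernel: pd.DataFrame

    def __post_init__(self) -> None:
        if self.M_i <= 0:
            raise RateError("total mass must be positive")
        if not (0 <= self.m_s <= self.M_i):
            raise RateError("broken mass must lie in [0, total mass]")
        if self.Z_s != self.m_s / self.M_i * 100:
            raise RateError("Z_s must equal m_s / M_i * 100 exactly")

    @classmethod
    def from_masses(cls, m_s: float, m_i: float, per_kernel: pd.DataFrame) -> "BrokenRateResult":
        return cls(m_s=m_s, M_i=m_i, Z_s=m_s / m_i * 100, per_kernel=per_kernel)


def estimate_broken_rate(
    features: pd.DataFrame,
    classifier: TrainedModel,
    broken_regressor: TrainedModel,
    unbroken_regressor: TrainedModel,
) -> BrokenRateResult:
    """Classify each kernel, weigh it with its class's regressor, and form
    the mass-ratio broken rate.

    Misclassified kernels are weighed by the routed (possibly wrong-class)
    regressor, exactly as a deployed pipeline would.  Non-positive weight
    predictions are floored at 0.01 g with a warning.
    """
    if len(features) == 0:
        raise RateError("empty kernel table")
    labels = np.asarray(classifier.predict(features))
    weights = np.empty(len(features), dtype=float)
    for cls_label, reg in (("broken", broken_regressor), ("unbroken", unbroken_regressor)):
        sel = labels == cls_label
        if sel.any():
            weights[sel] = reg.predict(features.loc[sel])
    if (weights < WEIGHT_FLOOR).any():
        warnings.warn(
            f"{int((weights < WEIGHT_FLOOR).sum())} predicted weights floored at "
            f"{WEIGHT_FLOOR} g",
            stacklevel=2,
        )
        weights = np.maximum(weights, WEIGHT_FLOOR)
    per_kernel = pd.DataFrame(
        {
            "kernel_id": features["kernel_id"].to_numpy()
            if "kernel_id" in features
            else np.arange(len(features)),
            "predicted_class": labels,
            "predicted_weight_g": weights,
        }
    )
    m_i = float(weights.sum())
    m_s = float(weights[labels == "broken"].sum())
    return BrokenRateResult.from_masses(m_s=m_s, m_i=m_i, per_kernel=per_kernel)


def estimate_from_scene(
    image: np.ndarray,
    classifier: TrainedModel,
    broken_regressor: TrainedModel,
    unbroken_regressor: TrainedModel,
    scale: float | None = None,
    background: np.ndarray | None = None,
    min_area: int = 50,
) -> BrokenRateResult:
    """Segment a scene image and estimate its broken rate."""
    masks = segment_scene(image, background=background, min_area=min_area)
    if not masks:
        raise RateError("no kernels found in scene")
    table = features_table([m.pixels for m in masks], scale=scale)
    return estimate_broken_rate(table, classifier, broken_regressor, unbroken_regressor)


@dataclass(frozen=True)
class ValidationResult:
    """Predicted-vs-true broken rates with the OLS fit of predicted on true."""

    table: pd.DataFrame  # columns: level, rep, true_rate, predicted_rate
    slope: float
    intercept: float
    r_squared: float


DEFAULT_LEVELS = (1, 3, 5, 7, 9, 11, 13, 15)


def run_validation(
    levels=DEFAULT_LEVELS,
    reps: int = 3,
    classifier: TrainedModel | None = None,
    broken_regressor: TrainedModel | None = None,
    unbroken_regressor: TrainedModel | None = None,
    seed: int = 2018,
    scale: float | None = None,
    total_mass: float = 10.0,
    oracle: bool = False,
    weight_model=None,
) -> ValidationResult:
    """Bench-validation protocol: for each target level x rep, pack a ~10 g
    mixture at that broken rate, image it, segment, extract features,
    estimate Z_s, then regress predicted on true rates.

    With ``oracle=True`` the generator's ground-truth classes and weights are
    used instead of trained models (slope 1, intercept 0, R^2 = 1 by
    construction); otherwise all three models must be supplied.
    """
    from .synth import WeightModel, generate_mixture

    if len(levels) == 0 or reps < 1:
        raise RateError("need at least one level and one rep")
    if not oracle and None in (classifier, broken_regressor, unbroken_regressor):
        raise RateError("trained models required unless oracle=True")
    weight_model = weight_model or WeightModel()
    if scale is None:
        scale = weight_model.mm_per_px
    rng = np.random.default_rng(seed)

    rows = []
    for level in levels:
        for rep in range(reps):
            image, _, truth, truth_result = generate_mixture(
                float(level), total_mass=total_mass, rng=rng,
                weight_model=weight_model, scene_id=f"L{level}r{rep}",
            )
            if oracle:
                predicted = truth_result.Z_s
            else:
                est = estimate_from_scene(
                    image, classifier, broken_regressor, unbroken_regressor, scale=scale
                )
                predicted = est.Z_s
            rows.append(
                {
                    "level": float(level),
                    "rep": rep,
                    "true_rate": truth_result.Z_s,
                    "predicted_rate": predicted,
                }
            )
    table = pd.DataFrame(rows)
    fit = stats.linregress(table["true_rate"], table["predicted_rate"])
    return ValidationResult(
        table=table,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
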