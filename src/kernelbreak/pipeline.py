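"""High-level Model/Results interface over the full pipeline.

``BrokenRateModel`` is built from a :class:`~kernelbreak.dataset.KernelDataset`
(or a plain feature DataFrame); ``fit()`` trains the broken/unbroken defect
classifier and the two class-specific weight regressors and returns a
``BrokenRateResults`` carrying held-out evaluation reports, a ``summary()``
table, scene-level estimation and the bench-validation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import KernelDataset
from .metrics import (
    ClassificationReport,
    RegressionReport,
    classification_report,
    regression_report,
    taylor_summary,
)
from .models import TrainedModel, fit_default, grid_search_fit
from .rate import BrokenRateResult, ValidationResult, estimate_broken_rate, estimate_from_scene, run_validation
from .synth import WeightModel


class BrokenRateModel:
    """Broken-rate estimation model over a labelled kernel feature dataset.

    Parameters
    ----------
    dataset
        Calibration/prediction-split kernel dataset.
    classifier_algorithm
        Defect classifier family (default SVM, selected by grid search).
    broken_algorithm, unbroken_algorithm
        Per-class weight regressors (defaults LGBM and RF, the algorithms
        found optimal for each class).
    search
        If True, grid-search the regressors too; otherwise fit them with the
        shipped default hyperparameters.
    """

    def __init__(
        self,
        dataset: KernelDataset,
        classifier_algorithm: str = "SVM",
        broken_algorithm: str = "LGBM",
        unbroken_algorithm: str = "RF",
        search: bool = False,
        seed: int = 2018,
        weight_model: WeightModel | None = None,
    ):
        self.dataset = dataset
        self.classifier_algorithm = classifier_algorithm
        self.broken_algorithm = broken_algorithm
        self.unbroken_algorithm = unbroken_algorithm
        self.search = search
        self.seed = seed
        self.weight_model = weight_model or WeightModel()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, seed: int = 2018, **kwargs) -> "BrokenRateModel":
        """Build from a flat table with class/weight/split columns."""
        return cls(KernelDataset(frame=frame, seed=seed), seed=seed, **kwargs)

    def fit(self) -> "BrokenRateResults":
        ds = self.dataset
        Xc, yc = ds.xy("calibration", "class")
        classifier = grid_search_fit(
            Xc, yc, "classification", self.classifier_algorithm, seed=self.seed
        )
        regressors = {}
        for cls_label, algo in (
            ("broken", self.broken_algorithm),
            ("unbroken", self.unbroken_algorithm),
        ):
            Xw, yw = ds.xy("calibration", "weight", class_label=cls_label)
            if self.search:
                regressors[cls_label] = grid_search_fit(
                    Xw, yw, "regression", algo, seed=self.seed
                )
            else:
                regressors[cls_label] = fit_default("regression", algo, Xw, yw, seed=self.seed)
        return BrokenRateResults(model=self, classifier=classifier,
                                 broken_regressor=regressors["broken"],
                                 unbroken_regressor=regressors["unbroken"])


@dataclass
class BrokenRateResults:
    """Fitted pipeline with held-out diagnostics."""

    model: BrokenRateModel
    classifier: TrainedModel
    broken_regressor: TrainedModel
    unbroken_regressor: TrainedModel
    _weight_reports: dict = field(default_factory=dict, init=False, repr=False)
    _class_report: ClassificationReport | None = field(default=None, init=False, repr=False)

    # -- held-out evaluation -------------------------------------------------
    def weight_report(self, class_label: str) -> RegressionReport:
        """r / SD / RMSE of the class's weight regressor on the prediction split."""
        if class_label not in self._weight_reports:
            reg = self.broken_regressor if class_label == "broken" else self.unbroken_regressor
            X, y = self.model.dataset.xy("prediction", "weight", class_label=class_label)
            self._weight_reports[class_label] = regression_report(y, reg.predict(X))
        return self._weight_reports[class_label]

    def classification_report(self) -> ClassificationReport:
        if self._class_report is None:
            X, y = self.model.dataset.xy("prediction", "class")
            self._class_report = classification_report(y, self.classifier.predict(X))
        return self._class_report

    def summary(self) -> str:
        """Plain-text summary of fitted components and held-out scores."""
        rows = []
        for cls_label, reg in (("broken", self.broken_regressor), ("unbroken", self.unbroken_regressor)):
            rep = self.weight_report(cls_label)
            rows.append(
                f"  {cls_label:>9} weight | {reg.algorithm:<4} "
                f"r={rep.r:6.3f}  SD={rep.SD:6.3f}  RMSE={rep.RMSE:6.3f} g  (N={rep.N})"
            )
        crep = self.classification_report()
        lines = [
            "Broken-rate pipeline (fitted)",
            "=" * 60,
            f"  dataset: {len(self.model.dataset)} kernels "
            f"({(self.model.dataset.frame['class'] == 'broken').sum()} broken), "
            f"seed={self.model.seed}",
            *rows,
            f"  classifier       | {self.classifier.algorithm:<4} "
            f"accuracy={crep.accuracy:5.3f}  misjudgment={crep.misjudgment_rate:5.3f}",
            f"  confusion (rows actual unbroken/broken): {crep.confusion.tolist()}",
        ]
        return "\n".join(lines)

    def taylor_table(self) -> pd.DataFrame:
        reports = [
            (f"{c}:{r.algorithm}", self.weight_report(c))
            for c, r in (("broken", self.broken_regressor), ("unbroken", self.unbroken_regressor))
        ]
        return taylor_summary(reports)

    # -- application ---------------------------------------------------------
    def estimate(self, features: pd.DataFrame) -> BrokenRateResult:
        """Broken rate of a batch given its kernel feature table."""
        return estimate_broken_rate(
            features, self.classifier, self.broken_regressor, self.unbroken_regressor
        )

    def estimate_scene(self, image: np.ndarray, **kwargs) -> BrokenRateResult:
        """Broken rate of a scene image (segmentation + features + fusion)."""
        kwargs.setdefault("scale", self.model.weight_model.mm_per_px)
        return estimate_from_scene(
            image, self.classifier, self.broken_regressor, self.unbroken_regressor, **kwargs
        )

    def validate(self, levels=(1, 3, 5, 7, 9, 11, 13, 15), reps: int = 3, seed: int | None = None) -> ValidationResult:
        """Bench validation on fresh synthetic mixtures at the given levels."""
        return run_validation(
            levels=levels,
            reps=reps,
            classifier=self.classifier,
            broken_regressor=self.broken_regressor,
            unbroken_regressor=self.unbroken_regressor,
            seed=self.model.seed if seed is None else seed,
            weight_model=self.model.weight_model,
        )
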