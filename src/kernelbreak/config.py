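"""Run configuration, manifests and model persistence.

A run is reproducible bit-for-bit from its manifest: the config snapshot,
the master seed and the library versions.  Config files are YAML; CLI flags
override file values.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import yaml

DEFAULT_SEED = 2018


@dataclass
class RunConfig:
    seed: int = DEFAULT_SEED
    data_dir: str = "data"
    model_dir: str = "models"
    report_dir: str = "reports"
    scale_mm_per_px: float = 0.1
    logging_level: str = "INFO"
    # generator
    n_broken: int = 180
    n_unbroken: int = 120
    split_fraction: float = 0.75
    scene_kernels: int = 36
    image_size: tuple[int, int] = (2048, 2592)
    background_level: float = 40.0
    kernel_level: float = 200.0
    noise_sd: float = 5.0
    min_gap: int = 12
    # segmentation
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area: int = 50
    # models
    classifier_algorithm: str = "SVM"
    broken_algorithm: str = "LGBM"
    unbroken_algorithm: str = "RF"
    grid_search: bool = False
    grids: dict = field(default_factory=dict)  # overrides of models.default_grids()
    # validation
    validation_levels: tuple = (1, 3, 5, 7, 9, 11, 13, 15)
    validation_reps: int = 3

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if not 0 < cfg.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        for name, g in (cfg.grids or {}).items():
            if not g:
                raise ValueError(f"grid for {name} is empty")
        return cfg

    def to_yaml(self) -> str:
        d = self.as_dict()
        d["image_size"] = list(d["image_size"])
        d["validation_levels"] = list(d["validation_levels"])
        return yaml.safe_dump(d, sort_keys=False)


def _versions() -> dict:
    import lightgbm
    import numpy
    import pandas
    import shapely
    import skimage
    import sklearn

    from . import __version__

    return {
        "kernelbreak": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "lightgbm": lightgbm.__version__,
        "shapely": shapely.__version__,
    }


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "seed": config.seed,
        "config": json.loads(json.dumps(config.as_dict(), default=list)),
        "versions": _versions(),
    }
    if extra:
        manifest.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def save_models(directory: str | Path, results, config: RunConfig) -> None:
    """Persist a fitted pipeline (classifier + two regressors) with manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "classifier": results.classifier,
            "broken_regressor": results.broken_regressor,
            "unbroken_regressor": results.unbroken_regressor,
            "weight_model": results.model.weight_model,
        },
        directory / "models.joblib",
    )
    chosen = {
        "classifier": results.classifier.chosen_params,
        "broken_regressor": results.broken_regressor.chosen_params,
        "unbroken_regressor": results.unbroken_regressor.chosen_params,
    }
    write_manifest(directory / "manifest.json", config, extra={"chosen_params": chosen})


def load_models(directory: str | Path) -> dict:
    return joblib.load(Path(directory) / "models.joblib")
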