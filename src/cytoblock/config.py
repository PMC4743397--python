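"""Run configuration: every numeric constant of the screen in one place.

Defaults reproduce the published operating point of the method (working
resolution 800×1000, 100-pixel blocks, 5×5 median window, GLCM distance 2
with 16 levels, RIU non-background peak bin 5, tenfold CV, RBF parameters
c = 10 and g = 3.1623).  Any value can be overridden from a YAML file or a
CLI flag without code changes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("cytoblock")


@dataclass
class RunConfig:
    # image preparation
    resize_rows: int = 800
    resize_cols: int = 1000
    block_size: int = 100
    median_window: int = 5
    # background filter
    riu_non_background_bin: int = 5
    min_peak_proportion: float = 0.0
    keep_background: bool = False
    # GLCM
    glcm_levels: int = 16
    glcm_distance: int = 2
    # classifier
    svm_c: float = 10.0
    svm_g: float = 3.1623
    folds: int = 10
    grid_log10_c: tuple[float, float] = (-2.0, 3.0)
    grid_log10_g: tuple[float, float] = (-2.0, 2.0)
    grid_step: float = 0.25
    use_grid_search: bool = True
    # seeds
    seed: int = 0          # master seed: synthetic data + CV fold assignment
    # synthetic dataset sizing
    n_train_images: int = 14
    n_test_images: int = 12
    # screening-safety gate: non-zero exit if sensitivity falls below this
    # percentage (None disables the gate)
    sensitivity_floor: float | None = None

    def target_shape(self) -> tuple[int, int]:
        return (self.resize_rows, self.resize_cols)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("grid_log10_c", "grid_log10_g"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_log10_c"] = list(d["grid_log10_c"])
        d["grid_log10_g"] = list(d["grid_log10_g"])
        return d

    def echo(self, stage: str) -> None:
        """Log the parameter snapshot a stage ran with."""
        log.info("stage=%s config=%s", stage, self.to_dict())
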