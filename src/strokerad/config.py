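"""Pipeline configuration: typed blocks, YAML/JSON round-trip.

Every stochastic stage carries an explicit seed so that a saved config fully
determines a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._utils import DEFAULT_SEED


@dataclass
class PreprocessingConfig:
    """HU window, gray-level bin count and isotropic resampling target."""

    window: tuple[float, float] = (0.0, 80.0)
    n_bins: int = 64
    target_spacing_mm: float = 1.0

    def validate(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"window must satisfy low < high, got {self.window}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")


@dataclass
class FeatureConfig:
    """Texture grid: in-plane angles (degrees) and pixel offsets/steps."""

    angles: tuple[int, ...] = (0, 45, 90, 135)
    offsets: tuple[int, ...] = (1, 4, 7)
    families: tuple[str, ...] = (
        "histogram",
        "formfactor",
        "haralick",
        "GLCM",
        "RLM",
        "GLSZM",
    )

    def validate(self) -> None:
        if any(o < 1 for o in self.offsets):
            raise ValueError("offsets must be >= 1")
        bad = set(self.angles) - {0, 45, 90, 135}
        if bad:
            raise ValueError(f"unsupported angles: {sorted(bad)}")


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    rho_max: float = 0.9
    n_folds: int = 10
    n_lambdas: int = 100
    lambda_decades: float = 4.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.rho_max <= 1:
            raise ValueError("rho_max must be in (0,1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class EvaluationConfig:
    dca_grid_step: float = 0.01
    icc_inter_mode: str = "inter"
    icc_intra_mode: str = "intra"
    n_icc_subjects: int = 30
    inter_rater_magnitude: float = 0.15
    intra_rater_magnitude: float = 0.05

    def validate(self) -> None:
        if not 0 < self.dca_grid_step < 1:
            raise ValueError("dca_grid_step must be in (0,1)")


@dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = DEFAULT_SEED
    # synthetic-cohort knobs used by `run` when no external cohort is given
    n_dev: int = 85
    n_val: int = 38
    phantom_shape: tuple[int, int, int] = (48, 48, 48)
    compute_icc: bool = True

    def validate(self) -> None:
        self.preprocessing.validate()
        self.features.validate()
        self.selection.validate()
        self.evaluation.validate()

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def _mk(klass, block):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in block.items():
                if k not in fields:
                    raise KeyError(f"unknown config key {k!r} for {klass.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        d = dict(d)
        cfg = cls(
            preprocessing=_mk(PreprocessingConfig, d.pop("preprocessing", {})),
            features=_mk(FeatureConfig, d.pop("features", {})),
            selection=_mk(SelectionConfig, d.pop("selection", {})),
            evaluation=_mk(EvaluationConfig, d.pop("evaluation", {})),
        )
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        path = Path(path)
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest_text(self) -> str:
        return json.dumps(_jsonable(self.to_dict()), sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
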