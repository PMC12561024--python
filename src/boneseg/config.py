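"""Run configuration: YAML loading, validation and defaults.

Every study constant (positive-class weight 20, 10 warm-up epochs, the
50:50 loss endpoint, AdamW 1e-3 / 5e-4, plateau factor 0.5 patience 3,
192x192 input, blur sigma 5, rotations +/-10 deg, shear +/-0.2, contrast
0.25-1.75, augmented quarter, 5 folds) lives here in the default config —
the logic modules take these values as parameters and hard-code none.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_io import AugmentConfig
from .losses import LossSchedule, SoftSkeletonParams
from .phantom import PhantomConfig
from .training import TrainConfig
from .unext import UNeXtConfig


@dataclass
class RunConfig:
    name: str = "run"
    out_dir: str = "runs"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: UNeXtConfig = field(default_factory=UNeXtConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for key, sub_cls in (("phantom", PhantomConfig),
                             ("augment", AugmentConfig),
                             ("model", UNeXtConfig)):
            if key in d:
                kw[key] = _build(sub_cls, d.pop(key))
        if "train" in d:
            td = dict(d.pop("train"))
            if "schedule" in td and td["schedule"] is not None:
                td["schedule"] = _build(LossSchedule, td["schedule"])
            if "skeleton" in td and td["skeleton"] is not None:
                td["skeleton"] = _build(SoftSkeletonParams, td["skeleton"])
            if "model" in td and td["model"] is not None:
                td["model"] = _build(UNeXtConfig, td["model"])
            if "augment" in td and td["augment"] is not None:
                td["augment"] = _build(AugmentConfig, td["augment"])
            kw["train"] = _build(TrainConfig, td)
        kw.update(d)
        return cls(**kw)


def _tupleize(cls, kw: dict) -> dict:
    """YAML has no tuples; coerce list values for tuple-typed fields."""
    out = {}
    for f in dataclasses.fields(cls):
        if f.name not in kw:
            continue
        v = kw[f.name]
        out[f.name] = tuple(v) if isinstance(v, list) else v
    unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return out


def _build(cls, kw):
    if dataclasses.is_dataclass(kw):
        return kw
    return cls(**_tupleize(cls, dict(kw)))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; raises on parse/schema errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
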