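"""Run configuration: YAML round-trip and seed fan-out.

One master seed deterministically derives per-stage seeds, so a partial rerun
of any stage reproduces the full run's behaviour for that stage.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .lots_iam import IAMConfig
from .models import ArchitectureSpec
from .phantom import PhantomSpec
from .training import TrainConfig

__all__ = ["EXPERIMENTS", "RunConfig", "derive_seed"]

# experiment name -> (model family, channel layout)
EXPERIMENTS = {
    "unet_flair": ("unet", ("flair",)),
    "unet_iam": ("unet", ("iam",)),
    "unet_fi": ("unet", ("flair", "iam")),
    "saliency_fi": ("saliency_unet", ("flair", "iam")),
    "dilated_saliency_fi": ("dilated_saliency_unet", ("flair", "iam")),
}

_STAGES = ("phantom_train", "phantom_test", "iam", "patches", "train")


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    if stage not in _STAGES:
        raise ParameterError(f"unknown stage {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence([int(master), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _coerce(cls, d: dict):
    kw = {}
    for f in fields(cls):
        if f.name in d:
            v = d[f.name]
            kw[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kw)


@dataclass
class RunConfig:
    """Everything one end-to-end experiment needs."""

    experiment: str = "saliency_fi"
    seed: int = 0
    n_train_scans: int = 1
    n_test_scans: int = 1
    n_patches_per_scan: int = 50
    patch_size: int = 64
    base_width: int = 8
    wmh_fraction: float = 0.5
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(shape=(128, 128, 9)))
    iam: IAMConfig = field(default_factory=lambda: IAMConfig(n_targets=512))
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ParameterError(
                f"unknown experiment {self.experiment!r}; known: {sorted(EXPERIMENTS)}"
            )

    @property
    def family(self) -> str:
        return EXPERIMENTS[self.experiment][0]

    @property
    def channel_layout(self) -> tuple[str, ...]:
        return EXPERIMENTS[self.experiment][1]

    def architecture(self) -> ArchitectureSpec:
        fam, chans = EXPERIMENTS[self.experiment]
        in_ch = len(chans) if fam == "unet" else 1
        return ArchitectureSpec(family=fam, in_channels=in_ch, base_width=self.base_width)

    def to_yaml(self, path) -> Path:
        d = asdict(self)
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key, sub in (("phantom", PhantomSpec), ("iam", IAMConfig), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = _coerce(sub, d[key])
        return _coerce(cls, d)
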