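"""Pipeline configuration: defaults, YAML/JSON round-trip, seed policy.

One global seed is carried in the config; per-stage sub-seeds are derived
from it deterministically so a multi-stage run is reproducible end to end.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .classify import ClassificationThresholds
from .records import (
    DEFAULT_ACTIVATION_SYNONYMS,
    DEFAULT_INHIBITION_SYNONYMS,
    SignVocabulary,
)

__all__ = ["PipelineConfig", "load_config", "save_config", "derive_seed"]

#: Currency metabolites conventionally omitted from signaling maps.
DEFAULT_EXCLUSION: tuple[str, ...] = ()


@dataclass(frozen=True)
class PipelineConfig:
    """Every consumed option has a default; round-trips losslessly."""

    delimiter: str = ","
    header: bool = True
    exclusion: tuple[str, ...] = DEFAULT_EXCLUSION
    activation_synonyms: tuple[str, ...] = DEFAULT_ACTIVATION_SYNONYMS
    inhibition_synonyms: tuple[str, ...] = DEFAULT_INHIBITION_SYNONYMS
    path_mode: str = "directed"
    r2_powerlaw: float = 0.8
    r2_ck: float = 0.8
    poisson_min: float = 0.8
    poisson_margin: float = 0.3
    attack_n_remove: int = 2
    attack_reps: int = 100
    hub_aliases: dict = field(
        default_factory=lambda: {"ATP-ADP system": ["ATP", "ADP"]}
    )
    seed: int = 0

    def sign_vocabulary(self) -> SignVocabulary:
        return SignVocabulary(
            activation=tuple(self.activation_synonyms),
            inhibition=tuple(self.inhibition_synonyms),
        )

    def thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(
            r2_powerlaw=self.r2_powerlaw,
            r2_ck=self.r2_ck,
            poisson_min=self.poisson_min,
            poisson_margin=self.poisson_margin,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("exclusion", "activation_synonyms", "inhibition_synonyms"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("exclusion", "activation_synonyms", "inhibition_synonyms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load YAML or JSON config (YAML is a JSON superset, so one loader)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False), encoding="utf-8")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    stage_code = zlib.crc32(stage.encode("utf-8")) % (2**31)
    ss = np.random.SeedSequence([seed, stage_code])
    return int(ss.generate_state(1)[0] % (2**31))
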