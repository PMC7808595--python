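"""Run-level configuration shared across the pipeline stages.

Every option has a documented default; unknown keys are rejected so a typo in
a config file cannot silently change an analysis.
"""
from __future__ import annotations

import enum
import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .risk import RiskCategory


class FisherConvention(str, enum.Enum):
    """Two-sided Fisher p-value convention.

    ``minlike`` (sum of outcome probabilities no larger than the observed
    one) is the convention matched by the Fay interval construction and is
    the default; ``doubled`` doubles the smaller one-sided tail.
    """

    minlike = "minlike"
    doubled = "doubled"


class PediatricEgfrMode(str, enum.Enum):
    none = "none"
    schwartz = "schwartz"


class DeclineStaging(str, enum.Enum):
    """How creatinine-decline AKI events are staged (not defined by KDIGO)."""

    ratio_bands = "ratio_bands"  # enrollment/nadir through the same bands as rises
    always_stage1 = "always_stage1"


class VisitWindow(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")
    lo: float
    hi: float
    nominal: float

    @model_validator(mode="after")
    def _ordered(self) -> "VisitWindow":
        if not self.lo <= self.nominal <= self.hi:
            raise ValueError("window must contain its nominal time")
        return self


class VisitWindows(BaseModel):
    """Nominal-time windows (hours since enrollment) for each scheduled visit.

    Field follow-up was irregular, so a sample is assigned to the nearest
    window containing its timestamp.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    h48: VisitWindow = VisitWindow(lo=1e-9, hi=60.0, nominal=48.0)
    day7: VisitWindow = VisitWindow(lo=120.0, hi=240.0, nominal=168.0)
    month1: VisitWindow = VisitWindow(lo=504.0, hi=1080.0, nominal=720.0)
    month3: VisitWindow = VisitWindow(lo=1440.0, hi=3240.0, nominal=2160.0)
    month6: VisitWindow = VisitWindow(lo=3600.0, hi=5400.0, nominal=4320.0)


class EgfrOptions(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    race_coefficient: bool = False
    pediatric: PediatricEgfrMode = PediatricEgfrMode.none


class RunConfig(BaseModel):
    """Options that parameterize classification and inference."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int = 0
    egfr: EgfrOptions = EgfrOptions()
    score6_category: RiskCategory = RiskCategory.high
    visit_windows: VisitWindows = VisitWindows()
    fisher_convention: FisherConvention = FisherConvention.minlike
    decline_staging: DeclineStaging = DeclineStaging.ratio_bands
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def config_hash(self) -> str:
        """Stable short digest of the configuration, recorded in manifests."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CONFIG = RunConfig()
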