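"""Pipeline configuration: every constant of the method in one serializable object."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .composition import AtwaterFactors
from .daily_value import DailyReference, RoundingMode
from .exchanges import ExchangeQuantum, WheelerBands

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    atwater: AtwaterFactors = Field(default_factory=AtwaterFactors)
    daily_reference: DailyReference = Field(default_factory=DailyReference)
    quanta: ExchangeQuantum = Field(default_factory=ExchangeQuantum)
    wheeler: WheelerBands = Field(default_factory=WheelerBands)
    dv_rounding: RoundingMode = RoundingMode.truncate
    closure_tol_g: float = Field(default=0.2, gt=0)
    energy_tol_kcal: float = Field(default=1.5, gt=0)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.model_validate(data)
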