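"""Run configuration: validated, unknown keys rejected, echoed into reports."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "PuckerOptions", "MeltOptions", "ExchangeOptions"]


class ExchangeOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mc_runs: int = Field(200, ge=2)
    seed: int = 0


class PuckerOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    zeta_ms: float = Field(13.05, gt=0)
    j_north: float = 1.0
    j_south: float = 8.8
    detection_threshold: float = Field(0.01, gt=0)


class MeltOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # baseline windows as fractions of the temperature span
    baseline_fraction: float = Field(0.15, gt=0, lt=0.5)
    n_boot: int = Field(200, ge=0)
    seed: int = 0


class RunConfig(BaseModel):
    """Pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    exchange_csv: Path | None = None
    peaks_csv: Path | None = None
    traces_csv: Path | None = None
    couplings_csv: Path | None = None
    melt_csv: Path | None = None
    out_dir: Path = Path("results")
    strict: bool = False
    exchange: ExchangeOptions = ExchangeOptions()
    pucker: PuckerOptions = PuckerOptions()
    melt: MeltOptions = MeltOptions()

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def echo(self) -> dict:
        return json.loads(self.model_dump_json())
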