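"""Schema-validated YAML run configuration.

Unknown keys are rejected at load time, and physically impossible settings
(band edges at or above Nyquist) fail validation immediately rather than
mid-run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = ["RunConfig", "load_config", "save_config"]


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "bandpass"
    band: tuple[float, float] | float = (8.0, 30.0)
    order: int = 4
    phase: str = "causal"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sampling_rate: float = 512.0
    montage: list[str] = []
    class_set: list[str] = ["HAND", "FEET", "SUB", "REST"]
    bands: list[tuple[float, float]] = [(8.0, 16.0), (16.0, 30.0)]
    filters: list[FilterConfig] = []
    fit_window: tuple[float, float] = (1.0, 3.0)
    train_times: list[float] = [2.5, 3.5, 4.5]
    cv_repeats: int = 10
    cv_folds: int = 5
    thresholds: dict[str, float] = {}
    erd_depth: float = -0.5
    trials_per_class: int = 40
    seed: int = 0
    paths: dict[str, str] = {}

    @field_validator("sampling_rate")
    @classmethod
    def _positive_rate(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("sampling_rate must be positive")
        return v

    @model_validator(mode="after")
    def _bands_below_nyquist(self) -> "RunConfig":
        nyq = self.sampling_rate / 2.0
        for lo, hi in self.bands:
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz")
        for f in self.filters:
            if f.kind == "bandpass":
                lo, hi = f.band  # type: ignore[misc]
                if not 0 < lo < hi < nyq:
                    raise ValueError(
                        f"filter band ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz"
                    )
        for c, th in self.thresholds.items():
            if not 0 <= th <= 1:
                raise ValueError(f"threshold for {c!r} outside [0, 1]")
        return self


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
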