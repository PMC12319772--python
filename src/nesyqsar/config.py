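"""Run configuration: one serializable object wiring every pipeline stage.

A run is fully described by a ``RunConfig``; it is written into every run
directory, and re-running from the saved file reproduces the outputs (up to
floating-point associativity on the same backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to execute (and re-execute) one pipeline run."""

    # input: either an existing raw CSV or a simulation request
    input_csv: str | None = None
    simulate: dict = field(default_factory=lambda: {"n_records": 500, "seed": 42})

    # curation
    threshold: float = 6.0
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    exclusion_band: tuple[float, float] | None = None

    # featurization
    schemes: tuple[str, ...] = ("morgan",)
    morgan_bits: tuple[int, ...] = (1024,)
    morgan_radius: int = 2

    # model
    model: str = "ltn"  # "ltn" or "dnn"
    hidden: tuple[int, ...] = (384, 192)
    activation: str = "relu"
    dropout: float = 0.25
    label_map: dict = field(default_factory=lambda: {"active": 0, "inactive": 1})

    # logic
    p_forall: float = 2.0
    p_satagg: float = 2.0
    satagg_operator: str = "pmean_error"

    # training
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-4
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls(**data)
        cfg.ratios = tuple(cfg.ratios)
        cfg.schemes = tuple(cfg.schemes)
        cfg.morgan_bits = tuple(int(b) for b in cfg.morgan_bits)
        cfg.hidden = tuple(int(h) for h in cfg.hidden)
        if cfg.exclusion_band is not None:
            cfg.exclusion_band = tuple(cfg.exclusion_band)
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
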