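"""Pipeline configuration with the standard parameter defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import yaml

from .connectivity import RHYTHM_BANDS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters in one place.

    Defaults match the reference operating point: spline order 10,
    smoothness 4, regularization 1e-5; two ICA cleanup passes with the
    3-sigma rejection rule; the four sensorimotor rhythms; a 0.5-3.5 s
    post-cue analysis window.
    """

    bands: Sequence[Tuple[str, float, float]] = RHYTHM_BANDS
    window: Tuple[float, float] = (0.5, 3.5)
    sl_order: int = 10
    sl_rho: float = 4.0
    sl_lambda: float = 1e-5
    ica_seed: int = 0
    ica_passes: int = 2
    ref_mode: str = "auto"
    measure: str = "gfc"
    scheme: str = "kfold10"
    seed: int = 0
    test_size: float = 0.2
    select_folds: int = 5

    def validate(self) -> "PipelineConfig":
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name!r} has low >= high")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")
        if self.ica_passes < 1:
            raise ValueError("ica_passes must be >= 1")
        return self

    @property
    def sl_params(self) -> dict:
        return {"order_o": self.sl_order, "rho": self.sl_rho,
                "lambda_reg": self.sl_lambda}

    @property
    def ica_params(self) -> dict:
        return {"seed": self.ica_seed, "passes": self.ica_passes}

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "bands" in raw:
            raw["bands"] = [tuple(b) for b in raw["bands"]]
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw).validate()

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)
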