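"""Run configuration: paths by role plus analysis options, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .denaturation import CHANNELS, ROOM_TEMPERATURE_K
from .errors import ValidationError


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Input roles (any may be None; stages without inputs are skipped):
    ``spectra`` is a list of spectra CSV paths (variant/direction read from
    their metadata lines), ``trajectories`` a list of
    ``{label, frames, exchange}`` path mappings, ``predictors`` and
    ``reference`` single TSV paths.
    """

    spectra: list = field(default_factory=list)
    trajectories: list = field(default_factory=list)
    predictors: Optional[str] = None
    reference: Optional[str] = None

    wt_label: str = "WT"
    thermal_channel: str = "peak_intensity"
    chemical_channel: str = "lambda_max"
    chemical_fit_temperature: float = ROOM_TEMPERATURE_K

    wham_bins: int = 200
    wham_tol: float = 1e-7
    wham_max_iter: int = 10000
    cv_grid_step: float = 0.5

    predictor_rule: str = "mean"             # mean | median | <tool name>
    # which dD1/2 feeds the chemical impact component:
    #   "wt_minus_mutant": D1/2,unf(WT) - D1/2,unf(mut), WT unfolding m-value
    #   "hysteresis": the per-variant unfolding-refolding gap
    cd_convention: str = "wt_minus_mutant"

    synthetic: bool = False
    synthetic_frames: int = 4000             # frames/replica for synthetic REX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.thermal_channel!r}")
        if self.chemical_channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.chemical_channel!r}")
        if self.cd_convention not in ("wt_minus_mutant", "hysteresis"):
            raise ValidationError(f"unknown cd_convention {self.cd_convention!r}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
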