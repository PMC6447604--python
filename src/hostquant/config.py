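"""Run configuration: instrument constants, thresholds, conversion constants."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .assays import DEFAULT_THRESHOLDS
from .droplet import DEFAULT_DROPLET_VOLUME_NL, DEFAULT_REACTION_VOLUME_UL, MIN_ACCEPTED_DROPLETS
from .stats import ConversionConstants


@dataclass
class RunConfig:
    """Everything the quantification pipeline needs beyond the input files.

    ``acn_ntc_override`` supplies an explicit NTC background (usually 0.0)
    for runs whose droplet file carries no NTC wells; without it such runs
    are an error.
    """

    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL
    min_accepted_droplets: int = MIN_ACCEPTED_DROPLETS
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    normalisation_mode: str = "literal"
    acn_ntc_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.droplet_volume_nl, self.reaction_volume_ul) <= 0:
            raise ValueError("volumes must be positive")
        if self.min_accepted_droplets <= 0:
            raise ValueError("droplet minimum must be positive")
        if self.normalisation_mode not in {"literal", "total"}:
            raise ValueError("normalisation mode must be 'literal' or 'total'")

    def threshold_for(self, assay_id: str) -> float:
        try:
            return self.thresholds[assay_id]
        except KeyError:
            raise KeyError(f"no amplitude threshold configured for assay {assay_id!r}") from None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            merged = dict(DEFAULT_THRESHOLDS)
            merged.update({k: float(v) for k, v in raw["thresholds"].items()})
            raw["thresholds"] = merged
        if "constants" in raw:
            raw["constants"] = ConversionConstants(**raw["constants"])
        return cls(**raw)
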