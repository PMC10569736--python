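"""Pipeline-wide configuration with serialization round trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import InvalidInputError


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline in one serializable object.

    ``thickness_nm`` is the capsid shell thickness used when no calibration
    anchor is given; ``distance_model`` feeds the MSA distance step; the ANI
    block follows the classic fragment scheme; ``min_length`` and
    ``retention`` are the triage and duplication thresholds; the species rule
    uses ``species_identity``/``species_coverage`` percent cutoffs.
    """

    seed: int = 0
    thickness_nm: float = 5.0
    distance_model: str = "uncorrected"
    ani_fragment_length: int = 1020
    ani_min_fragment_identity: float = 30.0
    ani_min_fragment_cover: float = 0.7
    min_length: int = 90_000
    retention: float = 0.5
    species_identity: float = 95.0
    species_coverage: float = 85.0
    output_dir: str = "."
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness_nm < 0:
            raise InvalidInputError("thickness_nm must be >= 0")
        if self.distance_model not in ("uncorrected", "jukes_cantor"):
            raise InvalidInputError(
                f"unknown distance_model {self.distance_model!r}"
            )
        if self.ani_fragment_length < 1:
            raise InvalidInputError("ani_fragment_length must be >= 1")
        if not 0 <= self.ani_min_fragment_cover <= 1:
            raise InvalidInputError("ani_min_fragment_cover must be in [0, 1]")
        for name in ("ani_min_fragment_identity", "species_identity",
                     "species_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InvalidInputError(f"{name} must be a percentage in [0, 100]")
        if not 0 <= self.retention <= 1:
            raise InvalidInputError("retention must be in [0, 1]")
        if self.min_length < 0:
            raise InvalidInputError("min_length must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
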