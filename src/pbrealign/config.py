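"""Pipeline configuration: every threshold in one place, nothing hard-coded.

Defaults are the method's published operating point: SCR/SVR split at a
3 A superposed CA-CA distance for runs of >= 3 columns, realignment of SVRs
whose shorter side has >= 4 PBs, and the inclusive -0.42 cutoff on the
normalised PB score separating conformationally similar from dissimilar.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    scr_max_dist: float = 3.0  # A
    svr_min_len: int = 3  # columns
    realign_min_pbs: int = 4  # shorter-side PB count ("more than three")
    pb_score_cutoff: float = -0.42  # normalised PB score, inclusive
    gap_open: float = -5.0
    gap_extend: float = -0.5
    fit_on: str = "all"  # "all" | "scr_iterative"
    pb_definitions: str | None = None  # path; bundled table when None
    substitution_matrix: str | None = None  # path; bundled synthetic matrix when None
    seed: int = 0

    def __post_init__(self):
        if self.scr_max_dist <= 0:
            raise ValueError("scr_max_dist must be positive")
        if self.svr_min_len < 1:
            raise ValueError("svr_min_len must be >= 1")
        if self.fit_on not in ("all", "scr_iterative"):
            raise ValueError("fit_on must be 'all' or 'scr_iterative'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        d = self.to_dict()
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**d)
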