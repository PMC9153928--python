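"""Pipeline configuration: a YAML-serializable record sufficient to
reproduce every output byte-for-byte."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .cohort import CONDITIONS, CohortDesign
from .specs import MODALITIES, default_spec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 31
    conditions: Tuple[str, ...] = CONDITIONS
    n_trials: int = 145
    target_count: Optional[int] = None
    lure_rate: float = 0.2
    rt_pool: str = "all"  # 'all' or 'hits_only'
    rank_ascending: bool = True
    outdir: str = "dualnback_out"

    def design(self) -> CohortDesign:
        # Preserve the default 40/145 target density when n_trials is scaled.
        specs = {}
        for m in MODALITIES:
            base = default_spec(m)
            max_targets = (
                base.max_targets
                if self.n_trials == base.n_trials
                else int(round(base.max_targets / base.n_trials * self.n_trials))
            )
            specs[m] = base.with_(
                n_trials=self.n_trials,
                lure_rate=self.lure_rate,
                max_targets=min(max_targets, self.n_trials - base.n_back),
            )
        return CohortDesign(
            n_subjects=self.n_subjects,
            conditions=tuple(self.conditions),
            blocks_per_session=len(self.conditions),
            block_specs=specs,
            target_count=self.target_count,
        )

    def to_yaml(self, path: Path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)
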