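"""YAML pipeline configuration."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sessionize import SegmentationParams
from .violations import DutyHourRules

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Paths, parameters, and policies for one pipeline run.

    Round-trips unchanged through YAML serialization; ``config_hash`` is a
    stable digest of the serialized form, logged with every run.
    """

    access_log: str = "access_log.csv"
    workstations: str = "workstations.csv"
    roster: str = "roster.csv"
    blocks: str = "blocks.csv"
    self_reports: str = "self_reports.csv"
    outdir: str = "out"
    reference_tz: str = "America/New_York"
    overlap_policy: str = "reject"
    seed: int = 0  # simulation stage only
    sim_profile: str = "study_scale"  # study_scale | minimal
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    rules: DutyHourRules = field(default_factory=DutyHourRules)

    def to_dict(self) -> dict:
        return {
            "access_log": self.access_log,
            "workstations": self.workstations,
            "roster": self.roster,
            "blocks": self.blocks,
            "self_reports": self.self_reports,
            "outdir": self.outdir,
            "reference_tz": self.reference_tz,
            "overlap_policy": self.overlap_policy,
            "seed": self.seed,
            "sim_profile": self.sim_profile,
            "segmentation": self.segmentation.to_dict(),
            "rules": self.rules.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        rules = d.pop("rules", {})
        return cls(
            segmentation=SegmentationParams.from_dict(seg) if seg else SegmentationParams(),
            rules=DutyHourRules.from_dict(rules) if rules else DutyHourRules(),
            **d,
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def resolve(self, name: str) -> Path:
        return Path(getattr(self, name))


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
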