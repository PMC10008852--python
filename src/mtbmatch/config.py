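"""Pipeline configuration: every tunable threshold in one place.

Defaults are the study's operating points: depth >= 8 reads, VAF >= 5%,
population AF < 0.001, CADD phred > 20 for strong deleteriousness,
TMB-high at >= 10 mut/Mb, BRCAness positivity at >= 20% SBS6 exposure,
a 30 Mb exome denominator, and m2B as the minimum evidence level
reported without a below-threshold tag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .evidence import EvidenceLevelNCT
from .variants import FilterConfig


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    tmb_high_cutoff: float = 10.0
    brcaness_cutoff: float = 0.20
    exome_size_mb: float = 30.0
    msi_threshold: float = 10.0
    min_report_level: EvidenceLevelNCT = EvidenceLevelNCT.m2B
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tmb_high_cutoff", "brcaness_cutoff",
                     "exome_size_mb", "msi_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "filter": {
                "min_total_reads": self.filter.min_total_reads,
                "min_vaf": self.filter.min_vaf,
                "max_pop_af": self.filter.max_pop_af,
                "cadd_deleterious_threshold":
                    self.filter.cadd_deleterious_threshold,
            },
            "tmb_high_cutoff": self.tmb_high_cutoff,
            "brcaness_cutoff": self.brcaness_cutoff,
            "exome_size_mb": self.exome_size_mb,
            "msi_threshold": self.msi_threshold,
            "min_report_level": self.min_report_level.value,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        filt = FilterConfig(**payload.get("filter", {}))
        kwargs = {k: v for k, v in payload.items() if k != "filter"}
        if "min_report_level" in kwargs:
            kwargs["min_report_level"] = EvidenceLevelNCT(
                kwargs["min_report_level"])
        return cls(filter=filt, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))
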