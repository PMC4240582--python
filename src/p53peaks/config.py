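"""Pipeline configuration: every numeric constant used by any stage.

Defaults follow the study design: 700 bp average chromatin fragments (350 nt
half-size drives all slop rules), a 99% dual-confidence requirement, the 75%
response-element score cutoff over 2 kb windows with a ±100 nt report radius,
10 kb TSS profile windows, and gene proximity from 20 kb upstream of the TSS
to 5 kb past the TES.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration value violates its contract."""


@dataclass
class PipelineConfig:
    fragment_size: int = 700
    tag_len: int = 36
    slop: int = 350
    hc_confidence: float = 0.99
    p53mh_min_percent: float = 75.0
    p53mh_window: int = 2000
    p53mh_report_radius: int = 100
    tss_window: int = 10_000
    tss_bin: int = 200
    upstream_limit: int = 20_000
    tes_downstream: int = 5_000
    merge_gap: int = 200
    poisson_q: float = 1e-4
    background_samples: int = 1000
    symmetric_max_offset: int = 100
    symmetric_max_height_ratio: float = 2.0
    density_bandwidth: float = 2e6
    density_grid: int = 100_000
    seed: int = 0
    gene_table_dialect: str = "zero_based"
    repeat_dialect: str = "bed"

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.hc_confidence <= 1.0):
            raise ConfigError(f"hc_confidence must be in (0, 1], got {self.hc_confidence}")
        if not (0.0 < self.p53mh_min_percent <= 100.0):
            raise ConfigError("p53mh_min_percent must be in (0, 100]")
        if not (0.0 < self.poisson_q < 1.0):
            raise ConfigError("poisson_q must be in (0, 1)")
        if self.fragment_size < self.tag_len:
            raise ConfigError("fragment_size must be >= tag_len")
        for name in (
            "slop",
            "p53mh_window",
            "p53mh_report_radius",
            "tss_window",
            "upstream_limit",
            "tes_downstream",
            "merge_gap",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.background_samples < 100:
            raise ConfigError("background_samples must be >= 100")
        if self.tss_window % 2:
            raise ConfigError("tss_window must be even")
        if self.gene_table_dialect not in ("zero_based", "one_based"):
            raise ConfigError(f"unknown gene_table_dialect {self.gene_table_dialect!r}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
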