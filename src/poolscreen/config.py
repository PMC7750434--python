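"""Run configuration: one structured document driving the whole pipeline.

YAML on disk, a dataclass in memory, echoed verbatim into every run manifest
for provenance.  Thresholds default to the screening cutoffs of the method
(95% identity / 1e-6 e-value for cross-pool matching, >1 kb for mining,
e < 1e-5 / >= 45 bp / >= 300 bp / 75% identity for 16S hits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class LayoutConfig:
    n_plates: int = 4
    plate_format: int = 96
    set_size: int = 10
    strategy: str = "direct384"


@dataclass
class SimulateConfig:
    mean_length: float = 6000.0
    dispersion: float = 0.35
    min_length: int | None = None
    max_length: int | None = None
    cassette_rate: float = 0.1
    coverage_per_pool: float = 60.0
    coverage_shape: float = 6.0
    c_star: float = 55.0
    plateau_len: float = 8000.0
    base_len: float = 300.0
    substitution_rate: float = 0.0
    min_fragment_len: int = 300
    contaminant_fraction: float = 0.0
    reads: bool = False
    read_depth: float = 10.0
    read_len: int = 150


@dataclass
class MatchConfig:
    k: int = 15
    min_identity: float = 95.0
    max_evalue: float = 1e-6
    min_aln_len: int = 100
    x_drop: float = 20.0


@dataclass
class ScreenConfig:
    min_contig_len: int = 1000
    s16_max_e: float = 1e-5
    s16_min_init_aln: int = 45
    s16_min_len: int = 300
    s16_phylum_identity: float = 75.0


@dataclass
class RunConfig:
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 17
    outdir: str = "poolscreen_run"

    def validate(self) -> None:
        if not 0 < self.match.min_identity <= 100:
            raise ConfigError("min_identity must be in (0, 100]")
        if self.match.max_evalue <= 0:
            raise ConfigError("max_evalue must be > 0")
        if self.screen.min_contig_len < 0:
            raise ConfigError("min_contig_len must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, key):
            return klass(**data.get(key, {}))

        cfg = cls(
            layout=build(LayoutConfig, "layout"),
            simulate=build(SimulateConfig, "simulate"),
            match=build(MatchConfig, "match"),
            screen=build(ScreenConfig, "screen"),
            seed=int(data.get("seed", 17)),
            outdir=str(data.get("outdir", "poolscreen_run")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
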