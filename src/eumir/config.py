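"""Pipeline configuration: per-stage parameter blocks, sample sheet, seed.

Every threshold the pipeline applies lives here with its documented
default; stages receive the relevant block and never read files
themselves.  Configurations load from / dump to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


@dataclass
class Sample:
    sample_id: str
    condition: str  # "LR" or "HR"
    replicate: int


def default_sample_sheet() -> list[Sample]:
    return [Sample(f"{c}{i:02d}", c, i) for c in ("LR", "HR") for i in (1, 2, 3)]


@dataclass
class SimulateConfig:
    """Study conditions emulated by the synthetic-data generator.

    Two leaf pools differing in trans-polyisoprene (Eu-rubber) content
    -- LR (1.39%) and HR (4.80%) -- with three biological replicates
    each; read counts are negative-binomial with condition-specific
    means, and the pooled read-length histogram peaks at 24 nt with
    21 nt second, as bulk plant sRNA libraries do.
    """

    n_transcripts: int = 60
    transcript_length: tuple[int, int] = (500, 1500)
    gc: float = 0.45
    n_mirnas: int = 20
    known_fraction: float = 0.4  # fraction matched by the miRBase-style set
    n_secondary_known: int = 2   # matched (exactly) by the published-set refs
    # mature length profile: 21 nt dominant, 24 nt second among miRNAs
    mature_length_dist: dict[int, float] = field(
        default_factory=lambda: {20: 0.10, 21: 0.50, 22: 0.10, 24: 0.30}
    )
    depth: int = 200_000          # reads per library
    dispersion: float = 0.1       # NB: var = mu + alpha * mu^2
    frac_dem: float = 0.3
    lfc_magnitude: float = 2.0
    background_ncrna_frac: float = 0.35  # rRNA/tRNA/... fragments, rRNA-heavy
    background_random_frac: float = 0.25  # heterochromatic-siRNA-like 24-mers
    frac_bad_n: float = 0.015     # reads with >=10% N
    frac_no_adapter: float = 0.01
    frac_bad_length: float = 0.01
    frac_low_quality: float = 0.01
    adapter: str = "AGATCGGAAGAGCACACGTC"
    site_spike_factor: float = 50.0
    background_rate: float = 0.02       # per-position coverage probability
    background_tag_mean: float = 2.0    # mean tag count at a covered position
    mrna_depth: int = 300_000
    frac_anti: float = 0.8        # targets regulated opposite to their DEM
    frac_extra_deg: float = 0.05  # DE transcripts that are not miRNA targets
    conditions: dict[str, float] = field(
        default_factory=lambda: {"LR": 1.39, "HR": 4.80}  # rubber content, %
    )

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if self.transcript_length[0] < 200:
            raise ConfigError("transcript length must be >= 200")
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError("gc must be in [0, 1]")
        if not 0.0 <= self.frac_dem <= 1.0:
            raise ConfigError("frac_dem must be in [0, 1]")
        if self.frac_dem > 0 and self.lfc_magnitude < 1.0:
            raise ConfigError("lfc_magnitude must be >= 1")
        if any(length < 18 or length > 25 for length in self.mature_length_dist):
            raise ConfigError("mature_length_dist must be supported on 18-25 nt")
        if self.site_spike_factor <= 1.0:
            raise ConfigError("site_spike_factor must be > 1")
        if not self.adapter:
            raise ConfigError("adapter must be non-empty")


@dataclass
class PreprocessConfig:
    min_len: int = 18
    max_len: int = 30
    max_n_frac: float = 0.10
    min_mean_q: float = 20.0
    min_candidate_count: int = 2  # pooled count for a read to enter discovery

    def validate(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ConfigError("need 0 < min_len <= max_len")
        if not 0.0 < self.max_n_frac <= 1.0:
            raise ConfigError("max_n_frac must be in (0, 1]")


@dataclass
class DiscoveryConfig:
    max_mm: int = 3        # mismatch cap vs the miRBase-style mature set
    max_shift: int = 2     # isomiR-style terminal offset allowance
    max_mm2: int = 0       # mismatch cap vs the secondary published set
    mfe_max: float = -15.8  # pseudo-MFE ceiling for novel precursors
    min_paired_frac: float = 0.6
    max_mature_bulge: int = 4
    min_hairpin_loop: int = 3

    def validate(self) -> None:
        if self.max_mm < 0 or self.max_mm2 < 0:
            raise ConfigError("mismatch caps must be non-negative")
        if self.mfe_max >= 0:
            raise ConfigError("mfe_max must be negative")
        if not 0.0 <= self.min_paired_frac <= 1.0:
            raise ConfigError("min_paired_frac must be in [0, 1]")


@dataclass
class ExpressionConfig:
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    dispersion_floor: float = 0.01
    pseudocount: float = 0.5

    def validate(self) -> None:
        if self.lfc_threshold < 0:
            raise ConfigError("lfc_threshold must be >= 0")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ConfigError("fdr_threshold must be in (0, 1]")


@dataclass
class TargetConfig:
    """Complementarity scoring emulating the default plant-target schema."""

    wc: float = 0.0
    wobble: float = 0.5
    mismatch: float = 1.0
    gap: float = 2.0
    seed_start: int = 2   # miRNA positions (1-based, from 5') with
    seed_end: int = 13    # penalties multiplied by seed_factor
    seed_factor: float = 1.5
    cutoff: float = 5.0
    max_gaps: int = 1

    def validate(self) -> None:
        if self.max_gaps not in (0, 1):
            raise ConfigError("max_gaps must be 0 or 1")
        if self.cutoff < 0:
            raise ConfigError("cutoff must be >= 0")


@dataclass
class DegradomeConfig:
    max_mm: float = 5.0       # mismatch budget for a cleavage alignment
    wobble_weight: float = 0.5  # G:U contribution toward the budget
    median_covered_only: bool = True

    def validate(self) -> None:
        if self.max_mm < 0:
            raise ConfigError("max_mm must be >= 0")


@dataclass
class EnrichmentConfig:
    p_threshold: float = 0.05
    method: str = "fdr_bh"  # or "bonferroni"

    def validate(self) -> None:
        if self.method not in ("fdr_bh", "bonferroni"):
            raise ConfigError("method must be fdr_bh or bonferroni")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ConfigError("p_threshold must be in (0, 1]")


@dataclass
class PipelineConfig:
    seed: int = 0
    samples: list[Sample] = field(default_factory=default_sample_sheet)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    degradome: DegradomeConfig = field(default_factory=DegradomeConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def validate(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("sample ids must be unique")
        for s in self.samples:
            if s.condition not in ("LR", "HR"):
                raise ConfigError(f"unknown condition {s.condition!r}")
        for block in (self.simulate, self.preprocess, self.discovery,
                      self.expression, self.targets, self.degradome,
                      self.enrichment):
            block.validate()

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["transcript_length"] = list(
            d["simulate"]["transcript_length"]
        )
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    cfg = PipelineConfig()
    if "seed" in data:
        cfg.seed = data.pop("seed")
    if "samples" in data:
        cfg.samples = [Sample(**s) for s in data.pop("samples")]
    blocks = {
        "simulate": SimulateConfig,
        "preprocess": PreprocessConfig,
        "discovery": DiscoveryConfig,
        "expression": ExpressionConfig,
        "targets": TargetConfig,
        "degradome": DegradomeConfig,
        "enrichment": EnrichmentConfig,
    }
    for name, cls in blocks.items():
        if name in data:
            block = data.pop(name)
            if name == "simulate" and "transcript_length" in block:
                block["transcript_length"] = tuple(block["transcript_length"])
            if name == "simulate" and "mature_length_dist" in block:
                block["mature_length_dist"] = {
                    int(k): float(v)
                    for k, v in block["mature_length_dist"].items()
                }
            setattr(cfg, name, _build(cls, block))
    if data:
        raise ConfigError(f"unknown config sections: {sorted(data)}")
    cfg.validate()
    return cfg


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load a YAML configuration; ``None`` gives the defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)
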