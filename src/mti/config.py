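"""Pipeline configuration: file paths plus every tunable, with validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Unknown key or out-of-range tunable in a pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths and tunables for one end-to-end run.

    Coverage inputs are a sample-name -> bedGraph-path map; the paired
    usage comparison takes the first two samples in order, and
    ``verdict_sample`` (default: the last sample) supplies the coverage
    used for expression verdicts on predicted sites.  ``polya``,
    ``transcripts`` and ``coverage`` may all be omitted, in which case
    the 3' UTR expression filter is skipped and every verdict stays
    UNSET ("unfiltered" mode).
    """

    utrs: str = ""
    mirnas: str = ""
    quant: str = ""
    control: str = ""
    mrna: str = ""
    polya: str = ""
    transcripts: str = ""
    coverage: dict[str, str] = field(default_factory=dict)
    verdict_sample: str = ""
    tf_lists: dict[str, str] = field(default_factory=dict)
    partition_tf: str = "MYC"
    outdir: str = "mti_run"

    bin_size: int = 300
    q_low: float = 0.005
    q_high: float = 0.995
    cutoff_override: float | None = None
    max_gap: int = 20
    window: int = 100
    min_sites: int = 2
    min_mean_cov: float = 10.0
    min_window_bases: int = 20
    mrna_threshold: float = -0.5
    theta_hi: float = 0.5
    theta_lo: float = 0.2
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        if not (0 < self.q_low <= self.q_high < 1):
            raise ConfigError("require 0 < q_low <= q_high < 1")
        if self.cutoff_override is not None and not self.cutoff_override > 0:
            raise ConfigError("cutoff_override must be positive")
        if self.max_gap < 0 or self.window < 1 or self.min_sites < 1:
            raise ConfigError("max_gap/window/min_sites out of range")
        if self.min_mean_cov < 0 or self.min_window_bases < 1:
            raise ConfigError("coverage filter parameters out of range")
        if not (0 < self.theta_lo <= self.theta_hi <= 1):
            raise ConfigError("require 0 < theta_lo <= theta_hi <= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected, not ignored."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )
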