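"""Pipeline configuration.

Every threshold used anywhere in the pipeline lives here with its
register-study default, so a run is fully described by one config object
(plus a seed). Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the phenotyping/QC/PRS/association pipeline.

    Defaults are the conventional register-study values: 120-day
    dispense gap, 42-day (6-week) adequacy, Ricopili-style QC cut-offs,
    the summary-statistic filters, 10% assumed TRD prevalence among MDD
    cases, and Bonferroni control over six comparisons.
    """

    # phenotyping
    gap_days: int = 120
    adequate_days: int = 42
    # sample QC
    sample_call_rate: float = 0.98
    fhet_bound: float = 0.20
    # variant QC
    variant_call_rate: float = 0.98
    hwe_p: float = 1e-6
    diff_call_rate: float = 0.01
    maf_min: float = 0.01
    # ancestry / relatedness
    pc_sd: float = 6.0
    n_pcs_flag: int = 2
    pi_hat: float = 0.2
    # summary-statistic filters
    sumstat_maf: float = 0.10
    sumstat_info: float = 0.90
    mhc_chrom: str = "6"
    mhc_start: int = 28_000_000
    mhc_end: int = 34_000_000
    # association
    k_prevalence: float = 0.10
    n_pcs_covar: int = 4
    alpha: float = 0.05
    m_comparisons: int = 6
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_days <= 0 or self.adequate_days <= 0:
            raise ValueError("gap_days and adequate_days must be positive")
        for name in ("sample_call_rate", "variant_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.k_prevalence < 1.0:
            raise ValueError("k_prevalence must be in (0, 1)")
        if self.m_comparisons <= 0:
            raise ValueError("m_comparisons must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
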