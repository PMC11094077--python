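"""Pipeline-wide default thresholds, collected in one overridable config.

Every named constant of the analysis lives here with its field-standard
default: the 95%/85% dereplication thresholds, the 90%/95% read-mapping
filter, the 5th/95th tpmean trim, the 70% (and relaxed 40%) breadth
presence rule, the 20%/600 bp hypervariable-region rule, the SNV filters
(QUAL > 30, AF > 1%, >= 4 reads) and 10X locus subsample, the resampling
sizes (1000 x 100 bootstrap, 999/1000 permutations, 10000 prevalence
bootstrap), the host-evidence tier tables with the >= 3 assignment gate,
and the 70/10 MAG-quality gate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # dereplication
    min_ani: float = 0.95
    min_cov: float = 0.85
    min_member_len: int = 1000
    # read-mapping filter
    min_read_fraction: float = 0.90
    min_read_identity: float = 0.95
    # abundance / presence
    tpmean_lower_pct: float = 0.05
    tpmean_upper_pct: float = 0.95
    min_breadth: float = 0.70
    relaxed_breadth: float = 0.40
    subsample_reads_n: int = 5_000_000
    # hypervariable regions
    hvr_frac_cutoff: float = 0.20
    hvr_min_len: int = 600
    hvr_top_n: int = 50
    # microdiversity
    snv_min_qual: float = 30.0
    snv_min_af: float = 0.01
    snv_min_alt_reads: int = 4
    pi_subsample_depth: int = 10
    pi_min_breadth: float = 0.70
    pi_min_mean_depth: float = 10.0
    n_boot: int = 1000
    boot_subsample: int = 100
    n_perm: int = 1000
    # ecology
    permanova_n_perm: int = 999
    prevalence_n_boot: int = 10_000
    # host prediction
    host_assignment_threshold: float = 3.0
    bin_min_completeness: float = 70.0
    bin_max_contamination: float = 10.0
    # global
    seed: int = 0

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced; each override is logged."""
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key, value in kwargs.items():
            default = getattr(self, key)
            if value != default:
                logger.info("config override: %s = %r (default %r)", key, value, default)
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/key-value config file over the defaults (None = defaults)."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg.override(**data)
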