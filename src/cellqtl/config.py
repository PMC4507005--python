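"""Pipeline configuration: defaults, YAML round trip, validation."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults follow the study design this pipeline reproduces: a 1 Mb cis
    window, FDR 5% (cis) / 1% (trans), 15 expression PCs as covariates,
    MAF >= 5%, imputation info >= 0.9, HWE exact-test thresholds of 1e-6
    for directly genotyped and 1e-3 for imputed variants, LD r^2 > 0.8 for
    trait-proxy tagging and r^2 < 0.2 for peak independence, detection
    P < 0.01 in > 5% of samples, consensus epigenetic features present in
    at least half of donors, and a 2-df chi-square for the ddPCR
    allele-specific binding test.
    """

    cis_window: int = 1_000_000
    cis_fdr: float = 0.05
    trans_fdr: float = 0.01
    n_pcs: int = 15
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    hwe_p_min_imputed: float = 1e-3
    info_min: float = 0.9
    max_missing: float = 0.05      # call-rate proxy; the source study gives none
    ld_proxy_r2: float = 0.8
    ld_independent_r2: float = 0.2
    detection_alpha: float = 0.01
    detection_min_frac: float = 0.05
    consensus_min_frac: float = 0.5
    outlier_sd: float = 3.0
    ddpcr_df: int = 2
    seed: int = 0

    _FRACTIONS = (
        "cis_fdr", "trans_fdr", "maf_min", "max_missing", "ld_proxy_r2",
        "ld_independent_r2", "detection_alpha", "detection_min_frac",
        "consensus_min_frac",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v!r} must lie in (0, 1)")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be non-negative")
        if self.ddpcr_df < 1:
            raise ValueError("ddpcr_df must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**data)
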