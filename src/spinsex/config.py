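"""Pipeline configuration.

Every threshold used anywhere in the pipeline lives here with its default,
so a run is fully described by one flat key:value config file (YAML mapping,
scalar values only). Defaults follow the published analysis where the
analysis states them (10% homozygosity rule, p-value tiers, neutral rate
6.5e-9/site/generation) and are documented per field otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # genotyping
    min_total_depth: int = 10          # reads; sites below are MISSING
    hom_fraction: float = 0.10         # minor fraction strictly below -> homozygous
    min_qual: float | None = None      # optional VCF QUAL filter, off by default

    # segregation
    require_complete: bool = True      # every progeny sample callable at a site
    min_per_sex: int = 4               # floor when require_complete is off

    # association (raw p, no multiple-testing correction)
    msy_p: float = 1e-60               # below: fully sex-linked (MSY)
    significant_p: float = 1e-10       # below: significant sex association
    weak_p: float = 1e-5               # at or below: weak / recent linkage

    # molecular evolution
    neutral_rate: float = 6.5e-9       # substitutions / site / generation
    generation_years: float = 1.0      # years per generation
    min_orf_len: int = 150             # nt, incl. the stop codon

    # expression
    rpkm_pseudocount: float = 0.01     # added before log2
    de_p_cutoff: float = 0.01
    de_min_length: int = 400           # nt; shorter unigenes excluded
    min_yx_snps: int = 2               # qualifying SNPs needed for a Y/X ratio

    def validate(self) -> "PipelineConfig":
        if not 0 < self.hom_fraction < 0.5:
            raise ValueError("hom_fraction must be in (0, 0.5)")
        if self.min_total_depth < 0:
            raise ValueError("min_total_depth must be non-negative")
        if not self.msy_p < self.significant_p < self.weak_p:
            raise ValueError("p-value tiers must be ordered msy < significant < weak")
        if self.neutral_rate <= 0:
            raise ValueError("neutral_rate must be positive")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key: value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
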