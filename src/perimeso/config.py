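"""Run configuration: one serializable object holding every threshold of the
pipeline, with the published analysis values as defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import CohortConfig
from .variants import VariantConfig


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    variants: VariantConfig = field(default_factory=VariantConfig)
    # copy-number stage
    segment_penalty: float | None = None  # None -> gamma * sd^2 * log(n)
    segment_gamma: float = 40.0
    logr_threshold: float = 0.25
    baf_threshold: float = 0.55
    cytoband_fraction: float = 0.75
    min_segment_size: int = 1_000_000
    min_recurrent_band_samples: int = 3
    center_logr: bool = True
    # integration stage
    target_gene: str = "BAP1"
    purity_assumption: float = 0.7
    subclonal_af_factor: float = 0.5
    subclonal_logr_factor: float = 0.5
    whole_chromosome_fraction: float = 0.95
    min_recurrent_gene_samples: int = 2

    def validate(self) -> None:
        def positive(name, value):
            if value is None:
                return
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")

        def fraction(name, value):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1] (got {value})")

        if self.seed < 0:
            raise ValueError(f"seed must be >= 0 (got {self.seed})")
        positive("segment_penalty", self.segment_penalty)
        positive("segment_gamma", self.segment_gamma)
        positive("logr_threshold", self.logr_threshold)
        positive("min_segment_size", self.min_segment_size)
        fraction("baf_threshold", self.baf_threshold)
        fraction("cytoband_fraction", self.cytoband_fraction)
        fraction("subclonal_af_factor", self.subclonal_af_factor)
        fraction("subclonal_logr_factor", self.subclonal_logr_factor)
        fraction("whole_chromosome_fraction", self.whole_chromosome_fraction)
        fraction("purity_assumption", self.purity_assumption)
        v = self.variants
        if v.min_coverage < 0:
            raise ValueError(f"min_coverage must be >= 0 (got {v.min_coverage})")
        fraction("min_vaf", v.min_vaf)
        positive("min_avg_qual", v.min_avg_qual)
        fraction("somatic_alpha", v.somatic_alpha)
        lo, hi = v.het_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"het_band must satisfy 0 <= lo < hi <= 1 "
                             f"(got {v.het_band})")
        c = self.cohort
        fraction("cohort.purity", c.purity)
        positive("cohort.mean_depth", c.mean_depth)
        positive("cohort.probe_spacing", c.probe_spacing)
        if c.noise_sd < 0:
            raise ValueError(f"cohort.noise_sd must be >= 0 (got {c.noise_sd})")
        fraction("cohort.error_rate", c.error_rate)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        variants = d.pop("variants", {})
        cfg = cls(**d)
        if cohort:
            cohort = dict(cohort)
            if "named_genes" in cohort:
                cohort.pop("named_genes", None)
            cfg.cohort = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cohort.items()})
        if variants:
            cfg.variants = VariantConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in variants.items()})
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls.from_dict(data)
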