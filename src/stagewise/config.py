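"""Pipeline configuration: every scalar threshold of the workflow."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Scalar thresholds and seeds governing the whole pipeline.

    Defaults follow the published workflow: expressed at >= 1 rpmqn in all
    replicates of a stage; DE requires >= 2 rpmqn in the higher stage, a
    two-fold change, replicate SD <= 25 % of the stage mean, and BH FDR 5 %;
    k-means with k = 12; bootstrap enrichment with one million runs, a
    minimum of 5 set members per term and FDR 5 %; sRNA reads longer than
    15 nt retained, DE window 18-28 nt.
    """

    expressed_min_rpmqn: float = 1.0
    de_min_rpmqn: float = 2.0
    de_min_fold: float = 2.0
    de_max_cv: float = 0.25
    de_fdr_alpha: float = 0.05
    kmeans_k: int = 12
    kmeans_restarts: int = 20
    boot_runs: int = 1_000_000
    enrich_min_count: int = 5
    enrich_fdr_alpha: float = 0.05
    srna_min_len: int = 18
    srna_max_len: int = 28
    srna_retain_gt_len: int = 15
    target_corr_max: float = -0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "expressed_min_rpmqn",
            "de_min_rpmqn",
            "de_min_fold",
            "de_max_cv",
            "de_fdr_alpha",
            "kmeans_k",
            "kmeans_restarts",
            "enrich_min_count",
            "enrich_fdr_alpha",
            "srna_min_len",
            "srna_max_len",
            "srna_retain_gt_len",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")
        if not (-1.0 <= self.target_corr_max < 0.0):
            raise ValueError("target_corr_max must lie in [-1, 0)")
        if self.srna_min_len > self.srna_max_len:
            raise ValueError("srna_min_len must be <= srna_max_len")
        if self.boot_runs < 1:
            raise ValueError("boot_runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key: value YAML file; unknown keys are an error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} is not a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
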