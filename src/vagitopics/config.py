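"""Declarative analysis configuration (YAML key: value), CLI-overridable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class AnalysisConfig:
    """All tunable thresholds and stage toggles of the pipeline.

    Defaults are the study settings: 1000-read sample inclusion, the
    (2 reads, 10% prevalence) taxon filter, species-level agglomeration,
    five initial community state types, four topics.
    """

    min_sample_reads: int = 1000
    taxon_min_count: int = 2
    taxon_min_prevalence: float = 0.10
    agglomeration_rank: str = "species"
    pseudocount: float = 1.0
    seed: int = 0

    n_cmt: int = 5
    cmt_alpha: float = 0.05
    cmt_linkage: str = "complete"

    n_topics: int = 4
    select_k: bool = False
    k_min: int = 1
    k_max: int = 8

    rf_rounds: int = 200
    rf_trees: int = 200
    n_train: int = 69
    n_test: int = 30

    counts_path: str | None = None
    metadata_path: str | None = None
    simulate: bool = True

    stages: dict = field(default_factory=lambda: {
        "filter": True, "diversity": True, "cmt": True, "topics": True,
        "diff_abundance": True, "associations": True, "prediction": True,
    })

    def __post_init__(self):
        if not (0 < self.taxon_min_prevalence <= 1):
            raise ValueError("taxon_min_prevalence must be in (0, 1]")
        if self.min_sample_reads < 0:
            raise ValueError("min_sample_reads must be >= 0")
        if self.agglomeration_rank not in ("genus", "species"):
            raise ValueError("agglomeration_rank must be genus or species")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
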