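"""Pipeline configuration and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Library
from .orient import AnnealSchedule

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the scaffolding pipeline.

    ``min_links`` (W) is the minimum number of mate pairs that must join two
    contigs for the edge to count; ``min_length`` (L) the minimum contig
    length admitted to scaffolding.  The defaults are working values for a
    bacterial SOLiD mate-pair assembly.  Runs with the same config, inputs
    and seed are reproducible.
    """

    libraries: list[Library] = field(default_factory=list)
    min_links: int = 5  # W
    min_length: int = 150  # L
    majority_fraction: float = 0.7
    self_consistency: bool = False
    self_consistency_max_violations: int = 5
    split_chimeric: bool = False
    split_min_span: int = 3
    mean_cov_factor: float = 2.5
    local_cov_factor: float = 3.0
    coverage_window: int = 100
    delta_threshold_k: float = 5.0  # spring residual cutoff, in sd units
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    layer_cap: int = 6
    density_window: int = 1000
    small_gap: int = 10
    min_join_identity: float = 0.90
    max_iterations: int = 100
    max_segmentation_rounds: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.min_links < 1:
            raise ValueError("min_links (W) must be >= 1")
        if self.min_length < 0:
            raise ValueError("min_length (L) must be >= 0")
        if not (0.5 < self.majority_fraction <= 1.0):
            raise ValueError("majority_fraction must lie in (0.5, 1]")
        for name in (
            "mean_cov_factor",
            "local_cov_factor",
            "delta_threshold_k",
            "coverage_window",
            "density_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")

    def library(self, name: str) -> Library:
        for lib in self.libraries:
            if lib.name == name:
                return lib
        raise KeyError(f"unknown library id {name!r}")
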