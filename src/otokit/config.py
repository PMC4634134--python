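"""Pipeline configuration.

All stage parameters that carry scientific meaning live here with their
defaults: the 1 nTPM limit of detection, the coefficient-of-variation and
minimum-detected-cell gene filters, the FDR level, the Jensen-Shannon
specificity threshold, the detection-fraction marker filter, the number of
gap-statistic reference draws, the magnitude of the noise injected before
likelihood-ratio testing, and the master seed for every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    lod: float = 1.0                     # nTPM below which a value is "undetected"
    cv_min: float = 0.5                  # minimum cell-to-cell CV for a clustering gene
    min_cells_expressed: int = 2         # "two or fewer cells" detection filter
    fdr_alpha: float = 0.05              # Benjamini-Hochberg FDR level
    specificity_threshold: float = 0.5   # 0.5 or 0.6 depending on the comparison
    detection_fraction: float = 0.5      # marker must be above LOD in this fraction
    gap_B: int = 100                     # gap-statistic Monte Carlo reference draws
    noise_sd: float = 0.01               # log2-scale jitter injected before LRT
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.detection_fraction <= 1):
            raise ValueError("detection_fraction must be in (0, 1]")
        if not (0 <= self.specificity_threshold <= 1):
            raise ValueError("specificity_threshold must be in [0, 1]")
        if self.gap_B < 1:
            raise ValueError("gap_B must be >= 1")
        if self.lod <= 0:
            raise ValueError("lod must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_run_report(path, stage: str, config: PipelineConfig | None = None,
                     seed: int | None = None, **extras) -> None:
    """Write the JSON run report logged next to every pipeline output."""
    from . import __version__

    report = {"stage": stage, "version": __version__}
    if config is not None:
        report["config"] = config.to_dict()
    if seed is not None:
        report["seed"] = seed
    report.update(extras)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=str) + "\n")
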