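"""Pipeline configuration: generator parameters, thresholds, model options."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """One document holding every tunable of the pipeline.

    Thresholds mirror the study rules (20 mm distance exclusion, 0.3 mm RMD
    QC, FDR level 0.05); generator parameters are the desk-scale defaults
    of the synthetic cohort.
    """

    # network construction / QC
    min_dist_mm: float = 20.0
    rmd_threshold_mm: float = 0.3
    fisher_z: bool = False  # optional Fisher z-transform of correlations
    # statistical model
    model: str = "model1"
    fdr_q: float = 0.05
    reml: bool = True
    # synthetic cohort
    n_nodes: int = 80
    n_dmn: int = 20
    n_per_group: int = 15
    box_mm: float = 160.0
    dmn_spread_mm: float = 40.0
    lambda_mm: float = 60.0
    dmn_increment: float = 0.15
    baseline_shift: float = 0.2
    hub_sd: float = 0.30
    noise_sd: float = 0.05
    sigma_e: float = 0.05
    sigma_b: float = 0.02
    # reporting
    globalT_eval: tuple[float, float] = (38.0, 60.0)
    retain_fraction: float = 0.15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "globalT_eval" in data:
            data["globalT_eval"] = tuple(data["globalT_eval"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["globalT_eval"] = list(data["globalT_eval"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
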