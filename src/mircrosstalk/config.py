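"""Run configuration: validated paths, parameters and seeds for the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .crosstalk_network import COREG_MODES, DEFAULT_THRESHOLD


@dataclass
class RunConfig:
    out_dir: str
    mirna_fasta: Optional[str] = None
    transcript_fasta: Optional[str] = None
    vcf: Optional[str] = None
    ortho_tsv: Optional[str] = None
    family_tsv: Optional[str] = None
    blast_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    stress_tsv: Optional[str] = None
    climate_csv: Optional[str] = None
    coreg_threshold: float = DEFAULT_THRESHOLD
    coreg_mode: str = "extended"
    topology_percentile: float = 0.15
    n_reps: int = 1000
    seed: int = 0
    remove_singletons: bool = True

    def __post_init__(self):
        if not 0 <= self.coreg_threshold <= 1:
            raise ValueError("coreg_threshold must lie in [0, 1]")
        if self.coreg_mode not in COREG_MODES:
            raise ValueError(f"coreg_mode must be one of {COREG_MODES}")
        if not 0 < self.topology_percentile <= 1:
            raise ValueError("topology_percentile must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("mirna_fasta", "transcript_fasta", "vcf"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
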