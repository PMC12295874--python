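"""Pipeline configuration: every threshold the analyses use, with defaults
matching the study settings, serializable to/from JSON and overridable from
CLI flags one-to-one."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .mcfs import MCFSParams


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and sizes for a full pipeline run.

    Defaults reproduce the study settings: splitSetSize 200 / mode 2 /
    20 cutoff permutations for feature selection; methylation log2FC cut 1.0
    and miRNA down-expression cut -0.5; cis screen |rho| >= 0.6 with FDR 0.05
    inside +/- 1 Mbp of the TSS; miRNA screen rho <= -0.2; 41-bp motif
    windows with scan p <= 1e-4 and enrichment p <= 1e-3; well-predicted
    gate Pearson >= 0.8; best-fitted linear models adjusted p <= 0.05 and
    R-squared > 0.5; 1000 chromatin-state draws and 100 survival bootstrap
    rounds.
    """

    seed: int = 0
    mcfs: MCFSParams = dataclasses.field(default_factory=MCFSParams)
    meth_log2fc: float = 1.0
    mirna_down_log2fc: float = -0.5
    cis_rho: float = 0.6
    cis_q: float = 0.05
    cis_window: int = 1_000_000
    mirna_rho: float = -0.2
    mirna_q: float = 0.05
    promoter_flank: int = 2000
    cpg_flank: int = 2000
    motif_flank: int = 20           # 41-bp windows
    scan_p: float = 1e-4
    enrich_p: float = 1e-3
    pearson_gate: float = 0.8
    model_q: float = 0.05
    model_r2: float = 0.5
    n_state_draws: int = 1000
    n_survival_boot: int = 100
    survival_alpha: float = 0.05

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        mcfs = d.pop("mcfs", {})
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.mcfs = MCFSParams(**mcfs)
        return cfg

    def override(self, **kwargs) -> "PipelineConfig":
        mcfs_kw = {k[5:]: v for k, v in kwargs.items()
                   if k.startswith("mcfs_") and v is not None}
        own = {k: v for k, v in kwargs.items()
               if not k.startswith("mcfs_") and v is not None}
        cfg = dataclasses.replace(self, **own)
        if mcfs_kw:
            cfg.mcfs = dataclasses.replace(self.mcfs, **mcfs_kw)
        return cfg
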