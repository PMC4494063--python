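"""Run configuration: YAML-backed parameter sets with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .gene_caller import CallerParams
from .simulate import SimParams


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Unknown keys in a config file are rejected rather than ignored, so
    typos cannot silently fall back to defaults.
    """

    out_dir: str = "nucmorph_out"
    seed: int = 0
    verbosity: int = 1
    # gene caller
    min_protein_aa: int = 50
    intron_min: int = 18
    intron_max: int = 23
    max_introns_per_gene: int = 12
    require_atg: bool = True
    donor_consensus: str = "GTAAG"
    # homology / synteny
    evalue_cutoff: float = 0.001
    missing_gene_evalue: float = 1e-5
    min_block_genes: int = 4
    max_block_gap: int = 3
    # repeats
    min_dup_len: int = 1000
    telomere_max_motif: int = 10
    telomere_min_copies: int = 3
    subtelomere_search_depth: int = 50_000
    subtelomere_min_unit: int = 100
    # simulation
    sim: dict[str, Any] = field(default_factory=dict)

    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_protein_aa=self.min_protein_aa,
            intron_min=self.intron_min,
            intron_max=self.intron_max,
            max_introns_per_gene=self.max_introns_per_gene,
            require_atg=self.require_atg,
            donor_consensus=self.donor_consensus,
        )

    def sim_params(self) -> SimParams:
        known = {f.name for f in fields(SimParams)}
        unknown = set(self.sim) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        return SimParams(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
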