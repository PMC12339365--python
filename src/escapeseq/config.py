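"""Run configuration: a validated YAML schema shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .escore import COMBINATORIAL_THRESHOLD, SINGLE_THRESHOLD


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "escapeseq_run"
    seed: int = 0
    mode: str = "combinatorial"            # single | combinatorial
    # synthetic screen geometry
    n_peptides: int = 200
    n_alleles: int = 10
    replicates: int = 2
    peptide_length: int = 9
    # sorter / sequencing model
    sigma_log10: float = 0.12
    cells_per_construct: int = 1500
    reads_per_bin: int | None = None
    recombination_rate: float = 0.0
    binder_fraction: float = 0.10
    # scoring
    threshold: float | None = None          # None -> mode default (3.2 / 3.8)
    weights: tuple = (0.0, 2.0, 4.0, 8.0)
    align: bool = True
    min_trimers: int = 50
    # benchmarking
    bootstrap_B: int = 1000
    # anchors (peptide_flank5, peptide_flank3, barcode_flank5, barcode_flank3)
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("single", "combinatorial"):
            raise ConfigError(f"mode must be single|combinatorial, got {self.mode!r}")
        if self.n_peptides <= 0 or self.n_alleles <= 0 or self.replicates < 1:
            raise ConfigError("screen geometry must be positive")
        if not 8 <= self.peptide_length <= 12:
            raise ConfigError("peptide length must lie in 8..12")
        if not 0 <= self.recombination_rate <= 1:
            raise ConfigError("recombination_rate must lie in [0, 1]")
        w = list(self.weights)
        if len(w) != 4 or any(b <= a for a, b in zip(w, w[1:])):
            raise ConfigError("weights must be 4 strictly increasing numbers")
        if self.threshold is not None and not 0 < self.threshold < 8:
            raise ConfigError("threshold must lie in (0, 8)")
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be >= 1")

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return (SINGLE_THRESHOLD if self.mode == "single"
                else COMBINATORIAL_THRESHOLD)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "weights" in raw:
            raw["weights"] = tuple(raw["weights"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["weights"] = list(d["weights"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
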