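"""Analysis configuration.

Every tunable threshold of the pipeline lives in :class:`AnalysisConfig` so
that a run is fully described by (inputs, config, seed).  Defaults follow the
conventions of barcoded transposon (RB-TnSeq / BarSeq) fitness analysis:
0.2 for the essentiality cutoffs on median-scaled insertion statistics,
|f| > 0.5 and |t| > 4 for a significant phenotype, |f| > 1 and |t| > 5 plus
a 95th-percentile margin for a specific phenotype, and r >= 0.8 for high
cofitness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any, Mapping


class ValidationError(ValueError):
    """Raised when an input table, coordinate or configuration is invalid."""


@dataclass(frozen=True)
class AnalysisConfig:
    # strain/gene fitness
    pseudocount: float = 1.0          # added to every count before log ratios
    min_t0_reads: int = 3             # Time0 reads for a strain to be usable
    min_gene_t0_reads: int = 30       # summed Time0 reads for a gene to get fitness
    central_lo: float = 0.1           # central-insertion window (fraction of gene)
    central_hi: float = 0.9

    # positional normalization
    window: int = 251                 # running-median window, in genes; must be odd
    min_replicon_genes: int = 100     # smaller replicons use a plain median
    mode_grid_step: float = 0.01
    mode_pad: float = 0.5

    # t statistic
    sigma0: float = 0.1               # variance floor, log2 units

    # essentiality
    essentiality_threshold: float = 0.2
    min_nonrepetitive_nt: int = 100
    gc_bin_width: float = 0.05
    gc_min_bin_genes: int = 10
    dispensable_min_positions: int = 10
    dispensable_min_reads: int = 100
    dispensable_ignore_reads: int = 1  # central positions with <= this many reads are ignored

    # significant phenotypes
    sig_min_abs_f: float = 0.5
    sig_min_abs_t: float = 4.0

    # specific phenotypes
    specific_min_abs_f: float = 1.0
    specific_min_abs_t: float = 5.0
    specific_quiet_fraction: float = 0.95  # fraction of experiments with |f| < 1
    specific_margin: float = 0.5           # |f| must exceed pct95(|f|) by this much
    specific_min_experiments: int = 20

    # cofitness
    cofit_threshold: float = 0.8
    cofit_min_overlap: int = 50

    # per-experiment quality control
    qc_min_gmed: float = 50.0
    qc_min_cor12: float = 0.5
    qc_max_mad12: float = 0.5

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValidationError(f"running-median window must be odd, got {self.window}")
        for name in (
            "pseudocount", "window", "sigma0", "essentiality_threshold",
            "sig_min_abs_f", "sig_min_abs_t", "specific_min_abs_f",
            "specific_min_abs_t", "specific_margin", "cofit_threshold",
            "mode_grid_step",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name!r} must be positive")
        if not 0.0 <= self.central_lo < self.central_hi <= 1.0:
            raise ValidationError("central window must satisfy 0 <= lo < hi <= 1")
        if not 0.0 < self.specific_quiet_fraction <= 1.0:
            raise ValidationError("specific_quiet_fraction must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_json(cls, path: str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_CONFIG = AnalysisConfig()
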