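"""Run configuration: every pipeline threshold in one place.

Defaults are the calling thresholds the method was designed with: 40x
coverage, Phred 30 base quality, minor-allele count 6, splice distance
7 bp, binomial error rate 0.001 at level 1e-4, VAF lower-tail level 0.05,
bias-test level 0.05, homopolymer runs of 7 within 20 bp, 4% recurrence,
1.5 IQR over 4 depth groups and 10 CV folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RunConfig:
    # candidate selection
    min_coverage: int = 40
    min_base_phred: int = 30
    min_minor_count: int = 6
    # artifact filters
    splice_min_distance: int = 7
    seq_error_p: float = 0.001
    seq_error_alpha: float = 1e-4
    vaf_alpha: float = 0.05
    bias_alpha: float = 0.05
    polyrun_length: int = 7
    polyrun_window: int = 20
    recurrence_fraction: float = 0.04
    iqr_k: float = 1.5
    n_depth_groups: int = 4
    # modeling
    cv_folds: int = 10
    # synthetic-data generation
    n_chrom: int = 2
    n_genes: int = 20
    n_accessions: int = 50
    seed: int = 0
    simulate_params: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
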