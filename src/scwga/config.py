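"""Run configuration with the pipeline's standard constants.

Defaults: 100 kb depth windows, 10,000 genome bins, 1 Mb minimum CNV length,
100 bp chimera-matching threshold, 3e9 genotypable genome sites, GC strata
cutoffs 0.50/0.35, segmentation significance 0.01.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    window_width: int = 100_000
    n_bins: int = 10_000
    cnv_min_length: int = 1_000_000
    chimera_threshold: int = 100
    genome_sites: int = 3_000_000_000
    gc_high_cutoff: float = 0.50
    gc_low_cutoff: float = 0.35
    alpha: float = 0.01
    paths: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
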