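"""Analysis configuration.

All numeric knobs of the pipeline live in a single :class:`AnalysisConfig`
so that a run is fully described by (inputs, config, seed).  The defaults
are the values used throughout the receptor-architecture literature this
package implements: LRR motifs closer than 13 residues belong to one
LRR-region, inter-region gaps of 15-29 residues are N-loopout (NL)
candidates and gaps of 30-90 residues are island-domain (ID) candidates,
LRR-kinase candidates must be at least 250 residues long (150 for all other
proteins), cophenetic distances below 0.2 substitutions/site define network
edges, and Pearson r thresholds 0.6/0.3 separate strong/medium co-expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml


@dataclass
class AnalysisConfig:
    # LRR-architecture parsing
    merge_lt: int = 13            # motifs < this many residues apart share a region
    nl_range: Tuple[int, int] = (15, 29)   # N-loopout gap length, inclusive
    id_range: Tuple[int, int] = (30, 90)   # island-domain gap length, inclusive
    id4_n2: int = 4               # motifs after the ID for the ID+4LRR flag
    id4_le: bool = False          # compare n2 with <= instead of ==
    include_terminal_gaps: bool = False    # also call gaps flanking first/last motif
    cjm_mode: str = "kd_start"    # cJM of RLKs ends at KD start - 1

    # length pre-filters
    min_len_other: int = 150
    min_len_lrr_rlk: int = 250

    # built-in detector stand-ins
    tm_window: int = 19
    tm_threshold: float = 1.6     # mean Kyte-Doolittle hydropathy
    tm_min_len: int = 15
    tm_max_len: int = 35
    tm_trim_len: int = 21
    sp_threshold: float = 2.0     # mean hydropathy of signal-peptide run
    sp_min_len: int = 7
    sp_max_len: int = 15
    sp_start_within: int = 10     # run must begin within the first N residues

    # juxtamembrane charge
    charge_window: int = 10       # residues of eJM counted as "terminal"

    # evolutionary statistics
    r_strong: float = 0.6
    r_medium: float = 0.3
    n_perm: int = 10_000
    mantel_alternative: str = "greater"

    # tree clustering
    cophenetic_cutoff: float = 0.2
    similarity_mode: str = "scaled"   # weight = 1 - d/cutoff ("linear": 1 - d)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.nl_range[0] > self.nl_range[1] or self.id_range[0] > self.id_range[1]:
            raise ValueError("gap ranges must be (lo, hi) with lo <= hi")
        if self.nl_range[1] >= self.id_range[0]:
            raise ValueError("NL range must lie strictly below the ID range")
        if self.id4_n2 < 1:
            raise ValueError("id4_n2 must be >= 1")
        if self.cophenetic_cutoff <= 0:
            raise ValueError("cophenetic_cutoff must be positive")
        if not (0 < self.r_medium < self.r_strong < 1):
            raise ValueError("require 0 < r_medium < r_strong < 1")
        if self.tm_window < 7 or self.tm_window % 2 == 0:
            raise ValueError("tm_window must be odd and >= 7")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nl_range"] = list(self.nl_range)
        d["id_range"] = list(self.id_range)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("nl_range", "id_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
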