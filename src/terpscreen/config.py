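"""Run configuration: one flat, strictly-validated mapping of every tunable.

Unknown keys are rejected so a typo in a YAML file cannot silently fall back
to a default, and every resolved value is written into the run log by the CLI
so reports stay auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .identify import DEFAULT_MIN_SI, DEFAULT_RI_WINDOW
from .screen import DEFAULT_NSE_DTE_PATTERN, DEFAULT_SEARCH_REGION

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # global
    seed: int = 0
    log_level: str = "INFO"

    # identification thresholds
    ri_window: float = DEFAULT_RI_WINDOW
    min_si: float = DEFAULT_MIN_SI

    # motif screen
    search_region: tuple[int, int] = DEFAULT_SEARCH_REGION
    nse_dte_pattern: str = DEFAULT_NSE_DTE_PATTERN
    require_motif_order: bool = True

    # alignment scoring
    align_match: int = 1
    align_mismatch: int = 0
    align_gap: int = -1

    # synthetic library / spectra
    n_compounds: int = 50
    n_peaks: int = 25
    mz_low: int = 41
    mz_high: int = 220
    decay_rate: float = 0.15
    ri_low: float = 1300.0
    ri_high: float = 1670.0

    # measurement noise
    intensity_cv: float = 0.05
    dropout_p: float = 0.02
    contaminant_rate: float = 1.0

    # alkane ladder
    ladder_c_min: int = 8
    ladder_c_max: int = 30
    ladder_t0: float = 8.0
    ladder_spacing: float = 3.2
    ladder_curvature: float = 0.0

    # enzymes / queries
    n_enzymes: int = 20

    # candidate genes
    n_candidates: int = 86
    n_no_start: int = 4

    # motif fixture
    n_motif_pos: int = 20
    n_motif_neg: int = 10
    n_motif_noncanonical: int = 2
    protein_length: int = 350

    # clade fixture
    n_clades: int = 5
    refs_per_clade: int = 4
    within_divergence: float = 0.05
    between_divergence: float = 0.4
    n_clade_queries: int = 10
    n_orphans: int = 1
    clade_seq_length: int = 250

    def __post_init__(self) -> None:
        if not (0 <= self.min_si <= 100):
            raise ValueError("min_si must lie in [0, 100]")
        if self.ri_window < 0:
            raise ValueError("ri_window must be >= 0")
        lo, hi = self.search_region
        if not (1 <= lo <= hi):
            raise ValueError("search_region must be a 1-based (low, high) span")
        if not (0 <= self.n_no_start <= self.n_candidates):
            raise ValueError("need 0 <= n_no_start <= n_candidates")

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "search_region" in data:
            data = dict(data)
            data["search_region"] = tuple(data["search_region"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["search_region"] = list(d["search_region"])
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a YAML file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_mapping(data)
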