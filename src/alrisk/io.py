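"""Cohort CSV I/O and analysis configuration files.

Cohort CSV schema (header, exact names): patient_id, seq, sex, age_years,
bmi, asa, stage, tumor_size_cm, location, op_time_min, transfusion,
neoadjuvant_crt, stapler_firings, leak. sex in {F,M}, location in
{upper,mid,low}, binaries in {0,1}, seq 1-based and contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import COLUMNS, Cohort
from .errors import ConfigurationError, DataError


def load_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read and validate a cohort CSV; records come back seq-sorted."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"could not parse {path}: {exc}") from exc
    return Cohort.from_frame(df, provenance=str(path), strict=strict)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.df.loc[:, COLUMNS].to_csv(path, index=False)
    return path


@dataclass
class AnalysisConfig:
    """End-to-end run settings (defaults mirror the published analysis)."""

    input_path: str | None = None     # None -> generate a synthetic cohort
    n_patients: int = 736
    entry_alpha: float = 0.10
    stay_alpha: float = 0.05
    n_boot: int = 240
    seed: int = 0
    calibration_bins: int = 10
    max_segments: int = 5
    min_segment_len: int = 30
    era_starts: tuple = (155, 397, 480, 584)
    era_labels: tuple = ("A", "B", "C", "D")  # glue, sutures, extended SFM, transanal tube
    output_dir: str = "alrisk_out"

    def validate(self) -> None:
        for name in ("entry_alpha", "stay_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1); got {v}")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if len(self.era_starts) != len(self.era_labels):
            raise ConfigurationError("era_starts and era_labels must have equal length")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(bad))}")
        for key in ("era_starts", "era_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
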