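"""End-to-end analysis: screen -> stepwise fit -> nomogram -> internal
validation -> calibration -> RA-CUSUM -> change-points -> era annotation.

Every stage consumes the same cohort snapshot and a single seed, so a run
is fully deterministic: re-running with the same config writes
byte-identical artifacts. Run metadata records package/library versions,
the seed and a config digest (no wall-clock time, precisely so that
determinism holds at the byte level).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .cusum import ChangePointSet, CusumTrace, annotate_eras, detect_changepoints, ra_cusum_trace, segment_summary
from .io import AnalysisConfig, load_cohort, write_cohort
from .logistic import LogisticFit, ModelSpec, backward_stepwise, multivariate_table, predict_risk
from .nomogram import NomogramSpec, build_nomogram, tabulate_axes
from .screening import DEFAULT_CANDIDATES, screen_variables, univariate_table
from .simulate import default_config, generate_cohort
from .validation import ValidationReport, bootstrap_validate, calibration_table

log = logging.getLogger("alrisk")


@dataclass
class AnalysisBundle:
    cohort: Cohort
    univariate: pd.DataFrame
    screened: list
    fit: LogisticFit
    nomogram: NomogramSpec
    validation: ValidationReport
    calibration: pd.DataFrame
    trace: CusumTrace
    changepoints: ChangePointSet
    segments: pd.DataFrame
    config: AnalysisConfig
    metadata: dict


def _obtain_cohort(config: AnalysisConfig) -> Cohort:
    if config.input_path is not None:
        cohort = load_cohort(config.input_path)
        log.info("loaded cohort: %d records from %s", len(cohort), config.input_path)
        return cohort
    gen = default_config(seed=config.seed, n_patients=config.n_patients)
    cohort = generate_cohort(gen)
    log.info("generated synthetic cohort: %d records, %d leaks", len(cohort), cohort.n_leaks)
    return cohort


def run_analysis(config: AnalysisConfig) -> AnalysisBundle:
    """Execute the full pipeline on a loaded or generated cohort."""
    config.validate()
    cohort = _obtain_cohort(config)

    uni = univariate_table(cohort, DEFAULT_CANDIDATES, entry_alpha=config.entry_alpha)
    screened = screen_variables(cohort, DEFAULT_CANDIDATES, entry_alpha=config.entry_alpha)
    log.info("univariate screen: %d/%d candidates pass at alpha=%.2f",
             len(screened), len(DEFAULT_CANDIDATES), config.entry_alpha)

    fit = backward_stepwise(cohort, screened, stay_alpha=config.stay_alpha)
    log.info("stepwise model: %d term(s) retained (n_used=%d)", len(fit.spec.terms), fit.n_used)

    nomo = build_nomogram(fit, cohort=cohort)

    report = bootstrap_validate(cohort, fit.spec, n_boot=config.n_boot, seed=config.seed)
    log.info("validation: apparent C=%.3f, corrected C=%.3f (%d resamples)",
             report.apparent_c, report.bias_corrected_c, report.n_boot)

    risks = predict_risk(fit, cohort.df)
    calib = calibration_table(risks, cohort.leak, n_bins=config.calibration_bins)

    trace = ra_cusum_trace(risks, cohort.leak, seq=cohort.df["seq"].to_numpy())
    trace = annotate_eras(trace, list(config.era_starts), list(config.era_labels))
    cps = detect_changepoints(trace, max_segments=config.max_segments,
                              min_segment_len=config.min_segment_len)
    segs = segment_summary(trace, cps)
    log.info("RA-CUSUM: final S=%.2f, change-points at %s", trace.final_value, list(cps.indices))

    meta = {
        "alrisk_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "cohort_provenance": cohort.provenance,
        "n_records": len(cohort),
        "n_leaks": cohort.n_leaks,
    }
    return AnalysisBundle(cohort, uni, screened, fit, nomo, report, calib, trace, cps, segs, config, meta)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(bundle: AnalysisBundle, outdir: str | Path) -> dict:
    """Serialise every pipeline artifact; returns the manifest (also written).

    Files: cohort.csv, univariate.csv, multivariate.csv, nomogram_axes.csv,
    validation.json, calibration.csv, cusum_trace.csv, changepoints.json,
    segments.csv, manifest.json (name -> sha256 content hash).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle.cohort, outdir / "cohort.csv")
    bundle.univariate.to_csv(outdir / "univariate.csv", index=False)
    multivariate_table(bundle.fit).to_csv(outdir / "multivariate.csv", index=False)
    tabulate_axes(bundle.nomogram).to_csv(outdir / "nomogram_axes.csv", index=False)
    with open(outdir / "validation.json", "w") as fh:
        json.dump(bundle.validation.to_dict(), fh, indent=2, sort_keys=True)
    bundle.calibration.to_csv(outdir / "calibration.csv", index=False)
    bundle.trace.frame.to_csv(outdir / "cusum_trace.csv", index=False)
    with open(outdir / "changepoints.json", "w") as fh:
        json.dump(
            {
                "indices": list(bundle.changepoints.indices),
                "segment_slopes": list(bundle.changepoints.segment_slopes),
                "fit_criterion": bundle.changepoints.fit_criterion,
                "n_segments": bundle.changepoints.n_segments,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    bundle.segments.to_csv(outdir / "segments.csv", index=False)
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=str)

    names = [
        "cohort.csv", "univariate.csv", "multivariate.csv", "nomogram_axes.csv",
        "validation.json", "calibration.csv", "cusum_trace.csv", "changepoints.json",
        "segments.csv", "metadata.json",
    ]
    manifest = {name: _sha256(outdir / name) for name in names}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
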