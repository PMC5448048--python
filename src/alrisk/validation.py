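"""Discrimination, optimism-corrected internal validation and calibration.

The concordance index (C-index) is the probability that a randomly chosen
leak case is assigned a higher predicted risk than a randomly chosen
non-leak case (ties credit 1/2); Somers' Dxy = 2(C - 0.5). Optimism is
estimated by Harrell's bootstrap: refit on each resample, score the
resample fit on both the resample and the original cohort, average the
difference, and subtract it from the apparent C-index. Calibration bins
predicted risks into quantile groups and compares mean predicted risk with
the observed leak fraction per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import Cohort
from .errors import DataError, DomainError, FitError
from .logistic import ModelSpec, backward_stepwise, fit_logistic, predict_risk


@dataclass(frozen=True)
class CIndexResult:
    c_index: float
    ci_low: float
    ci_high: float
    n_pairs: int


@dataclass(frozen=True)
class ValidationReport:
    apparent_c: float
    optimism: float
    bias_corrected_c: float
    dxy_apparent: float
    dxy_corrected: float
    n_boot: int
    seed: int
    n_redrawn: int = 0
    per_resample: tuple = ()  # (c_on_resample, c_on_original) pairs

    def to_dict(self) -> dict:
        return {
            "apparent_c": self.apparent_c,
            "optimism": self.optimism,
            "bias_corrected_c": self.bias_corrected_c,
            "dxy_apparent": self.dxy_apparent,
            "dxy_corrected": self.dxy_corrected,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "per_resample": [list(p) for p in self.per_resample],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        d = dict(d)
        d["per_resample"] = tuple(tuple(p) for p in d.get("per_resample", []))
        return cls(**d)


def concordance_index(risks, outcomes, ci_method: str = "hanley") -> CIndexResult:
    """C-index over all (event, non-event) pairs, ties scored 1/2.

    Computed via mid-ranks (Mann-Whitney identity), so ties are handled
    exactly. The 95% CI uses the Hanley-McNeil normal approximation by
    default (``ci_method='none'`` skips it).
    """
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes)
    if r.shape != y.shape or r.ndim != 1:
        raise DataError("risks and outcomes must be 1-D and equal length")
    if not np.isin(y, (0, 1)).all():
        raise DomainError("outcomes must be binary 0/1")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise DataError("C-index undefined without both an event and a non-event")
    ranks = rankdata(r)  # mid-ranks give the tie credit of 1/2 exactly
    c = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    c = float(c)
    if ci_method == "none":
        lo = hi = float("nan")
    elif ci_method == "hanley":
        q1 = c / (2.0 - c)
        q2 = 2.0 * c * c / (1.0 + c)
        var = (c * (1 - c) + (n1 - 1) * (q1 - c * c) + (n0 - 1) * (q2 - c * c)) / (n1 * n0)
        half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
        lo, hi = float(max(0.0, c - half)), float(min(1.0, c + half))
    else:
        raise DomainError(f"unknown ci_method {ci_method!r}")
    return CIndexResult(c, lo, hi, n1 * n0)


def somers_dxy(c_index: float) -> float:
    """Somers' rank correlation from a concordance index: Dxy = 2(C - 0.5)."""
    if not (0.0 <= c_index <= 1.0):
        raise DomainError(f"c_index must be in [0, 1]; got {c_index}")
    return 2.0 * (c_index - 0.5)


def _fit_and_c(df: pd.DataFrame, spec: ModelSpec, refit_policy: str):
    if refit_policy == "refit_final":
        fit = fit_logistic(df, spec)
    elif refit_policy == "full_stepwise":
        fit = backward_stepwise(df, list(spec.terms), stay_alpha=spec.stay_alpha, outcome=spec.outcome)
    else:
        raise DomainError(f"unknown refit_policy {refit_policy!r}")
    return fit


def bootstrap_validate(
    cohort: Cohort,
    spec: ModelSpec,
    n_boot: int = 240,
    seed: int = 0,
    refit_policy: str = "refit_final",
    max_redraws: int = 100,
    keep_per_resample: bool = False,
) -> ValidationReport:
    """Harrell optimism-corrected C-index with ``n_boot`` bootstrap resamples.

    Per resample: optimism contribution = C(resample fit on resample) -
    C(resample fit on original cohort). Resamples whose outcome is constant,
    or on which the model cannot be fitted, are redrawn (counted, capped at
    ``max_redraws`` total). Bit-reproducible for a fixed seed.

    ``refit_policy='refit_final'`` refits the supplied final model on each
    resample; ``'full_stepwise'`` repeats the backward selection inside the
    bootstrap as a sensitivity analysis.
    """
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    y = df[spec.outcome].to_numpy(float)
    full_fit = _fit_and_c(df, spec, refit_policy)
    apparent_risk = predict_risk(full_fit, df)
    apparent = concordance_index(apparent_risk, y, ci_method="none").c_index

    rng = np.random.default_rng(seed)
    n = len(df)
    contributions = []
    per_resample = []
    redraws = 0
    while len(contributions) < n_boot:
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        yb = boot[spec.outcome].to_numpy(float)
        if yb.min() == yb.max():
            redraws += 1
            if redraws > max_redraws:
                raise FitError("exceeded bootstrap redraw cap (constant-outcome resamples)")
            continue
        try:
            boot_fit = _fit_and_c(boot, spec, refit_policy)
        except FitError:
            redraws += 1
            if redraws > max_redraws:
                raise
            continue
        c_boot = concordance_index(predict_risk(boot_fit, boot), yb, ci_method="none").c_index
        c_orig = concordance_index(predict_risk(boot_fit, df), y, ci_method="none").c_index
        contributions.append(c_boot - c_orig)
        if keep_per_resample:
            per_resample.append((c_boot, c_orig))
    optimism = float(np.mean(contributions))
    corrected = apparent - optimism
    return ValidationReport(
        apparent_c=float(apparent),
        optimism=optimism,
        bias_corrected_c=float(corrected),
        dxy_apparent=somers_dxy(apparent),
        dxy_corrected=somers_dxy(min(max(corrected, 0.0), 1.0)),
        n_boot=n_boot,
        seed=seed,
        n_redrawn=redraws,
        per_resample=tuple(per_resample),
    )


def calibration_table(risks, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Quantile-binned calibration: mean predicted risk vs observed leak
    fraction per bin. Bins with identical risk quantiles are merged (fewer
    distinct predictions than bins). Bin counts always sum to the input size."""
    if n_bins < 2:
        raise DomainError("n_bins must be >= 2")
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if r.shape != y.shape:
        raise DataError("risks and outcomes must have equal length")
    if np.unique(r).size == 1:  # constant predictions: a single usable bin
        return pd.DataFrame(
            {"bin": [1], "predicted_mean": [float(r.mean())],
             "observed_fraction": [float(y.mean())], "count": [len(y)]}
        )
    bins = pd.qcut(r, q=n_bins, duplicates="drop")
    frame = pd.DataFrame({"risk": r, "y": y, "bin": bins})
    grouped = frame.groupby("bin", observed=True)
    out = grouped.agg(
        predicted_mean=("risk", "mean"),
        observed_fraction=("y", "mean"),
        count=("y", "size"),
    ).reset_index(drop=True)
    out.insert(0, "bin", np.arange(1, len(out) + 1))
    return out
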