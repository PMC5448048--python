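"""Univariate chi-square screening of candidate leak risk factors.

Each candidate variable is cross-tabulated against the binary leak outcome
using the study's published categorisations (age at 70 y, BMI at 25 kg/m2,
tumour size at 4 cm, operative time at 240 min, stapler firings at 2; AJCC
stage 0-II vs III/IV; sex, ASA, tumour location and the binary exposures as
recorded). Variables with a chi-square p-value below the entry threshold
(default 0.10, strict inequality) pass into the multivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import Cohort
from .errors import DataError, DomainError


@dataclass(frozen=True)
class BinningRule:
    """Maps raw covariate values to ordered category labels."""

    variable: str
    labels: tuple
    assign: Callable[[pd.Series], pd.Series]  # values -> labels (must cover all)


def _cut(column: str, threshold: float, labels: tuple, right_first: bool = False) -> BinningRule:
    lo_label, hi_label = labels

    def assign(values: pd.Series) -> pd.Series:
        return pd.Series(np.where(values >= threshold, hi_label, lo_label), index=values.index)

    order = (hi_label, lo_label) if right_first else (lo_label, hi_label)
    return BinningRule(column, order, assign)


def _identity(column: str, level_map: dict, labels: tuple) -> BinningRule:
    def assign(values: pd.Series) -> pd.Series:
        unknown = ~values.isin(level_map)
        if unknown.any():
            raise DataError(
                f"value {values[unknown].iloc[0]!r} in {column!r} outside all bins "
                f"(row {int(values.index[unknown][0])})"
            )
        return values.map(level_map)

    return BinningRule(column, labels, assign)


#: Published dichotomisations / groupings, with Table-style row order.
DEFAULT_BINNINGS: dict[str, BinningRule] = {
    "sex": _identity("sex", {"F": "Female", "M": "Male"}, ("Female", "Male")),
    "age_years": _cut("age_years", 70.0, ("<70", ">=70"), right_first=True),
    "bmi": _cut("bmi", 25.0, ("<25", ">=25")),
    "asa": _identity("asa", {1: "1", 2: "2", 3: "3"}, ("1", "2", "3")),
    "stage": _identity("stage", {0: "0-II", 1: "0-II", 2: "0-II", 3: "III/IV", 4: "III/IV"}, ("0-II", "III/IV")),
    "tumor_size_cm": _cut("tumor_size_cm", 4.0, ("<4", ">=4")),
    "location": _identity("location", {"upper": "Upper", "mid": "Mid", "low": "Low"}, ("Upper", "Mid", "Low")),
    "op_time_min": _cut("op_time_min", 240.0, ("<240", ">=240")),
    "transfusion": _identity("transfusion", {0: "No", 1: "Yes"}, ("No", "Yes")),
    "neoadjuvant_crt": _identity("neoadjuvant_crt", {0: "No", 1: "Yes"}, ("No", "Yes")),
    "stapler_firings": BinningRule(
        "stapler_firings",
        ("<2", ">=2"),
        lambda v: pd.Series(np.where(v >= 2, ">=2", "<2"), index=v.index),
    ),
}

#: Candidate order mirrors the univariate table.
DEFAULT_CANDIDATES = list(DEFAULT_BINNINGS)


@dataclass(frozen=True)
class ContingencyTable:
    """levels x {leak, no-leak} counts for one variable."""

    variable: str
    level_labels: tuple
    counts: np.ndarray  # shape (levels, 2); column 0 = leak, column 1 = no leak

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
            raise DataError(f"{self.variable}: contingency table must be (>=2 levels) x 2")
        if (c < 0).any():
            raise DataError(f"{self.variable}: negative count in contingency table")


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    statistic: float
    df: int
    p_value: float
    correction_applied: bool
    passes_gate: bool


def crosstabulate(cohort: Cohort, variable: str, binning_rule: BinningRule | None = None) -> ContingencyTable:
    """Cross-tabulate one variable against the leak outcome.

    Counts sum to the cohort size; rows follow the rule's declared order.
    """
    if len(cohort) == 0:
        raise DataError("cannot crosstabulate an empty cohort")
    rule = binning_rule if binning_rule is not None else DEFAULT_BINNINGS.get(variable)
    if rule is None:
        raise DomainError(f"no binning rule for variable {variable!r}")
    if rule.variable not in cohort.df.columns:
        raise DataError(f"variable {rule.variable!r} not present in cohort")
    labels = rule.assign(cohort.df[rule.variable])
    uncovered = ~labels.isin(rule.labels)
    if uncovered.any():
        raise DataError(
            f"{variable}: value maps to unknown label {labels[uncovered].iloc[0]!r} "
            f"(row {int(labels.index[uncovered][0])})"
        )
    leak = cohort.df["leak"].to_numpy()
    counts = np.zeros((len(rule.labels), 2), dtype=int)
    for i, lab in enumerate(rule.labels):
        sel = (labels == lab).to_numpy()
        counts[i, 0] = int(leak[sel].sum())
        counts[i, 1] = int(sel.sum() - leak[sel].sum())
    return ContingencyTable(variable, tuple(rule.labels), counts)


def chi_square_test(
    table: ContingencyTable, yates_for_2x2: bool = True, entry_alpha: float = 0.10
) -> UnivariateResult:
    """Pearson chi-square on a levels x outcome table.

    Yates continuity correction is applied to 2x2 tables by default (it is
    what reproduces the published univariate p-values). Degrees of freedom
    are (rows-1)(cols-1).
    """
    counts = np.asarray(table.counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DataError(f"{table.variable}: zero marginal total; chi-square undefined")
    correction = bool(yates_for_2x2) and counts.shape == (2, 2)
    stat, p, dof, _ = chi2_contingency(counts, correction=correction)
    return UnivariateResult(
        variable=table.variable,
        statistic=float(stat),
        df=int(dof),
        p_value=float(p),
        correction_applied=correction,
        passes_gate=bool(p < entry_alpha),
    )


def screen_variables(
    cohort: Cohort,
    candidates: Sequence[str] | None = None,
    entry_alpha: float = 0.10,
    yates_for_2x2: bool = True,
) -> list[str]:
    """Return, in input order, the candidates with univariate p < entry_alpha."""
    if not (0.0 < entry_alpha <= 1.0):
        raise DomainError(f"entry_alpha must be in (0, 1]; got {entry_alpha}")
    candidates = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    passing = []
    for var in candidates:
        res = chi_square_test(crosstabulate(cohort, var), yates_for_2x2=yates_for_2x2, entry_alpha=entry_alpha)
        if res.p_value < entry_alpha:
            passing.append(var)
    return passing


def univariate_table(
    cohort: Cohort, candidates: Sequence[str] | None = None, entry_alpha: float = 0.10
) -> pd.DataFrame:
    """Long-format univariate summary: variable, level, leaks, total, percent, p."""
    candidates = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    rows = []
    for var in candidates:
        tab = crosstabulate(cohort, var)
        res = chi_square_test(tab, entry_alpha=entry_alpha)
        for lab, (leaks, no_leaks) in zip(tab.level_labels, tab.counts):
            total = int(leaks + no_leaks)
            rows.append(
                {
                    "variable": var,
                    "level": lab,
                    "leaks": int(leaks),
                    "total": total,
                    "percent": round(100.0 * leaks / total, 1) if total else float("nan"),
                    "p": res.p_value,
                    "passes_gate": res.passes_gate,
                }
            )
    return pd.DataFrame(rows)
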