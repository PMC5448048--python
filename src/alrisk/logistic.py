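"""Multivariate logistic model of anastomotic-leak risk.

Codes covariates the way the multivariate table presents them (male, ASA 1/2
and upper rectum as reference levels; operative time continuous per 60 min),
fits by maximum likelihood, and performs backward stepwise elimination.
Multi-level categorical terms are kept or dropped as blocks using a
likelihood-ratio test; single-column terms use their Wald p-value. Fitted
per-patient probabilities are the p0_i that drive the RA-CUSUM chart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, norm

from .cohort import Cohort, PatientRecord, record_frame
from .errors import DomainError, FitError


@dataclass(frozen=True)
class Term:
    """One model term: a named block of design columns built from a cohort frame.

    kind: "binary" (one indicator), "categorical" (k-1 indicators vs a
    reference level) or "continuous" (one column, value/scale).
    """

    name: str
    kind: str
    column: str
    levels: tuple = ()       # categorical: non-reference levels, in order
    reference: str | int | None = None
    threshold: float | None = None  # binary-from-numeric cutoff
    level: object = None     # binary-from-category level coded 1
    scale: float = 1.0       # continuous: design value = raw / scale

    def column_labels(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.name}[{lv}]" for lv in self.levels]
        return [self.name]

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        raw = df[self.column]
        if self.kind == "continuous":
            return pd.DataFrame({self.name: raw.to_numpy(float) / self.scale}, index=df.index)
        if self.kind == "binary":
            if self.threshold is not None:
                vals = (raw.to_numpy(float) >= self.threshold).astype(float)
            else:
                vals = (raw == self.level).to_numpy(float)
            return pd.DataFrame({self.name: vals}, index=df.index)
        if self.kind == "categorical":
            known = set(self.levels) | {self.reference}
            unknown = ~raw.isin(known)
            if unknown.any():
                raise DomainError(
                    f"term {self.name!r}: unseen category level {raw[unknown].iloc[0]!r}"
                )
            return pd.DataFrame(
                {f"{self.name}[{lv}]": (raw == lv).to_numpy(float) for lv in self.levels},
                index=df.index,
            )
        raise DomainError(f"unknown term kind {self.kind!r}")


#: Multivariate coding of each candidate variable (distinct from the
#: univariate screening dichotomisations).
DEFAULT_TERMS: dict[str, Term] = {
    "sex": Term("female", "binary", "sex", level="F"),
    "asa": Term("asa3", "binary", "asa", threshold=3.0),
    "location": Term("location", "categorical", "location", levels=("mid", "low"), reference="upper"),
    "op_time_min": Term("op_time_h", "continuous", "op_time_min", scale=60.0),
    "transfusion": Term("transfusion", "binary", "transfusion", level=1),
    "age_years": Term("age_dec", "continuous", "age_years", scale=10.0),
    "bmi": Term("bmi5", "continuous", "bmi", scale=5.0),
    "tumor_size_cm": Term("size_cm", "continuous", "tumor_size_cm", scale=1.0),
    "stage": Term("stage34", "binary", "stage", threshold=3.0),
    "neoadjuvant_crt": Term("crt", "binary", "neoadjuvant_crt", level=1),
    "stapler_firings": Term("firings2", "binary", "stapler_firings", threshold=2.0),
}


def terms_for(candidates: Sequence[str | Term]) -> list[Term]:
    """Resolve variable names to their default Term coding (Terms pass through)."""
    out = []
    for c in candidates:
        if isinstance(c, Term):
            out.append(c)
        elif c in DEFAULT_TERMS:
            out.append(DEFAULT_TERMS[c])
        else:
            raise DomainError(f"no default model coding for variable {c!r}")
    return out


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "leak"
    terms: tuple = ()
    stay_alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.stay_alpha <= 1.0):
            raise DomainError(f"stay_alpha must be in (0, 1]; got {self.stay_alpha}")

    @classmethod
    def from_candidates(cls, candidates: Sequence[str | Term], outcome: str = "leak",
                        stay_alpha: float = 0.05) -> "ModelSpec":
        return cls(outcome=outcome, terms=tuple(terms_for(candidates)), stay_alpha=stay_alpha)


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit with Wald summaries."""

    intercept: float
    coefficients: pd.Series      # per design column, log-odds
    std_errors: pd.Series
    odds_ratios: pd.DataFrame    # columns: OR, ci_low, ci_high, p
    log_likelihood: float
    converged: bool
    n_used: int
    spec: ModelSpec
    notes: tuple = ()

    @property
    def params(self) -> pd.Series:
        return pd.concat([pd.Series({"(intercept)": self.intercept}), self.coefficients])

    def term_columns(self, term: Term) -> list[str]:
        return term.column_labels()


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    blocks = [t.design(df) for t in spec.terms]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    return X


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise FitError("outcome is constant; logistic model undefined")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise FitError(f"term(s) constant across the cohort: {', '.join(const)}")
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        collinear = []
        cols = list(X.columns)
        for c in cols:
            sub = X.drop(columns=[c] + collinear)
            M = np.column_stack([np.ones(len(X)), sub.to_numpy(float)])
            if np.linalg.matrix_rank(M) == rank:
                collinear.append(c)
        raise FitError(f"singular design; collinear term(s): {', '.join(collinear) or 'unknown'}")


def fit_logistic(cohort: Cohort | pd.DataFrame, spec: ModelSpec) -> LogisticFit:
    """Maximum-likelihood logistic fit (Wald 95% CIs as exp(beta +/- 1.96 SE)).

    Records with missing model covariates are dropped (complete-case) with a
    note recording the count. Perfect separation and singular designs raise
    :class:`FitError`.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    needed = [spec.outcome] + [t.column for t in spec.terms]
    complete = df.dropna(subset=[c for c in needed if c in df.columns])
    notes = []
    if len(complete) < len(df):
        notes.append(f"dropped {len(df) - len(complete)} incomplete record(s)")
    y = complete[spec.outcome].to_numpy(float)
    X = design_matrix(complete, spec)
    _check_design(X, y)
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        # convergence is checked explicitly below; overflow in intermediate
        # newton steps on ill-conditioned resamples is benign
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise FitError(f"perfect separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular design during fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    params = pd.Series(res.params, index=Xc.columns)
    bse = pd.Series(res.bse, index=Xc.columns)
    coef = params.drop("const")
    se = bse.drop("const")
    z = norm.ppf(0.975)
    pvals = pd.Series(res.pvalues, index=Xc.columns).drop("const")
    with np.errstate(over="ignore"):  # huge CIs on near-separated fits are reported as inf
        ors = pd.DataFrame(
            {
                "OR": np.exp(coef),
                "ci_low": np.exp(coef - z * se),
                "ci_high": np.exp(coef + z * se),
                "p": pvals,
            }
        )
    return LogisticFit(
        intercept=float(params["const"]),
        coefficients=coef,
        std_errors=se,
        odds_ratios=ors,
        log_likelihood=float(res.llf),
        converged=True,
        n_used=int(len(complete)),
        spec=spec,
        notes=tuple(notes),
    )


def _term_pvalue(cohort_df: pd.DataFrame, fit: LogisticFit, term: Term) -> float:
    """Removal p-value for one term: Wald for single columns, LR for blocks."""
    cols = term.column_labels()
    if len(cols) == 1:
        return float(fit.odds_ratios.loc[cols[0], "p"])
    reduced_terms = tuple(t for t in fit.spec.terms if t.name != term.name)
    reduced = fit_logistic(cohort_df, replace(fit.spec, terms=reduced_terms))
    lr = 2.0 * (fit.log_likelihood - reduced.log_likelihood)
    return float(chi2.sf(max(lr, 0.0), df=len(cols)))


def backward_stepwise(
    cohort: Cohort | pd.DataFrame,
    candidates: Sequence[str | Term],
    stay_alpha: float = 0.05,
    outcome: str = "leak",
) -> LogisticFit:
    """Backward elimination: repeatedly drop the term with the largest removal
    p-value >= stay_alpha (one per iteration), refitting until all remaining
    terms stay. Deterministic for a given cohort."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    terms = terms_for(candidates)
    if not terms:
        spec = ModelSpec(outcome=outcome, terms=(), stay_alpha=stay_alpha)
        fit = fit_logistic(df, spec)
        fit.notes = fit.notes + ("empty candidate list: intercept-only model",)
        return fit
    spec = ModelSpec(outcome=outcome, terms=tuple(terms), stay_alpha=stay_alpha)
    fit = fit_logistic(df, spec)
    while fit.spec.terms:
        pvals = {t.name: _term_pvalue(df, fit, t) for t in fit.spec.terms}
        worst = max(pvals, key=lambda k: (pvals[k], k))  # name breaks exact ties
        if pvals[worst] < stay_alpha:
            break
        remaining = tuple(t for t in fit.spec.terms if t.name != worst)
        fit = fit_logistic(df, replace(fit.spec, terms=remaining))
        fit.notes = fit.notes + (f"removed {worst} (p={pvals[worst]:.4g})",)
    return fit


def linear_predictor(fit: LogisticFit, df: pd.DataFrame) -> np.ndarray:
    X = design_matrix(df, fit.spec)
    return fit.intercept + X.to_numpy(float) @ fit.coefficients.to_numpy()


def predict_risk(fit: LogisticFit, record: PatientRecord | Mapping | pd.DataFrame):
    """Per-patient predicted leak probability (the RA-CUSUM p0_i).

    Accepts a single record (returns a float) or a DataFrame (returns an
    array). Strictly inside (0, 1).
    """
    if isinstance(record, pd.DataFrame):
        return expit(linear_predictor(fit, record))
    lp = linear_predictor(fit, record_frame(record))
    return float(expit(lp)[0])


def multivariate_table(fit: LogisticFit) -> pd.DataFrame:
    """Publication-style summary: term, OR, 95% CI, p."""
    rows = []
    for term in fit.spec.terms:
        for col in term.column_labels():
            r = fit.odds_ratios.loc[col]
            rows.append(
                {
                    "term": term.name,
                    "level": col,
                    "OR": float(r["OR"]),
                    "ci_low": float(r["ci_low"]),
                    "ci_high": float(r["ci_high"]),
                    "p": float(r["p"]),
                }
            )
    return pd.DataFrame(rows, columns=["term", "level", "OR", "ci_low", "ci_high", "p"])
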