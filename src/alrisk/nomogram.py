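"""Nomogram construction from a fitted logistic model.

A nomogram re-expresses each model term's contribution to the linear
predictor on a common 0-100 point scale: the variable with the largest
contribution span (|beta| x domain span) reaches 100 points, every other
variable spans proportionally less, and the per-variable minimum
contribution maps to 0 points. The total across variables converts back to
a predicted probability by inverting the affine map, so scoring a patient
on the nomogram reproduces the model's predicted risk exactly (up to any
rounding applied when rendering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, PatientRecord, record_frame
from .errors import DomainError
from .logistic import LogisticFit, Term, predict_risk

_N_BREAKPOINTS = 11  # continuous axes: round grid, linear in between (exact for a linear term)


@dataclass(frozen=True)
class VariableAxis:
    """One variable's points scale.

    Categorical: ``level_points`` maps every level (reference included) to
    points. Continuous: ``breakpoints``/``breakpoint_points`` define a
    piecewise-linear (here: globally linear) value-to-points map over the
    plotted domain.
    """

    variable: str
    kind: str                      # "binary" | "categorical" | "continuous"
    term: Term
    min_contribution: float        # log-odds contribution mapped to 0 points
    span: float                    # log-odds span over the domain
    level_points: Mapping | None = None
    breakpoints: np.ndarray | None = None
    breakpoint_points: np.ndarray | None = None

    def points_for(self, value, clamp: bool = True) -> float:
        if self.kind in ("binary", "categorical"):
            if value not in self.level_points:
                raise DomainError(f"{self.variable}: level {value!r} not on the nomogram axis")
            return float(self.level_points[value])
        lo, hi = float(self.breakpoints[0]), float(self.breakpoints[-1])
        v = float(value)
        if v < lo or v > hi:
            if not clamp:
                raise DomainError(f"{self.variable}: value {v} outside nomogram domain [{lo}, {hi}]")
            v = min(max(v, lo), hi)
        return float(np.interp(v, self.breakpoints, self.breakpoint_points))


@dataclass(frozen=True)
class NomogramSpec:
    axes: tuple                     # VariableAxis, in model-term order
    scale_factor: float             # points per unit log-odds
    offset: float                   # sum over variables of min_contribution
    intercept: float
    probability_axis: pd.DataFrame  # columns: total_points, probability

    def max_total_points(self) -> float:
        return float(sum(a.span for a in self.axes)) * self.scale_factor


@dataclass(frozen=True)
class NomogramScore:
    per_variable_points: Mapping
    total_points: float
    probability: float


def _term_domain(term: Term, cohort: Cohort | None, domains: Mapping | None):
    if domains and term.name in domains:
        return domains[term.name]
    if domains and term.column in domains:
        return domains[term.column]
    if cohort is None:
        raise DomainError(f"no domain available for continuous term {term.name!r}")
    col = cohort.df[term.column]
    return float(col.min()), float(col.max())


def _nice_grid(lo: float, hi: float, n: int = _N_BREAKPOINTS) -> np.ndarray:
    """Round-number breakpoints covering [lo, hi]."""
    if hi <= lo:
        raise DomainError(f"degenerate continuous domain [{lo}, {hi}]")
    raw_step = (hi - lo) / (n - 1)
    mag = 10.0 ** np.floor(np.log10(raw_step))
    for mult in (1.0, 2.0, 2.5, 5.0, 10.0):
        step = mult * mag
        if step >= raw_step:
            break
    start = np.floor(lo / step) * step
    grid = start + step * np.arange(0, np.ceil((hi - start) / step) + 1)
    grid[0] = min(grid[0], lo)
    grid[-1] = max(grid[-1], hi)
    return grid


def build_nomogram(
    fit: LogisticFit,
    cohort: Cohort | None = None,
    domains: Mapping | None = None,
    prob_grid_step: float = 10.0,
) -> NomogramSpec:
    """Convert a converged fit into per-variable point axes plus a
    total-points-to-probability axis.

    Continuous domains default to the cohort's observed min/max; pass
    ``domains={'term_or_column': (lo, hi)}`` to override.
    """
    if not fit.spec.terms:
        raise DomainError("cannot build a nomogram from an intercept-only model")
    axes_raw = []
    for term in fit.spec.terms:
        if term.kind == "categorical":
            betas = {term.reference: 0.0}
            for lv in term.levels:
                betas[lv] = float(fit.coefficients[f"{term.name}[{lv}]"])
            lo = min(betas.values())
            span = max(betas.values()) - lo
            axes_raw.append((term, "categorical", lo, span, betas, None))
        elif term.kind == "binary":
            beta = float(fit.coefficients[term.name])
            betas = {0: 0.0, 1: beta}
            lo = min(betas.values())
            span = abs(beta)
            axes_raw.append((term, "binary", lo, span, betas, None))
        else:
            beta_unit = float(fit.coefficients[term.name]) / term.scale  # per raw unit
            dlo, dhi = _term_domain(term, cohort, domains)
            grid = _nice_grid(float(dlo), float(dhi))
            contrib = beta_unit * grid
            lo = float(contrib.min())
            span = float(contrib.max() - contrib.min())
            axes_raw.append((term, "continuous", lo, span, None, (grid, contrib)))
    max_span = max(span for _, _, _, span, _, _ in axes_raw)
    if max_span <= 0:
        raise DomainError("all model coefficients are zero over their domains; nomogram scale degenerate")
    scale = 100.0 / max_span

    axes = []
    offset = 0.0
    for term, kind, lo, span, betas, cont in axes_raw:
        offset += lo
        if kind in ("binary", "categorical"):
            pts = {lv: (b - lo) * scale for lv, b in betas.items()}
            axes.append(VariableAxis(term.name, kind, term, lo, span, level_points=pts))
        else:
            grid, contrib = cont
            axes.append(
                VariableAxis(
                    term.name,
                    "continuous",
                    term,
                    lo,
                    span,
                    breakpoints=grid,
                    breakpoint_points=(contrib - lo) * scale,
                )
            )

    total_max = sum(a.span for a in axes) * scale
    totals = np.arange(0.0, total_max + prob_grid_step, prob_grid_step)
    totals = totals[totals <= total_max + 1e-9]
    probs = expit(fit.intercept + offset + totals / scale)
    prob_axis = pd.DataFrame({"total_points": totals, "probability": probs})
    return NomogramSpec(tuple(axes), scale, offset, fit.intercept, prob_axis)


def probability_from_points(spec: NomogramSpec, total_points: float) -> float:
    """Invert the total-points axis back to a predicted probability (exact)."""
    return float(expit(spec.intercept + spec.offset + total_points / spec.scale_factor))


def score_patient(
    spec: NomogramSpec, record: PatientRecord | Mapping, clamp: bool = True
) -> NomogramScore:
    """Read a patient off the nomogram: per-variable points, total, probability.

    Out-of-domain continuous values are clamped to the axis ends by default
    (pass ``clamp=False`` to raise instead).
    """
    df = record_frame(record)
    per_var = {}
    for axis in spec.axes:
        design = axis.term.design(df)
        if axis.kind == "categorical":
            raw = df[axis.term.column].iloc[0]
            per_var[axis.variable] = axis.points_for(raw, clamp=clamp)
        elif axis.kind == "binary":
            per_var[axis.variable] = axis.points_for(int(design.iloc[0, 0]), clamp=clamp)
        else:
            per_var[axis.variable] = axis.points_for(float(df[axis.term.column].iloc[0]), clamp=clamp)
    total = float(sum(per_var.values()))
    return NomogramScore(per_var, total, probability_from_points(spec, total))


def tabulate_axes(spec: NomogramSpec, grid_step: float = 10.0) -> pd.DataFrame:
    """Long-format rendering of every axis: rows of (axis, label/value, points),
    plus the total-points-to-probability axis."""
    if grid_step <= 0:
        raise DomainError("grid_step must be positive")
    rows = []
    for axis in spec.axes:
        if axis.kind in ("binary", "categorical"):
            for lv, pts in axis.level_points.items():
                rows.append({"axis": axis.variable, "value": str(lv), "points": round(float(pts), 1),
                             "probability": np.nan})
        else:
            for v, pts in zip(axis.breakpoints, axis.breakpoint_points):
                rows.append({"axis": axis.variable, "value": f"{v:g}", "points": round(float(pts), 1),
                             "probability": np.nan})
    for _, r in spec.probability_axis.iterrows():
        rows.append(
            {
                "axis": "total_points",
                "value": f"{r['total_points']:g}",
                "points": round(float(r["total_points"]), 1),
                "probability": float(r["probability"]),
            }
        )
    return pd.DataFrame(rows, columns=["axis", "value", "points", "probability"])
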