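"""Risk-adjusted CUSUM monitoring of sequential surgical outcomes.

For consecutive operations i with binary outcome X_i (1 = anastomotic leak)
and model-predicted leak probability p0_i, the chart accumulates
S_n = sum_{i<=n} (X_i - p0_i): it rises by 1 - p0_i for each leak and falls
by p0_i for each leak-free case, so a leak in a low-risk patient moves the
curve up more than one in a high-risk patient. When outcomes truly follow
their p0_i the increments are a martingale difference sequence and the
trace drifts around zero; sustained slope changes indicate performance
shifts.

Change-points are found by exact dynamic-programming least squares: fitting
piecewise-constant means to the increment series is equivalent to fitting a
continuous piecewise-linear curve to the cumulative trace, and the number
of segments is chosen by a BIC-style penalty. The chart itself carries no
decision limits; it is an unbounded observed-minus-expected plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

_SSE_FLOOR = 1e-12


@dataclass
class CusumTrace:
    """Per-case chart state, in seq order: p0, outcome, increment, running sum."""

    frame: pd.DataFrame  # columns: seq, p0, x, increment, s (+ optional eras)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def increments(self) -> np.ndarray:
        return self.frame["increment"].to_numpy()

    @property
    def s(self) -> np.ndarray:
        return self.frame["s"].to_numpy()

    @property
    def final_value(self) -> float:
        return float(self.frame["s"].iloc[-1])


@dataclass(frozen=True)
class ChangePointSet:
    """Detected change-points: the last case index of each non-final segment."""

    indices: tuple            # strictly increasing seq indices
    segment_slopes: tuple     # mean increment per segment
    fit_criterion: float      # BIC of the selected segmentation
    n_segments: int

    def segments(self, n: int) -> list[tuple]:
        """1-based inclusive (start, end) case ranges partitioning [1, n]."""
        starts = [1] + [i + 1 for i in self.indices]
        ends = list(self.indices) + [n]
        return list(zip(starts, ends))


def ra_cusum_trace(risks, outcomes, seq=None) -> CusumTrace:
    """Build the chart: increment X_i - p0_i, cumulative sum starting at 0."""
    p0 = np.asarray(risks, dtype=float)
    x = np.asarray(outcomes)
    if p0.shape != x.shape or p0.ndim != 1 or len(p0) == 0:
        raise DataError("risks and outcomes must be equal-length non-empty 1-D sequences")
    if not np.isin(x, (0, 1)).all():
        raise DomainError("outcomes must be binary 0/1")
    if (p0 <= 0.0).any() or (p0 >= 1.0).any():
        raise DomainError("predicted risks must lie strictly in (0, 1)")
    seq = np.arange(1, len(p0) + 1) if seq is None else np.asarray(seq, dtype=int)
    if seq.shape != p0.shape:
        raise DataError("seq must match risks in length")
    inc = x.astype(float) - p0
    frame = pd.DataFrame({"seq": seq, "p0": p0, "x": x.astype(int), "increment": inc, "s": np.cumsum(inc)})
    return CusumTrace(frame)


def detect_changepoints(
    trace: CusumTrace, max_segments: int = 5, min_segment_len: int = 30
) -> ChangePointSet:
    """Exact least-squares segmentation of the increment series.

    Dynamic programming over candidate knots gives, for each segment count
    k <= max_segments, the optimal piecewise-constant mean fit (equivalently
    a continuous piecewise-linear fit to the cumulative trace); k is then
    selected by BIC = n ln(SSE/n) + (2k - 1) ln n. Deterministic; earliest
    optimal knot wins exact ties.
    """
    n = trace.n
    if max_segments < 1 or min_segment_len < 1:
        raise ConfigurationError("max_segments and min_segment_len must be >= 1")
    if n < 2 * min_segment_len:
        raise ConfigurationError(
            f"trace of length {n} cannot hold two segments of length >= {min_segment_len}"
        )
    y = trace.increments
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    kmax = min(max_segments, n // min_segment_len)

    # D[k][j]: best SSE for y[0:j] split into k segments; B[k][j]: last split point.
    INF = float("inf")
    D = np.full((kmax + 1, n + 1), INF)
    B = np.zeros((kmax + 1, n + 1), dtype=int)
    j_all = np.arange(min_segment_len, n + 1)
    D[1][j_all] = c2[j_all] - c1[j_all] ** 2 / j_all
    for k in range(2, kmax + 1):
        for j in range(k * min_segment_len, n + 1):
            t = np.arange((k - 1) * min_segment_len, j - min_segment_len + 1)
            seg = c2[j] - c2[t] - (c1[j] - c1[t]) ** 2 / (j - t)
            v = D[k - 1][t] + seg
            i = int(np.argmin(v))  # first minimum -> earliest knot on ties
            D[k][j], B[k][j] = v[i], t[i]

    best_k, best_bic = 1, INF
    for k in range(1, kmax + 1):
        if not np.isfinite(D[k][n]):
            continue
        sse = max(D[k][n], _SSE_FLOOR)
        bic = n * np.log(sse / n) + (2 * k - 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_k, best_bic = k, bic

    knots = []
    j, k = n, best_k
    while k > 1:
        t = int(B[k][j])
        knots.append(t)
        j, k = t, k - 1
    knots = sorted(knots)  # split positions in [0, n); case index of segment end = t

    seq = trace.frame["seq"].to_numpy()
    indices = tuple(int(seq[t - 1]) for t in knots)
    bounds = [0] + knots + [n]
    slopes = tuple(float(y[a:b].mean()) for a, b in zip(bounds, bounds[1:]))
    return ChangePointSet(indices, slopes, float(best_bic), best_k)


def annotate_eras(trace: CusumTrace, era_starts, era_labels) -> CusumTrace:
    """Label each case with every era active at its index (eras are
    cumulative: once a strategy starts it stays in use)."""
    starts = list(era_starts)
    labels = list(era_labels)
    if len(starts) != len(labels):
        raise DataError("era_starts and era_labels must have equal length")
    if any(b2 <= b1 for b1, b2 in zip(starts, starts[1:])):
        raise DataError("era_starts must be strictly increasing")
    n = trace.n
    seq = trace.frame["seq"].to_numpy()
    if starts and not all(1 <= s <= n for s in starts):
        raise DataError(f"era start outside [1, {n}]")
    eras = ["+".join(lab for s, lab in zip(starts, labels) if q >= s) for q in seq]
    frame = trace.frame.copy()
    frame["eras"] = eras
    return CusumTrace(frame)


def segment_summary(trace: CusumTrace, cps: ChangePointSet) -> pd.DataFrame:
    """Per segment: case range, events, mean p0, slope (mean increment) and
    observed-minus-expected event count."""
    rows = []
    for (start, end), slope in zip(cps.segments(trace.n), cps.segment_slopes):
        sub = trace.frame[(trace.frame["seq"] >= start) & (trace.frame["seq"] <= end)]
        events = int(sub["x"].sum())
        expected = float(sub["p0"].sum())
        rows.append(
            {
                "start": start,
                "end": end,
                "n_cases": len(sub),
                "events": events,
                "expected_events": expected,
                "mean_p0": float(sub["p0"].mean()),
                "slope": slope,
                "observed_minus_expected": events - expected,
            }
        )
    return pd.DataFrame(rows)
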