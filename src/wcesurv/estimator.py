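"""Weighted composite endpoint survival estimation.

Each event of type k multiplies a subject's survival path by (1 - w_k), so a
subject's weighted survival at time t is

    S_i(t) = prod_{j: t_j <= t} (1 - w_ij),

and the pooled estimate over n subjects is the mean of the individual paths,

    S(t) = (1/n) sum_i S_i(t).

The mean form is identical to the product-limit recursion
S(t_j) = S(t_{j-1}) (1 - d_j / n_j) with the weighted increments

    d_j = sum_i [S_i(t_{j-1}) - S_i(t_j)],    n_j = sum_i S_i(t_{j-1}),

which generalize the Kaplan-Meier death count and risk-set size.  With all
weights set to 1 and each subject truncated at the first event, the estimator
collapses to the classical time-to-first-event analysis (a no-censoring
Kaplan-Meier).

Paths are right-continuous step functions: the value reported "at t" already
includes events occurring at exactly t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTypeCatalog, SubjectHistory, ValidationError

IDENTITY_ATOL = 1e-12  # pure products/sums of well-scaled values


@dataclass
class SubjectSurvivalPath:
    """One subject's weighted survival path as a right-continuous step function.

    ``values[j]`` is the path value on ``[knots[j], knots[j+1])``; before the
    first knot the value is 1.  A terminal event drives the value to exactly 0.
    """

    subject_id: str
    knots: np.ndarray  # strictly increasing event times
    values: np.ndarray  # path value after the events at each knot

    def value_at(self, times: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the step function at ``times`` (right-continuous)."""
        idx = np.searchsorted(self.knots, np.asarray(times, dtype=float), side="right")
        padded = np.concatenate(([1.0], self.values))
        out = padded[idx]
        return float(out) if np.isscalar(times) else out


@dataclass
class SurvivalCurve:
    """Pooled survival estimate on the grid of distinct event times.

    The grid always starts at t=0 with estimate 1.  ``variance``, ``ci_lower``
    and ``ci_upper`` are filled by the variance module; ``n_effective`` is the
    weighted risk-set size n_j just before each grid time.
    """

    grid: np.ndarray
    estimate: np.ndarray
    n: int
    arm: str = ""
    variance: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_effective: np.ndarray | None = None
    # bookkeeping shared with the variance module (sum of squared path values)
    sum_sq: np.ndarray | None = None

    def value_at(self, times: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.grid, np.asarray(times, dtype=float), side="right")
        idx = np.clip(idx - 1, 0, len(self.grid) - 1)
        out = self.estimate[idx]
        return float(out) if np.isscalar(times) else out

    def to_frame(self) -> pd.DataFrame:
        def col(x):
            return x if x is not None else np.full(len(self.grid), np.nan)

        return pd.DataFrame(
            {
                "time": self.grid,
                "estimate": self.estimate,
                "variance": col(self.variance),
                "ci_lower": col(None if self.ci_lower is None else np.clip(self.ci_lower, 0.0, 1.0)),
                "ci_upper": col(None if self.ci_upper is None else np.clip(self.ci_upper, 0.0, 1.0)),
                "n_effective": col(self.n_effective),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def subject_path(
    history: SubjectHistory, catalog: EventTypeCatalog
) -> SubjectSurvivalPath:
    """Multiplicative weighted survival path for one subject.

    Simultaneous events at one time contribute the product of their (1 - w_k)
    factors in a single step; order within a time is irrelevant by
    commutativity.  A terminal event sets the path to exactly 0.
    """
    history.validate(catalog)
    knots: list[float] = []
    values: list[float] = []
    value = 1.0
    for time, label in history.events:
        factor = 1.0 - catalog.weight_of(label)
        if knots and knots[-1] == time:
            value = values[-1] * factor if values[-1] else 0.0
            values[-1] = value
        else:
            value = value * factor
            knots.append(time)
            values.append(value)
    return SubjectSurvivalPath(
        history.subject_id, np.asarray(knots, dtype=float), np.asarray(values, dtype=float)
    )


def _pooled_sweep(
    paths: list[SubjectSurvivalPath], n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single event-driven pass over the pooled grid.

    Returns (grid including t=0, pooled estimate, sum of squared path values).
    Runs in O(total events + grid length).
    """
    if n <= 0:
        raise ValidationError("sample size must be positive")
    if len(paths) > n:
        raise ValidationError("more paths than subjects")
    events: list[tuple[float, int, float]] = []  # (time, path index, new value)
    for i, p in enumerate(paths):
        for t, v in zip(p.knots, p.values):
            events.append((float(t), i, float(v)))
    events.sort(key=lambda e: e[0])

    grid = [0.0]
    total = float(n)
    total_sq = float(n)
    estimates = [1.0]
    sums_sq = [float(n)]
    current = np.ones(len(paths))
    pos = 0
    while pos < len(events):
        t = events[pos][0]
        while pos < len(events) and events[pos][0] == t:
            _, i, v = events[pos]
            total += v - current[i]
            total_sq += v * v - current[i] * current[i]
            current[i] = v
            pos += 1
        grid.append(t)
        estimates.append(total / n)
        sums_sq.append(total_sq)
    return (
        np.asarray(grid),
        np.asarray(estimates),
        np.maximum(np.asarray(sums_sq), 0.0),
    )


def pooled_curve(
    paths: list[SubjectSurvivalPath], n: int, arm: str = ""
) -> SurvivalCurve:
    """Pooled weighted survival curve: the mean of all n subject paths.

    ``n`` must count every subject, including event-free ones (who may be
    represented implicitly: paths with no knots can be omitted from ``paths``
    as long as ``n`` counts them).
    """
    grid, est, sum_sq = _pooled_sweep(paths, n)
    curve = SurvivalCurve(grid=grid, estimate=est, n=n, arm=arm, sum_sq=sum_sq)
    # weighted risk set just before each grid time: n_j = sum_i S_i(t_{j-1})
    curve.n_effective = np.concatenate(([float(n)], est[:-1] * n))
    return curve


def heuristic_increments(
    paths: list[SubjectSurvivalPath], grid: np.ndarray, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted death counts and risk-set sizes (d_j, n_j) on ``grid``.

    d_j = sum_i [S_i(t_{j-1}) - S_i(t_j)]  and  n_j = sum_i S_i(t_{j-1}),
    with event-free subjects contributing the constant 1; ``n`` defaults to
    ``len(paths)``.  The first grid point must be 0, where d_0 = 0 and
    n_0 = n.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValidationError("grid must start at t=0")
    n = len(paths) if n is None else n
    implicit = n - len(paths)  # event-free subjects not given as paths
    if implicit < 0:
        raise ValidationError("more paths than subjects")
    values = np.tile(np.ones(len(grid)), (len(paths), 1))
    for i, p in enumerate(paths):
        values[i] = p.value_at(grid)
    totals = values.sum(axis=0) + implicit
    d = np.concatenate(([0.0], totals[:-1] - totals[1:]))
    n_j = np.concatenate(([float(n)], totals[:-1]))
    return d, n_j


def product_limit_estimate(d: np.ndarray, n_j: np.ndarray) -> np.ndarray:
    """Recursive product-limit form S(t_j) = S(t_{j-1}) (1 - d_j/n_j)."""
    hazards = np.divide(d, n_j, out=np.zeros_like(d), where=n_j > 0)
    return np.cumprod(1.0 - hazards)


def first_event_paths(
    histories: list[SubjectHistory],
) -> list[SubjectSurvivalPath]:
    """Reduce each subject to the first event with weight 1 (traditional view)."""
    paths = []
    for h in histories:
        t = h.first_event_time()
        if t is None:
            paths.append(SubjectSurvivalPath(h.subject_id, np.array([]), np.array([])))
        else:
            paths.append(
                SubjectSurvivalPath(h.subject_id, np.array([t]), np.array([0.0]))
            )
    return paths


def traditional_curve(
    histories: list[SubjectHistory], followup: float | None = None, arm: str = ""
) -> SurvivalCurve:
    """Time-to-first-event survival curve (all weights 1, first event only).

    With no censoring this equals the empirical survival function of the
    first-event time — the special case of the weighted estimator where every
    weight is set to 1.
    """
    if not histories:
        raise ValidationError("no subjects")
    return pooled_curve(first_event_paths(histories), n=len(histories), arm=arm)


def wce_paths(
    histories: list[SubjectHistory], catalog: EventTypeCatalog
) -> list[SubjectSurvivalPath]:
    return [subject_path(h, catalog) for h in histories]


def wce_curve(
    histories: list[SubjectHistory], catalog: EventTypeCatalog, arm: str = ""
) -> SurvivalCurve:
    """Pooled weighted composite endpoint curve for one arm."""
    if not histories:
        raise ValidationError("no subjects")
    return pooled_curve(wce_paths(histories, catalog), n=len(histories), arm=arm)
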