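"""Variance of the weighted survival estimate and normal confidence bands.

At each distinct event time t_j the event indicator vector E_ij of subject i
is modelled as a single multinomial draw over the K event types plus the
no-event category, with type-probability vector P_j.  The random per-event
weight omega_ij = W' E_ij then has

    E[omega_ij]   = W' P_j,
    Var(omega_ij) = W' [diag(P_j) - P_j P_j'] W,

and a delta-method expansion of the product path gives

    Var(S(t)) ~= (1/n^2) sum_i S_i(t)^2
                 * sum_{j: t_j <= t} Var(omega_ij) / (1 - W' P_j)^2.

P_j is estimated by maximum likelihood as E_.j / n_j, where E_.j counts the
type-k events at exactly t_j and n_j is the risk-set size at t_j.  Here n_j
is the *weighted* risk set sum_i S_i(t_{j-1}) — the same n_j as in the
product-limit recursion, so that with all weights equal to 1 the quantity
W' P_j reduces to the Kaplan-Meier hazard d_j / n_j.  A raw head count of
surviving subjects is available as a sensitivity switch.

The confidence band is the pointwise normal approximation
S(t) +/- z_{alpha/2} sd(S(t)), clipped to [0, 1] for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import (
    SubjectSurvivalPath,
    SurvivalCurve,
    subject_path,
    wce_paths,
)
from .io import EventTypeCatalog, SubjectHistory, ValidationError

#: tolerated fraction of event rows where one subject has several events at
#: one time (formally outside the one-draw multinomial model)
SIMULTANEOUS_TOLERANCE = 0.01


@dataclass
class EventProbProfile:
    """Per-grid-time event-type probability estimates.

    ``probs[j]`` is the length-K vector P_j = E_.j / n_j; ``counts[j]`` is
    E_.j; ``n_risk[j]`` is the risk-set size n_j.  The remainder
    1 - sum_k P_jk is the no-event probability and must stay positive in
    weighted form (W'P_j < 1) wherever events occur.
    """

    grid: np.ndarray
    probs: np.ndarray  # (J, K)
    counts: np.ndarray  # (J, K)
    n_risk: np.ndarray  # (J,)
    simultaneous_rows: int = 0


def omega_moments(p: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the weighted event indicator omega = W'E.

    E is one multinomial draw over K event types (probabilities ``p``, with
    1 - sum(p) the no-event probability).
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(p < 0) or p.sum() > 1 + 1e-12:
        raise ValidationError("invalid event-probability vector")
    mean = float(w @ p)
    cov = np.diag(p) - np.outer(p, p)
    return mean, float(w @ cov @ w)


def estimate_event_probs(
    histories: list[SubjectHistory],
    catalog: EventTypeCatalog,
    grid: np.ndarray,
    risk_set: str = "weighted",
) -> EventProbProfile:
    """Estimate P_j = E_.j / n_j on ``grid`` (which must start at 0).

    ``risk_set`` selects the n_j definition: ``"weighted"`` (default) uses
    the weighted risk set sum_i S_i(t_{j-1}); ``"raw"`` counts subjects whose
    path is still positive just before t_j.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0 or grid[0] != 0.0:
        raise ValidationError("grid must start at t=0")
    if risk_set not in {"weighted", "raw"}:
        raise ValidationError(f"unknown risk_set {risk_set!r}")
    K = catalog.n_types
    counts = np.zeros((len(grid), K))
    n_event_rows = 0
    simultaneous = 0
    time_index = {t: j for j, t in enumerate(grid)}
    for h in histories:
        seen_times: dict[float, int] = {}
        for t, label in h.events:
            j = time_index.get(float(t))
            if j is None:
                raise ValidationError(
                    f"event time {t} of subject {h.subject_id} not on the grid"
                )
            counts[j, catalog.index_of(label)] += 1
            n_event_rows += 1
            seen_times[t] = seen_times.get(t, 0) + 1
        simultaneous += sum(c - 1 for c in seen_times.values() if c > 1)
    if n_event_rows and simultaneous / n_event_rows > SIMULTANEOUS_TOLERANCE:
        raise ValidationError(
            f"{simultaneous} of {n_event_rows} event rows are simultaneous "
            "same-subject events, exceeding the tolerated share "
            f"({SIMULTANEOUS_TOLERANCE:.0%}) of the one-draw multinomial model"
        )

    paths = wce_paths(histories, catalog)
    values = np.ones((len(histories), len(grid)))
    for i, p in enumerate(paths):
        values[i] = p.value_at(grid)
    if risk_set == "weighted":
        totals = values.sum(axis=0)
    else:
        totals = (values > 0).sum(axis=0).astype(float)
    n_risk = np.concatenate(([float(len(histories))], totals[:-1]))

    has_events = counts.sum(axis=1) > 0
    if np.any(has_events & (n_risk <= 0)):
        raise ValidationError("events observed at a time with empty risk set")
    probs = np.zeros_like(counts)
    np.divide(counts, n_risk[:, None], out=probs, where=n_risk[:, None] > 0)
    return EventProbProfile(grid, probs, counts, n_risk, simultaneous)


def survival_variance(
    curve: SurvivalCurve,
    paths: list[SubjectSurvivalPath],
    profile: EventProbProfile,
    weights: np.ndarray,
) -> np.ndarray:
    """Delta-method variance of the pooled estimate at every grid time.

    Times with no events contribute zero; a subject whose path has reached 0
    contributes nothing through S_i^2.
    """
    grid = np.asarray(curve.grid, dtype=float)
    if len(grid) != len(profile.grid) or not np.array_equal(grid, profile.grid):
        raise ValidationError("curve and probability profile use different grids")
    w = np.asarray(weights, dtype=float)
    wp = profile.probs @ w
    has_events = profile.counts.sum(axis=1) > 0
    if np.any(has_events & (wp >= 1.0)):
        raise ValidationError(
            "weighted hazard W'P_j >= 1 at some event time; variance undefined"
        )
    var_omega = np.array(
        [omega_moments(profile.probs[j], w)[1] if has_events[j] else 0.0
         for j in range(len(grid))]
    )
    terms = np.zeros(len(grid))
    np.divide(var_omega, (1.0 - wp) ** 2, out=terms, where=has_events)
    accumulated = np.cumsum(terms)

    if curve.sum_sq is not None:
        sum_sq = curve.sum_sq
    else:
        values = np.ones((len(paths), len(grid)))
        for i, p in enumerate(paths):
            values[i] = p.value_at(grid)
        sum_sq = (values**2).sum(axis=0) + (curve.n - len(paths))
    return sum_sq / curve.n**2 * accumulated


def confidence_band(
    curve: SurvivalCurve,
    variance: np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise normal band S(t) +/- z_{alpha/2} sd(S(t)), unclipped.

    Reporting layers clip to [0, 1]; the raw band is returned so callers can
    see overshoot near the boundaries.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(np.maximum(variance, 0.0))
    return curve.estimate - half, curve.estimate + half


def attach_uncertainty(
    curve: SurvivalCurve,
    histories: list[SubjectHistory],
    catalog: EventTypeCatalog,
    level: float = 0.95,
    risk_set: str = "weighted",
    weights: np.ndarray | None = None,
    paths: list[SubjectSurvivalPath] | None = None,
) -> SurvivalCurve:
    """Fill ``variance``, ``ci_lower`` and ``ci_upper`` on ``curve`` in place."""
    if paths is None:
        paths = wce_paths(histories, catalog)
    profile = estimate_event_probs(histories, catalog, curve.grid, risk_set)
    w = catalog.weight_vector if weights is None else np.asarray(weights, float)
    curve.variance = survival_variance(curve, paths, profile, w)
    curve.ci_lower, curve.ci_upper = confidence_band(curve, curve.variance, level)
    return curve


def traditional_uncertainty(
    curve: SurvivalCurve,
    histories: list[SubjectHistory],
    catalog: EventTypeCatalog,
    level: float = 0.95,
) -> SurvivalCurve:
    """Variance and band for the time-to-first-event curve.

    Uses the same machinery with every weight forced to 1 and each history
    truncated at its first event (any event becomes terminal-like).
    """
    truncated = []
    for h in histories:
        if h.is_event_free:
            truncated.append(h)
        else:
            t, _ = h.events[0]
            truncated.append(
                SubjectHistory(
                    h.subject_id, h.arm, [(t, catalog.terminal_type)], h.followup
                )
            )
    ones = np.ones(catalog.n_types)
    profile = estimate_event_probs(truncated, catalog, curve.grid, "weighted")
    paths = [subject_path(h, catalog) for h in truncated]
    curve.variance = survival_variance(curve, paths, profile, ones)
    curve.ci_lower, curve.ci_upper = confidence_band(curve, curve.variance, level)
    return curve
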