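"""Incidence rates, Kaplan-Meier estimation and quantile survival times.

Quantile survival times use the step-function convention: the q-quantile is
the smallest observed event time at which the Kaplan-Meier curve has dropped
to ``1 - q`` or below.  When the curve never falls that far (heavy censoring)
the quantile "cannot be computed" and is reported with the ``cbc`` sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)

RATE_DECIMALS = 6  # incidence rates are tabulated to 6 decimal places


class _NotComputable:
    """Sentinel for survival quantiles the KM curve never reaches."""

    def __repr__(self) -> str:
        return "cbc"

    def __str__(self) -> str:
        return "cbc"


NOT_COMPUTABLE = _NotComputable()


@dataclass(frozen=True)
class IncidenceResult:
    events: int
    person_time: float

    @property
    def rate(self) -> float:
        return self.events / self.person_time


def incidence_rate(events: int, person_time: float) -> IncidenceResult:
    """Events per person-day of observation."""
    if person_time <= 0:
        raise ValueError(f"person_time must be positive, got {person_time}")
    if events < 0:
        raise ValueError(f"events must be >= 0, got {events}")
    return IncidenceResult(events=int(events), person_time=float(person_time))


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: survival step values at ascending event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Left-continuous-from-the-right step evaluation S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_fit(cohort_or_arrays, group_by: str | None = None):
    """Kaplan-Meier estimate, optionally split by a covariate category.

    Accepts either a :class:`Cohort` or a tuple ``(entry, exit, event)`` of
    arrays.  Ties between events and censorings at the same time keep the
    censored records in the risk set (events precede censorings).  Returns a
    single :class:`KMEstimate`, or a dict level -> estimate when ``group_by``
    is given (empty groups are skipped with a log entry).
    """
    if isinstance(cohort_or_arrays, Cohort):
        cohort = cohort_or_arrays
        if group_by is not None:
            out = {}
            for level in cohort.covariate_spec.categories[group_by]:
                mask = (cohort.df[group_by] == level).to_numpy()
                if not mask.any():
                    logger.info("km_fit: empty group %s=%s skipped", group_by, level)
                    continue
                out[level] = _km_arrays(
                    cohort.entry[mask], cohort.exit[mask], cohort.event[mask]
                )
            return out
        return _km_arrays(cohort.entry, cohort.exit, cohort.event)
    entry, exit_, event = cohort_or_arrays
    return _km_arrays(np.asarray(entry, float), np.asarray(exit_, float), np.asarray(event, int))


def _km_arrays(entry: np.ndarray, exit_: np.ndarray, event: np.ndarray) -> KMEstimate:
    if event.sum() < 1:
        raise ValueError("Kaplan-Meier estimate requires at least one event")
    times = np.unique(exit_[event == 1])
    surv = np.empty(times.size)
    at_risk = np.empty(times.size, dtype=int)
    d = np.empty(times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(times):
        n_risk = int(np.sum((entry < t) & (exit_ >= t)))
        dj = int(np.sum((exit_ == t) & (event == 1)))
        s *= 1.0 - dj / n_risk
        surv[i] = s
        at_risk[i] = n_risk
        d[i] = dj
    return KMEstimate(event_times=times, survival=surv, at_risk=at_risk, n_events=d)


def survival_quantile(km: KMEstimate, q: float):
    """Smallest event time with S(t) <= 1 - q, else the ``cbc`` sentinel."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    hits = np.nonzero(km.survival <= 1.0 - q + 1e-12)[0]
    if hits.size == 0:
        return NOT_COMPUTABLE
    return float(km.event_times[hits[0]])


def _quantile_str(value) -> str:
    return "cbc" if value is NOT_COMPUTABLE else f"{value:.0f}"


def table1(cohort: Cohort, categories: list[str] | None = None) -> pd.DataFrame:
    """Per-level descriptives: N(%), days at risk, incidence rate, quartiles.

    One row per level of each requested category plus a ``Total`` row;
    non-computable quantiles carry the literal ``cbc``.
    """
    if categories is None:
        categories = list(cohort.covariate_spec.names)
    rows = []

    def _one(label_cat: str, label_lev: str, mask: np.ndarray, denom: int):
        sub_entry = cohort.entry[mask]
        sub_exit = cohort.exit[mask]
        sub_event = cohort.event[mask]
        pt = float((sub_exit - sub_entry).sum())
        ev = int(sub_event.sum())
        rate = ev / pt if pt > 0 else np.nan
        if ev >= 1:
            km = _km_arrays(sub_entry, sub_exit, sub_event)
            qs = [survival_quantile(km, q) for q in (0.25, 0.5, 0.75)]
        else:
            qs = [NOT_COMPUTABLE] * 3
        rows.append(
            {
                "category": label_cat,
                "level": label_lev,
                "n": int(mask.sum()),
                "percent": round(100.0 * mask.sum() / denom, 1),
                "days_at_risk": pt,
                "incidence_rate": round(rate, RATE_DECIMALS),
                "q25": _quantile_str(qs[0]),
                "median": _quantile_str(qs[1]),
                "q75": _quantile_str(qs[2]),
            }
        )

    n = len(cohort)
    for cat in categories:
        for level in cohort.covariate_spec.categories[cat]:
            mask = (cohort.df[cat] == level).to_numpy()
            if mask.any():
                _one(cat, level, mask, n)
    _one("Total", "Total", np.ones(n, bool), n)
    return pd.DataFrame(rows)
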