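"""Lab-marker trend detection and the temporality evidence basis.

A patient on a drug is monitored through routine blood markers
(creatinine, glucose, urea, platelets, ...).  A drug that drives a
marker up or down leaves a linear trend L_j = beta0 + beta1 * t + eps_j
in the patient's series; the two-sided t-test of H0: beta1 = 0 at
alpha = 0.05 decides whether a trend is real, and its sign gives the
direction.  A knowledge map supplied by domain experts links a
(marker, direction) trend to the symptoms it can produce (e.g. falling
platelets -> bleeding).  Every (patient, drug, symptom) triple whose
significant trend overlaps the drug's exposure window enters the
*temporality basis*; membership of a candidate record in that basis is
its binary DepTemporal credibility component.

No multiplicity correction is applied across the patient x marker
tests: each series is judged on its own, as a per-record evidence
source rather than a family-wise discovery procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerSeries",
    "TrendResult",
    "TemporalityBasis",
    "TemporalError",
    "fit_trend",
    "classify_trend",
    "build_temporality_basis",
    "dep_temporal",
]

DEFAULT_ALPHA = 0.05
DEFAULT_EXPOSURE_LAG_DAYS = 30
MIN_OBSERVATIONS = 3


class TemporalError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerSeries:
    """One patient's observations of one lab marker over time.

    ``times`` are days from the first observation, strictly increasing;
    ``start_date`` anchors the series on the calendar so exposure
    overlap can be checked.
    """

    patient_id: str
    marker: str
    times: np.ndarray
    values: np.ndarray
    start_date: pd.Timestamp | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise TemporalError("times and values must be 1-d arrays of equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise TemporalError("observation times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise TemporalError("marker values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def midpoint_date(self) -> pd.Timestamp:
        if self.start_date is None:
            raise TemporalError("series has no calendar anchor")
        return self.start_date + pd.Timedelta(days=float(self.times[-1] + self.times[0]) / 2.0)


@dataclass(frozen=True)
class TrendResult:
    """OLS fit of marker value on time with the slope significance test."""

    beta0: float
    beta1: float
    sigma2: float
    p_value: float
    direction: str  # "increasing" | "decreasing" | "none"
    n_obs: int


def fit_trend(series: MarkerSeries, alpha: float = DEFAULT_ALPHA) -> TrendResult:
    """Ordinary least squares of value on time (days).

    The p-value is the two-sided t-test of H0: beta1 = 0, identical to
    the regression F-test with one numerator degree of freedom.
    """
    t, v = series.times, series.values
    if len(t) < MIN_OBSERVATIONS:
        raise TemporalError(f"trend fitting needs >= {MIN_OBSERVATIONS} observations, got {len(t)}")
    if np.ptp(t) == 0:
        raise TemporalError("all observation times equal")
    res = stats.linregress(t, v)
    resid = v - (res.intercept + res.slope * t)
    sigma2 = float(resid @ resid) / (len(t) - 2)
    p = float(res.pvalue)
    return TrendResult(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        sigma2=sigma2,
        p_value=p,
        direction=classify_trend_values(res.slope, p, alpha),
        n_obs=len(t),
    )


def classify_trend_values(beta1: float, p_value: float, alpha: float) -> str:
    if not 0.0 < alpha < 1.0:
        raise TemporalError(f"alpha {alpha} outside (0, 1)")
    if p_value < alpha:
        return "increasing" if beta1 > 0 else "decreasing"
    return "none"


def classify_trend(result: TrendResult, alpha: float = DEFAULT_ALPHA) -> str:
    """Reject H0: beta1 = 0 iff p < alpha; the slope sign gives the direction."""
    return classify_trend_values(result.beta1, result.p_value, alpha)


@dataclass
class TemporalityBasis:
    """The (patient, drug, symptom) triples supported by a marker trend."""

    entries: frozenset = field(default_factory=frozenset)

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return tuple(triple) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def build_temporality_basis(
    trends: Iterable[tuple[MarkerSeries, TrendResult]],
    exposures: pd.DataFrame,
    marker_symptom_map: pd.DataFrame,
    *,
    lag_days: float = DEFAULT_EXPOSURE_LAG_DAYS,
) -> TemporalityBasis:
    """Cross significant trends with drug exposure and expert knowledge.

    A triple (patient, drug, symptom) enters the basis iff the patient
    has a significant trend on some marker, the trend window's midpoint
    falls inside the drug's [start, end + lag] exposure interval, and the
    expert map links (marker, direction) to the symptom.

    ``exposures`` columns: patient_id, drug, start_date, end_date;
    ``marker_symptom_map`` columns: marker, direction, symptom.
    """
    exp = exposures.copy()
    exp["start_date"] = pd.to_datetime(exp["start_date"])
    exp["end_date"] = pd.to_datetime(exp["end_date"])
    if (exp["end_date"] < exp["start_date"]).any():
        bad = exp.loc[exp["end_date"] < exp["start_date"]].iloc[0]
        raise TemporalError(f"exposure with end before start for {bad['patient_id']!r}/{bad['drug']!r}")
    links: dict[tuple[str, str], list[str]] = {}
    for row in marker_symptom_map.itertuples(index=False):
        links.setdefault((row.marker, row.direction), []).append(row.symptom)

    triples: set[tuple[str, str, str]] = set()
    by_patient = dict(tuple(exp.groupby("patient_id", sort=False)))
    for series, result in trends:
        if result.direction == "none":
            continue
        symptoms = links.get((series.marker, result.direction))
        if not symptoms:
            continue
        windows = by_patient.get(series.patient_id)
        if windows is None:
            continue
        mid = series.midpoint_date
        for w in windows.itertuples(index=False):
            if w.start_date <= mid <= w.end_date + pd.Timedelta(days=lag_days):
                for s in symptoms:
                    triples.add((series.patient_id, w.drug, s))
    return TemporalityBasis(frozenset(triples))


def dep_temporal(patient_id: str, drug: str, symptom: str, basis: TemporalityBasis) -> int:
    """Temporal credibility component: 1 iff the record's triple is in the basis."""
    return 1 if (patient_id, drug, symptom) in basis else 0
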