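"""The per-record credibility index and its four dependency components.

Each candidate adverse-drug-reaction record z carries a component vector

    V(z) = (DepCausalStrength, DepCorrelation, DepEffectSize, DepTemporal)

- *DepCausalStrength*: posterior support of the drug->symptom arc in the
  Bayesian network structure samples (``bayesnet.dep_causal_strength``).
- *DepCorrelation*: 1 - p of the Pearson chi-square independence test on
  the record's disease x symptom contingency table.
- *DepEffectSize*: 1/n for n concurrently administered drugs -- a
  reaction that several drugs could explain is less believable than an
  isolated exposure.
- *DepTemporal*: binary membership of the record's (patient, drug,
  symptom) triple in the temporality basis (``temporal`` module).

The components are integrated by projecting onto the first eigenvector
e of their covariance matrix S = Var(V) -- the direction of maximum
variance -- and min-max rescaling the projection to [0, 1].  Records at
or below the first quartile of that normalised index form the
low-credibility zone.

``CredibilityIndexModel`` / ``CredibilityIndexResults`` expose the PCA
integration in the model/results idiom: the model holds the component
table, ``fit()`` performs the eigen-decomposition, and the results
object carries loadings, covariance, the normalised index, persisted
normalisation bounds for held-out records, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayesnet import ArcStrengthTable, dep_causal_strength
from .temporal import TemporalityBasis, dep_temporal

__all__ = [
    "COMPONENT_COLUMNS",
    "CredibilityError",
    "CredibilityIndexModel",
    "CredibilityIndexResults",
    "dep_correlation",
    "dep_effect_size",
    "assemble_components",
    "pca_integrate",
    "normalize_index",
    "low_credibility_cutoff",
]

COMPONENT_COLUMNS = (
    "dep_causal_strength",
    "dep_correlation",
    "dep_effect_size",
    "dep_temporal",
)

EIGENVALUE_TIE_TOL = 1e-9


class CredibilityError(ValueError):
    pass


def dep_correlation(contingency, *, direction: str = "one_minus_p") -> float:
    """Correlation component from the chi-square independence test.

    ``direction="one_minus_p"`` returns 1 - p (the implemented
    convention: strong disease-symptom association -> component near 1);
    ``direction="p"`` returns the p-value itself for the alternative
    reading in which unrejected independence should score high.
    No continuity correction is applied.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise CredibilityError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise CredibilityError("contingency counts must be non-negative")
    if table.sum() <= 0:
        raise CredibilityError("contingency table has zero grand total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CredibilityError("degenerate margin: a row or column sums to zero")
    if direction not in ("one_minus_p", "p"):
        raise CredibilityError(f"unknown correlation direction {direction!r}")
    res = stats.chi2_contingency(table, correction=False)
    p = float(res.pvalue)
    return 1.0 - p if direction == "one_minus_p" else p


def dep_effect_size(n_drugs: int) -> float:
    """Effect-size component 1/n over n concurrently administered drugs."""
    if n_drugs < 1:
        raise CredibilityError("no exposure: record lists zero concurrent drugs")
    return 1.0 / n_drugs


def assemble_components(
    records: pd.DataFrame,
    strength_table: ArcStrengthTable,
    contingencies: Mapping[tuple[str, str], object],
    temporality_basis: TemporalityBasis,
    *,
    undirected_strength: bool = False,
    correlation_direction: str = "one_minus_p",
) -> pd.DataFrame:
    """One component row per candidate record.

    ``records`` columns: record_id, patient_id, disease, drug, symptom,
    n_drugs.  ``contingencies`` maps (disease, symptom) to the 2x2
    patient-level count table used by the chi-square component.
    Component errors are re-raised with the record id attached.
    """
    corr_cache: dict[tuple[str, str], float] = {}
    rows = []
    for rec in records.itertuples(index=False):
        try:
            pair = (rec.disease, rec.symptom)
            if pair not in corr_cache:
                corr_cache[pair] = dep_correlation(
                    contingencies[pair], direction=correlation_direction
                )
            rows.append(
                {
                    "record_id": rec.record_id,
                    "dep_causal_strength": dep_causal_strength(
                        rec.drug, rec.symptom, strength_table, undirected=undirected_strength
                    ),
                    "dep_correlation": corr_cache[pair],
                    "dep_effect_size": dep_effect_size(int(rec.n_drugs)),
                    "dep_temporal": dep_temporal(
                        rec.patient_id, rec.drug, rec.symptom, temporality_basis
                    ),
                }
            )
        except (KeyError, ValueError) as exc:
            raise CredibilityError(f"record {rec.record_id!r}: {exc}") from exc
    return pd.DataFrame(rows, columns=("record_id",) + COMPONENT_COLUMNS)


def _first_eigenvector(cov: np.ndarray) -> np.ndarray:
    """Leading unit eigenvector, sign-fixed and tie-broken deterministically."""
    eigvals, eigvecs = np.linalg.eigh(cov)
    top = eigvals[-1]
    if top <= 0.0:
        raise CredibilityError("degenerate covariance: all components constant")
    tied = [i for i in range(len(eigvals)) if top - eigvals[i] <= EIGENVALUE_TIE_TOL]
    candidates = []
    for i in tied:
        e = eigvecs[:, i].copy()
        s = e.sum()
        if s < 0 or (s == 0 and next((x for x in e if x != 0), 1.0) < 0):
            e = -e
        candidates.append(tuple(e))
    return np.asarray(max(candidates))  # lexicographically larger among ties


@dataclass
class CredibilityIndexResults:
    """Fitted credibility index: loadings, covariance, normalised values."""

    loadings: np.ndarray
    covariance: np.ndarray
    columns: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    bounds: tuple[float, float]
    record_ids: np.ndarray | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def transform(self, components: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project held-out component rows and rescale with the fitted bounds."""
        x = _component_matrix(components, self.columns)
        if self.center is not None:
            x = (x - self.center) / self.scale
        raw = x @ self.loadings
        lo, hi = self.bounds
        return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)

    def low_credibility_cutoff(self) -> float:
        return low_credibility_cutoff(self.normalized)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"ic_pca_raw": self.raw, "ic_pca": self.normalized})
        if self.record_ids is not None:
            out.insert(0, "record_id", self.record_ids)
        return out

    def save(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "loadings": self.loadings.tolist(),
            "covariance": self.covariance.tolist(),
            "bounds": list(self.bounds),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def summary(self) -> str:
        lines = ["Credibility index (first principal component of the dependency components)"]
        lines.append(f"  records: {len(self.raw)}    explained direction loadings:")
        for c, e in zip(self.columns, self.loadings):
            lines.append(f"    {c:<22s} {e:+.4f}")
        lines.append(f"  raw range: [{self.bounds[0]:.4f}, {self.bounds[1]:.4f}]")
        lines.append(f"  low-credibility cutoff (first quartile): {self.low_credibility_cutoff():.4f}")
        return "\n".join(lines)


def _component_matrix(components, columns: Sequence[str]) -> np.ndarray:
    if isinstance(components, pd.DataFrame):
        return components.loc[:, list(columns)].to_numpy(dtype=float)
    x = np.asarray(components, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(columns):
        raise CredibilityError(f"component matrix must have {len(columns)} columns")
    return x


class CredibilityIndexModel:
    """PCA integration of the four dependency components.

    Parameters
    ----------
    components : DataFrame or (n, k) array
        One row per record.  A DataFrame may carry a ``record_id``
        column; the component columns default to the four canonical
        dependencies.
    standardize : bool
        Use the correlation rather than covariance matrix.
    """

    def __init__(
        self,
        components,
        columns: Sequence[str] = COMPONENT_COLUMNS,
        *,
        standardize: bool = False,
    ):
        self.columns = tuple(columns)
        self.record_ids = None
        if isinstance(components, pd.DataFrame) and "record_id" in components.columns:
            self.record_ids = components["record_id"].to_numpy()
        self.exog = _component_matrix(components, self.columns)
        if self.exog.shape[0] < 2:
            raise CredibilityError("PCA integration needs at least 2 records")
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CredibilityIndexModel":
        return cls(frame, **kwargs)

    def fit(self) -> CredibilityIndexResults:
        x = self.exog
        center = scale = None
        if self.standardize:
            sd = x.std(axis=0, ddof=1)
            if (sd == 0).all():
                raise CredibilityError("degenerate covariance: all components constant")
            center = x.mean(axis=0)
            scale = np.where(sd == 0, 1.0, sd)
            x = (x - center) / scale
        cov = np.cov(x, rowvar=False, ddof=1)
        e = _first_eigenvector(np.atleast_2d(cov))
        raw = x @ e
        normalized = normalize_index(raw)
        return CredibilityIndexResults(
            loadings=e,
            covariance=np.atleast_2d(cov),
            columns=self.columns,
            raw=raw,
            normalized=normalized,
            bounds=(float(raw.min()), float(raw.max())),
            record_ids=self.record_ids,
            center=center,
            scale=scale,
        )


def pca_integrate(components, columns: Sequence[str] = COMPONENT_COLUMNS) -> CredibilityIndexResults:
    """Functional form of ``CredibilityIndexModel(...).fit()``."""
    return CredibilityIndexModel(components, columns).fit()


def normalize_index(raw) -> np.ndarray:
    """Min-max rescale to [0, 1], order preserving."""
    x = np.asarray(raw, dtype=float)
    if x.size < 1 or not np.all(np.isfinite(x)):
        raise CredibilityError("normalisation needs at least one finite value")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise CredibilityError("constant index: max equals min")
    return (x - lo) / (hi - lo)


def low_credibility_cutoff(normalized) -> float:
    """First-quartile threshold of the normalised index (type-7 quantile)."""
    x = np.asarray(normalized, dtype=float)
    if x.size < 4:
        raise CredibilityError("quartile cutoff needs at least 4 values")
    return float(np.quantile(x, 0.25))
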