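"""Random-Forest evidence generation and fusion with leaflet knowledge.

A random forest trained on the candidate-record features produces class
probabilities; conditioning on the record's credibility index CI turns
them into a basic probability assignment

    m({k}) = CI * p_k,        m(Theta) = 1 - CI,

so a record the dependency analysis distrusts contributes mostly
ignorance.  The medicine-leaflet knowledge base supplies an independent
source: a known (drug, reaction) pair with source credibility c becomes
m({reaction}) = c, m(Theta) = 1 - c.  The two sources are pooled with
Dempster's rule and the fused belief per singleton is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dst import Frame, FusionResult, MassFunction, belief, dempster_combine

__all__ = [
    "EvidenceError",
    "LeafletKB",
    "FusedBelief",
    "train_bpa_model",
    "bpa_from_probabilities",
    "predict_bpa",
    "leaflet_mass",
    "fuse",
]

DEFAULT_FOREST_PARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
}


class EvidenceError(ValueError):
    pass


@dataclass
class LeafletKB:
    """Known (drug, reaction) pairs with a source credibility in [0, 1]."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self):
        for (d, r), c in self.entries.items():
            if not 0.0 <= c <= 1.0:
                raise EvidenceError(f"credibility {c} for ({d!r}, {r!r}) outside [0, 1]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LeafletKB":
        entries: dict[tuple[str, str], float] = {}
        for row in frame.itertuples(index=False):
            key = (row.drug, row.reaction)
            if key in entries:
                raise EvidenceError(f"duplicate leaflet entry {key!r}")
            entries[key] = float(row.credibility)
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "LeafletKB":
        return cls.from_frame(pd.read_csv(path))

    def credibility(self, drug: str, reaction: str) -> float | None:
        return self.entries.get((drug, reaction))


def train_bpa_model(
    features: pd.DataFrame,
    target: Sequence,
    seed: int,
    params: Mapping | None = None,
) -> RandomForestClassifier:
    """Fit the evidence-generating random forest (deterministic per seed)."""
    y = np.asarray(target)
    if len(features) != len(y):
        raise EvidenceError(f"feature rows ({len(features)}) != target length ({len(y)})")
    if len(features) < 20:
        raise EvidenceError("evidence model needs at least 20 records")
    if len(np.unique(y)) < 2:
        raise EvidenceError("target has a single class; evidence model needs >= 2")
    settings = dict(DEFAULT_FOREST_PARAMS)
    settings.update(params or {})
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **settings)
    model.fit(features.to_numpy(dtype=float), y)
    return model


def bpa_from_probabilities(
    probabilities: Sequence[float], classes: Sequence[str], ci: float, frame: Frame
) -> MassFunction:
    """CI-conditioned BPA: singleton masses CI * p_k, ignorance 1 - CI."""
    if not 0.0 <= ci <= 1.0:
        raise EvidenceError(f"credibility index {ci} outside [0, 1]")
    if set(classes) - set(frame.hypotheses):
        raise EvidenceError(
            f"classes {sorted(set(classes) - set(frame.hypotheses))!r} not in the frame"
        )
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (len(classes),):
        raise EvidenceError("probability vector length does not match classes")
    masses: dict[int, float] = {}
    for k, prob in zip(classes, p):
        if ci * prob > 0.0:
            masses[frame.mask([k])] = ci * float(prob)
    ignorance = 1.0 - ci
    if ignorance > 0.0:
        masses[frame.full_mask] = masses.get(frame.full_mask, 0.0) + ignorance
    return MassFunction(frame, masses)


def predict_bpa(
    model: RandomForestClassifier, features, ci: float, frame: Frame
) -> MassFunction:
    """BPA for one record from the fitted forest's class probabilities."""
    x = np.asarray(features, dtype=float).reshape(1, -1)
    probs = model.predict_proba(x)[0]
    return bpa_from_probabilities(probs, [str(c) for c in model.classes_], ci, frame)


def leaflet_mass(kb: LeafletKB, drug: str, symptom: str, frame: Frame) -> MassFunction:
    """External-source BPA; vacuous when the pair is not in the leaflet."""
    c = kb.credibility(drug, symptom)
    if c is None or c == 0.0:
        return MassFunction.vacuous(frame)
    masses = {frame.mask([symptom]): c}
    if c < 1.0:
        masses[frame.full_mask] = 1.0 - c
    return MassFunction(frame, masses)


@dataclass(frozen=True)
class FusedBelief:
    """Fusion outcome with the belief committed to each singleton."""

    fusion: FusionResult
    beliefs: dict[str, float]

    @property
    def conflict(self) -> float:
        return self.fusion.conflict


def fuse(bpa: MassFunction, external: MassFunction) -> FusedBelief:
    """Dempster-combine model evidence with an external source."""
    result = dempster_combine(bpa, external)
    beliefs = {h: belief(result.combined, [h]) for h in bpa.frame.hypotheses}
    return FusedBelief(result, beliefs)
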