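"""Dempster-Shafer evidence theory: frames, mass functions, combination.

A *frame of discernment* is the exhaustive set of mutually exclusive
hypotheses under consideration (e.g. the candidate causes of a symptom:
an adverse drug reaction, the underlying disease, or something else).
Evidence is expressed as a *basic probability assignment* (BPA, or mass
function) ``m`` that distributes one unit of belief over subsets of the
frame; mass on the whole frame encodes ignorance.  Independent sources
are pooled with Dempster's rule, the orthogonal sum normalised by the
conflict ``K`` between them, and unreliable sources are *discounted*:
their committed mass is scaled by a credibility in [0, 1] and the rest
moved to the frame.

Subsets are held internally as bitmasks over the frame's hypothesis
order, so set equality and intersection are exact integer operations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Frame",
    "MassFunction",
    "FusionResult",
    "DSTError",
    "EmptySetMassError",
    "NegativeMassError",
    "MassSumError",
    "SubsetError",
    "FrameMismatchError",
    "TotalConflictError",
    "validate_mass",
    "dempster_combine",
    "combine_all",
    "belief",
    "plausibility",
    "discount",
]

MASS_SUM_TOL = 1e-9
CONFLICT_TOL = 1e-12
PRUNE_TOL = 1e-15


class DSTError(ValueError):
    """Base class for evidence-theory errors."""


class EmptySetMassError(DSTError):
    """Positive mass assigned to the empty set."""


class NegativeMassError(DSTError):
    """A mass value outside [0, 1]."""


class MassSumError(DSTError):
    """Masses do not sum to one within tolerance."""


class SubsetError(DSTError):
    """A keyed subset is not contained in the frame."""


class FrameMismatchError(DSTError):
    """Two mass functions declared over different frames."""


class TotalConflictError(DSTError):
    """Sources are fully conflicting (K = 1); the orthogonal sum is undefined."""


@dataclass(frozen=True)
class Frame:
    """An ordered frame of discernment Theta = {h1, ..., hN}."""

    hypotheses: tuple[str, ...]

    def __init__(self, hypotheses: Iterable[str]):
        hyps = tuple(hypotheses)
        if not hyps:
            raise DSTError("frame must contain at least one hypothesis")
        if len(set(hyps)) != len(hyps):
            raise DSTError(f"hypothesis labels must be unique, got {hyps!r}")
        object.__setattr__(self, "hypotheses", hyps)

    def __len__(self) -> int:
        return len(self.hypotheses)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.hypotheses)) - 1

    def mask(self, subset: Iterable[str]) -> int:
        """Canonical bitmask of a subset given as hypothesis labels."""
        m = 0
        for label in subset:
            try:
                m |= 1 << self.hypotheses.index(label)
            except ValueError:
                raise SubsetError(
                    f"{label!r} is not a hypothesis of the frame {self.hypotheses!r}"
                ) from None
        return m

    def labels(self, mask: int) -> tuple[str, ...]:
        if mask < 0 or mask > self.full_mask:
            raise SubsetError(f"bitmask {mask} outside the frame's powerset")
        return tuple(h for i, h in enumerate(self.hypotheses) if mask >> i & 1)


def _as_mask(frame: Frame, subset: int | Iterable[str]) -> int:
    if isinstance(subset, int):
        if subset < 0 or subset > frame.full_mask:
            raise SubsetError(f"bitmask {subset} outside the frame's powerset")
        return subset
    return frame.mask(subset)


@dataclass(frozen=True)
class MassFunction:
    """A basic probability assignment over subsets of a frame.

    ``masses`` maps bitmask subsets to masses.  The three BPA axioms
    (range [0, 1], m(empty) = 0, total mass 1) are enforced on
    construction; masses whose sum is within ``MASS_SUM_TOL`` of one are
    renormalised exactly.
    """

    frame: Frame
    masses: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        cleaned: dict[int, float] = {}
        total = 0.0
        for subset, value in self.masses.items():
            mask = _as_mask(self.frame, subset)
            if value < 0.0 or value > 1.0 + MASS_SUM_TOL:
                raise NegativeMassError(f"mass {value} for {self.frame.labels(mask)!r} outside [0, 1]")
            if mask == 0 and value > 0.0:
                raise EmptySetMassError(f"mass on empty set must be 0, got {value}")
            if value > 0.0:
                cleaned[mask] = cleaned.get(mask, 0.0) + value
                total += value
        if abs(total - 1.0) > MASS_SUM_TOL:
            raise MassSumError(f"masses sum to {total!r} != 1")
        # renormalise within tolerance; deviations below fp resolution are
        # left untouched so that serialisation round-trips bit-exactly
        if abs(total - 1.0) > 1e-15:
            cleaned = {k: v / total for k, v in cleaned.items()}
        object.__setattr__(self, "masses", cleaned)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_labels(cls, frame: Frame, masses: Mapping[tuple[str, ...] | frozenset, float]) -> "MassFunction":
        return cls(frame, {frame.mask(subset): v for subset, v in masses.items()})

    @classmethod
    def vacuous(cls, frame: Frame) -> "MassFunction":
        """Total ignorance: all mass on the frame."""
        return cls(frame, {frame.full_mask: 1.0})

    # -- accessors ---------------------------------------------------------

    def mass(self, subset: int | Iterable[str]) -> float:
        return self.masses.get(_as_mask(self.frame, subset), 0.0)

    def focal_elements(self) -> dict[tuple[str, ...], float]:
        return {self.frame.labels(k): v for k, v in sorted(self.masses.items())}

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        enc = {}
        for mask, v in sorted(self.masses.items()):
            key = "*" if mask == self.frame.full_mask else "|".join(self.frame.labels(mask))
            enc[key] = v
        return json.dumps({"frame": list(self.frame.hypotheses), "masses": enc})

    @classmethod
    def from_json(cls, payload: str) -> "MassFunction":
        obj = json.loads(payload)
        frame = Frame(obj["frame"])
        masses = {}
        for key, v in obj["masses"].items():
            mask = frame.full_mask if key == "*" else frame.mask(key.split("|"))
            masses[mask] = v
        return cls(frame, masses)


@dataclass(frozen=True)
class FusionResult:
    """Outcome of an orthogonal sum: the combined BPA and the conflict K."""

    combined: MassFunction
    conflict: float


def validate_mass(m: MassFunction) -> MassFunction:
    """Re-assert the BPA axioms on ``m`` (they hold by construction)."""
    return MassFunction(m.frame, dict(m.masses))


def dempster_combine(m1: MassFunction, m2: MassFunction) -> FusionResult:
    """Dempster's rule: m(A) = sum_{B^C=A} m1(B) m2(C) / (1 - K).

    K is the total mass falling on empty intersections; the rule is
    undefined when the sources are fully conflicting (K = 1).
    """
    if m1.frame != m2.frame:
        raise FrameMismatchError(f"frames differ: {m1.frame.hypotheses!r} vs {m2.frame.hypotheses!r}")
    conflict = 0.0
    acc: dict[int, float] = {}
    for b, mb in m1.masses.items():
        for c, mc in m2.masses.items():
            inter = b & c
            w = mb * mc
            if inter == 0:
                conflict += w
            else:
                acc[inter] = acc.get(inter, 0.0) + w
    if conflict >= 1.0 - CONFLICT_TOL:
        raise TotalConflictError(f"sources fully conflicting (K = {conflict})")
    norm = 1.0 - conflict
    combined = {k: v / norm for k, v in acc.items() if v / norm > PRUNE_TOL}
    return FusionResult(MassFunction(m1.frame, combined), conflict)


def combine_all(masses: Iterable[MassFunction]) -> FusionResult:
    """Fuse several sources as a left fold of pairwise combinations.

    The normalised rule is associative and commutative, so the fold
    order only matters at floating-point level; the overall conflict
    reported is that of the final pairwise step.
    """
    it = iter(masses)
    try:
        acc = next(it)
    except StopIteration:
        raise DSTError("combine_all requires at least one mass function") from None
    result = FusionResult(acc, 0.0)
    for m in it:
        result = dempster_combine(result.combined, m)
    return result


def belief(m: MassFunction, subset: int | Iterable[str]) -> float:
    """Bel(A) = sum of masses of all subsets of A (minimum committed support)."""
    a = _as_mask(m.frame, subset)
    return math.fsum(v for k, v in m.masses.items() if k & ~a == 0)


def plausibility(m: MassFunction, subset: int | Iterable[str]) -> float:
    """Pl(A) = sum of masses of all subsets intersecting A."""
    a = _as_mask(m.frame, subset)
    return math.fsum(v for k, v in m.masses.items() if k & a != 0)


def discount(m: MassFunction, credibility: float) -> MassFunction:
    """Scale committed mass by a source credibility, moving the rest to Theta.

    m'(A) = c * m(A) for A != Theta and m'(Theta) = 1 - c + c * m(Theta),
    so credibility 1 leaves the source untouched and credibility 0 yields
    the vacuous (fully ignorant) BPA.
    """
    if not 0.0 <= credibility <= 1.0:
        raise DSTError(f"credibility {credibility} outside [0, 1]")
    full = m.frame.full_mask
    out = {k: credibility * v for k, v in m.masses.items() if k != full and credibility * v > 0.0}
    theta = 1.0 - credibility + credibility * m.masses.get(full, 0.0)
    if theta > 0.0:
        out[full] = theta
    return MassFunction(m.frame, out)
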