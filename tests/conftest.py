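import itertools

import numpy as np
import pandas as pd
import pytest

from credfuse.dst import Frame, MassFunction
from credfuse import synthetic


# ---------------------------------------------------------------------------
# independent brute-force oracle for Dempster's rule
# ---------------------------------------------------------------------------


def powerset(labels):
    out = []
    for r in range(len(labels) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(labels, r))
    return out


def brute_force_combine(labels, m1, m2):
    """Enumerate the full powerset-pair product over label frozensets.

    ``m1``/``m2`` map frozensets of labels to masses.  Returns
    (combined dict, conflict K).
    """
    subsets = powerset(labels)
    conflict = 0.0
    acc = {}
    for b in subsets:
        for c in subsets:
            w = m1.get(b, 0.0) * m2.get(c, 0.0)
            if w == 0.0:
                continue
            inter = b & c
            if inter:
                acc[inter] = acc.get(inter, 0.0) + w
            else:
                conflict += w
    combined = {k: v / (1.0 - conflict) for k, v in acc.items()}
    return combined, conflict


def random_mass_dict(labels, rng, max_focal=4):
    """A random valid BPA as a frozenset->mass dict."""
    candidates = [s for s in powerset(labels) if s]
    idx = rng.choice(len(candidates), size=min(max_focal, len(candidates)), replace=False)
    weights = rng.dirichlet(np.ones(len(idx)))
    return {candidates[i]: float(w) for i, w in zip(idx, weights) if w > 0}


def as_mass_function(labels, mass_dict):
    frame = Frame(labels)
    return MassFunction.from_labels(frame, {tuple(sorted(k)): v for k, v in mass_dict.items()})


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def john_paul():
    """The conflicting-doctors worked example: two BPAs on {ADR, DIS, OTH}."""
    frame = Frame(["ADR", "DIS", "OTH"])
    m1 = MassFunction.from_labels(frame, {("ADR",): 0.8, ("ADR", "DIS", "OTH"): 0.2})
    m2 = MassFunction.from_labels(
        frame, {("DIS",): 0.7, ("ADR",): 0.2, ("ADR", "DIS", "OTH"): 0.1}
    )
    return frame, m1, m2


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world for fast pipeline-level tests."""
    params = synthetic.WorldParams(seed=42, n_patients=200)
    world = synthetic.generate_world(params)
    records, prescriptions, registry = synthetic.generate_records(world, params)
    series = synthetic.generate_marker_series(world, prescriptions, params)
    return params, world, records, prescriptions, registry, series


@pytest.fixture(scope="session")
def small_components(small_world):
    from credfuse import pipeline

    params, world, records, prescriptions, registry, series = small_world
    components = pipeline.compute_components(
        records, registry, prescriptions, series, world.marker_symptom_map, params.seed,
        mcmc=pipeline.MCMCSettings(n_iter=800, burn_in=200),
    )
    return components
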