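"""Synthetic EHR generator with ground-truth causal structure.

Emulates the data-generating process the credibility analysis assumes:

- each patient has one disease and takes a small set of drugs
  (polypharmacy, truncated-Poisson count) over month-scale exposure
  windows inside a one-year horizon;
- a fixed fraction of (disease, symptom) pairs are *confounded*: the
  disease itself emits the symptom (mimicking an adverse reaction);
- a fixed fraction of (drug, symptom) pairs are *true ADRs*: exposure
  emits the symptom;
- background noise emits symptoms unrelated to either;
- a fraction of true ADR mechanisms act through a blood marker: exposed
  patients' series drift linearly during the exposure window, and an
  expert map links the (marker, direction) trend to the symptom.

Every emitted candidate record carries a hidden truth label in
{ADR, DISEASE, OTHER} used only for parameter-recovery evaluation.  All
randomness flows through ``numpy.random.default_rng`` seeded from the
single ``WorldParams.seed`` (per-stage child streams), so the same seed
reproduces every table bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .temporal import MarkerSeries

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "SyntheticError",
    "MARKER_PROFILES",
    "generate_world",
    "generate_records",
    "generate_marker_series",
    "export_ehr",
]

ORIGIN = pd.Timestamp("2019-01-01")

# marker name -> (baseline, observation noise sd), units typical of routine panels
MARKER_PROFILES = {
    "creatinine": (1.0, 0.10),   # mg/dL
    "glucose": (90.0, 8.0),      # mg/dL
    "urea": (30.0, 4.0),         # mg/dL
    "platelets": (250.0, 20.0),  # 10^9/L
    "leukocytes": (7.0, 0.8),    # 10^9/L
}

# |slope| * horizon / sd for drug-induced marker drift over a full year
TREND_SNR = 8.0
HORIZON_DAYS = 360


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class WorldParams:
    """Generating conditions for a synthetic ADR world."""

    seed: int
    n_patients: int = 1000
    n_diseases: int = 4
    n_drugs: int = 6
    n_symptoms: int = 5
    adr_rate: float = 0.2            # fraction of drug x symptom pairs that are true ADRs
    confound_rate: float = 0.3       # fraction of disease x symptom pairs the disease causes
    adr_prob: float = 0.4            # per-exposure emission probability of a true ADR
    confound_prob: float = 0.5       # per-patient emission probability of a confounded symptom
    noise_symptom_prob: float = 0.05  # per-patient background emission per symptom
    polypharmacy_mean: float = 2.5   # mean drugs per patient (truncated Poisson)
    polypharmacy_max: int = 6
    trend_fraction: float = 0.5      # fraction of true ADRs realised through a marker trend
    leaflet_coverage: float = 0.7    # fraction of true ADR pairs present in the leaflet KB

    def __post_init__(self):
        for name in (
            "adr_rate", "confound_rate", "adr_prob", "confound_prob",
            "noise_symptom_prob", "trend_fraction", "leaflet_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticError(f"{name} = {v} outside [0, 1]")
        for name in ("n_patients", "n_diseases", "n_drugs", "n_symptoms", "polypharmacy_max"):
            if getattr(self, name) < 1:
                raise SyntheticError(f"{name} must be >= 1")
        if self.adr_rate == 0 and self.confound_rate == 0 and self.noise_symptom_prob == 0:
            raise SyntheticError("no signal to generate: all emission channels are off")


@dataclass
class SyntheticWorld:
    """Sampled causal structure: who causes what, and through which marker."""

    diseases: list[str]
    drugs: list[str]
    symptoms: list[str]
    true_adr_pairs: frozenset
    confound_pairs: frozenset
    adr_prob: float
    confound_prob: float
    marker_effects: list[tuple[str, str, float]]  # (drug, marker, slope per day)
    marker_symptom_map: pd.DataFrame              # marker, direction, symptom
    leaflet: pd.DataFrame                         # drug, reaction, credibility
    params: WorldParams = field(repr=False, default=None)

    def drug_symptom_cpt(self) -> pd.DataFrame:
        """Emission table in the drug/reaction-yes/reaction-no dialect."""
        rows = [
            {
                "drug": d,
                "reaction_no": 1.0 - (self.adr_prob if (d, s) in self.true_adr_pairs else 0.0),
                "reaction_yes": self.adr_prob if (d, s) in self.true_adr_pairs else 0.0,
                "reaction": s,
            }
            for d in self.drugs
            for s in self.symptoms
        ]
        return pd.DataFrame(rows)

    def disease_symptom_cpt(self) -> pd.DataFrame:
        rows = [
            {
                "disease": d,
                "symptom_no": 1.0 - (self.confound_prob if (d, s) in self.confound_pairs else 0.0),
                "symptom_yes": self.confound_prob if (d, s) in self.confound_pairs else 0.0,
                "symptom": s,
            }
            for d in self.diseases
            for s in self.symptoms
        ]
        return pd.DataFrame(rows)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Sample the causal structure (ADR edges, confounders, marker effects)."""
    rng = _rng(0, params.seed)
    diseases = [f"disease_{i:02d}" for i in range(params.n_diseases)]
    drugs = [f"drug_{i:02d}" for i in range(params.n_drugs)]
    symptoms = [f"symptom_{i:02d}" for i in range(params.n_symptoms)]

    ds_pairs = [(d, s) for d in drugs for s in symptoms]
    n_adr = round(params.adr_rate * len(ds_pairs))
    adr_idx = rng.choice(len(ds_pairs), size=n_adr, replace=False)
    true_adr = frozenset(ds_pairs[i] for i in sorted(adr_idx))

    dis_pairs = [(d, s) for d in diseases for s in symptoms]
    n_conf = round(params.confound_rate * len(dis_pairs))
    conf_idx = rng.choice(len(dis_pairs), size=n_conf, replace=False)
    confound = frozenset(dis_pairs[i] for i in sorted(conf_idx))

    # marker-mediated ADR mechanisms: unique (marker, direction) slot per
    # pair, cycling through all markers before reusing one so that a drug
    # with several mechanisms never drives the same marker both ways
    markers = list(MARKER_PROFILES)
    slots = [(m, sign) for sign in (+1, -1) for m in markers]
    n_trend = round(params.trend_fraction * n_adr)
    trend_pairs = sorted(true_adr)[:n_trend]
    effects: list[tuple[str, str, float]] = []
    map_rows = []
    for i, (drug, symptom) in enumerate(trend_pairs):
        marker, sign = slots[i % len(slots)]
        sd = MARKER_PROFILES[marker][1]
        slope = sign * TREND_SNR * sd / HORIZON_DAYS
        effects.append((drug, marker, slope))
        map_rows.append(
            {
                "marker": marker,
                "direction": "increasing" if sign > 0 else "decreasing",
                "symptom": symptom,
            }
        )
    marker_symptom_map = pd.DataFrame(map_rows, columns=["marker", "direction", "symptom"])

    adr_sorted = sorted(true_adr)
    n_leaf = round(params.leaflet_coverage * len(adr_sorted))
    leaf_idx = sorted(rng.choice(len(adr_sorted), size=n_leaf, replace=False)) if adr_sorted else []
    leaflet = pd.DataFrame(
        [
            {
                "drug": adr_sorted[i][0],
                "reaction": adr_sorted[i][1],
                "credibility": round(float(rng.uniform(0.6, 0.95)), 4),
            }
            for i in leaf_idx
        ],
        columns=["drug", "reaction", "credibility"],
    )
    return SyntheticWorld(
        diseases, drugs, symptoms, true_adr, confound,
        params.adr_prob, params.confound_prob, effects, marker_symptom_map, leaflet, params,
    )


def generate_records(world: SyntheticWorld, params: WorldParams):
    """Emit the patient registry, prescriptions and labelled candidate records.

    Returns ``(records, prescriptions, registry)`` DataFrames; ``records``
    carries the generator-only ``truth`` column which ``export_ehr``
    strips into a separate ground-truth file.
    """
    rng = _rng(1, params.seed)
    registry_rows, prescription_rows, record_rows = [], [], []
    rec_k = 0
    confound_by_disease: dict[str, list[str]] = {}
    for d, s in sorted(world.confound_pairs):
        confound_by_disease.setdefault(d, []).append(s)
    adr_by_drug: dict[str, list[str]] = {}
    for d, s in sorted(world.true_adr_pairs):
        adr_by_drug.setdefault(d, []).append(s)

    for i in range(params.n_patients):
        pid = f"p{i:05d}"
        age = int(np.clip(rng.normal(58, 15), 18, 95))
        sex = "F" if rng.random() < 0.55 else "M"
        disease = world.diseases[rng.integers(len(world.diseases))]
        registry_rows.append({"patient_id": pid, "age": age, "sex": sex, "disease": disease})

        n_take = int(min(1 + rng.poisson(max(params.polypharmacy_mean - 1, 0.0)),
                         min(params.polypharmacy_max, len(world.drugs))))
        taken = [world.drugs[j] for j in sorted(rng.choice(len(world.drugs), size=n_take, replace=False))]
        windows = {}
        for drug in taken:
            start = int(rng.integers(0, 61))
            end = start + int(rng.integers(240, 301))
            windows[drug] = (start, min(end, HORIZON_DAYS))
            prescription_rows.append(
                {
                    "patient_id": pid,
                    "drug": drug,
                    "start_date": (ORIGIN + pd.Timedelta(days=windows[drug][0])).date().isoformat(),
                    "end_date": (ORIGIN + pd.Timedelta(days=windows[drug][1])).date().isoformat(),
                }
            )

        def emit(symptom, day, suspected, label):
            nonlocal rec_k
            concurrent = [d for d, (s0, s1) in windows.items() if s0 <= day <= s1]
            if suspected not in concurrent:
                concurrent.append(suspected)
            concurrent.sort()
            record_rows.append(
                {
                    "record_id": f"r{rec_k:06d}",
                    "patient_id": pid,
                    "disease": disease,
                    "drug": suspected,
                    "all_drugs": ";".join(concurrent),
                    "n_drugs": len(concurrent),
                    "symptom": symptom,
                    "date": (ORIGIN + pd.Timedelta(days=int(day))).date().isoformat(),
                    "truth": label,
                }
            )
            rec_k += 1

        # disease-confounded symptoms
        for symptom in confound_by_disease.get(disease, []):
            if rng.random() < world.confound_prob:
                drug = taken[rng.integers(len(taken))]
                s0, s1 = windows[drug]
                emit(symptom, rng.integers(s0, s1 + 1), drug, "DISEASE")
        # true adverse reactions
        for drug in taken:
            for symptom in adr_by_drug.get(drug, []):
                if rng.random() < world.adr_prob:
                    s0, s1 = windows[drug]
                    emit(symptom, rng.integers(s0 + 7, s1 + 1), drug, "ADR")
        # background noise
        for symptom in world.symptoms:
            if rng.random() < params.noise_symptom_prob:
                drug = taken[rng.integers(len(taken))]
                s0, s1 = windows[drug]
                emit(symptom, rng.integers(s0, s1 + 1), drug, "OTHER")

    records = pd.DataFrame(
        record_rows,
        columns=[
            "record_id", "patient_id", "disease", "drug", "all_drugs",
            "n_drugs", "symptom", "date", "truth",
        ],
    )
    prescriptions = pd.DataFrame(
        prescription_rows, columns=["patient_id", "drug", "start_date", "end_date"]
    )
    registry = pd.DataFrame(registry_rows, columns=["patient_id", "age", "sex", "disease"])
    return records, prescriptions, registry


def generate_marker_series(
    world: SyntheticWorld, prescriptions: pd.DataFrame, params: WorldParams
) -> list[MarkerSeries]:
    """Monthly lab panels per patient with drug-induced drift during exposure."""
    rng = _rng(2, params.seed)
    effects_by_drug: dict[str, list[tuple[str, float]]] = {}
    for drug, marker, slope in world.marker_effects:
        effects_by_drug.setdefault(drug, []).append((marker, slope))

    exposures: dict[str, list[tuple[str, int, int]]] = {}
    for row in prescriptions.itertuples(index=False):
        start = (pd.Timestamp(row.start_date) - ORIGIN).days
        end = (pd.Timestamp(row.end_date) - ORIGIN).days
        exposures.setdefault(row.patient_id, []).append((row.drug, start, end))

    out: list[MarkerSeries] = []
    for pid in sorted(exposures):
        for marker, (baseline, sd) in MARKER_PROFILES.items():
            days = np.arange(12) * 30 + rng.integers(-5, 6, size=12)
            days[0] = max(days[0], 0)
            values = baseline + rng.normal(0.0, sd, size=12)
            for drug, start, end in exposures[pid]:
                for m, slope in effects_by_drug.get(drug, []):
                    if m == marker:
                        # cumulative drift during exposure, persisting at its
                        # final level afterwards (no washout within the year)
                        drift = np.clip(days - start, 0.0, end - start)
                        values += slope * drift
            out.append(
                MarkerSeries(
                    patient_id=pid,
                    marker=marker,
                    times=(days - days[0]).astype(float),
                    values=values,
                    start_date=ORIGIN + pd.Timedelta(days=int(days[0])),
                )
            )
    return out


def export_ehr(
    world: SyntheticWorld,
    records: pd.DataFrame,
    prescriptions: pd.DataFrame,
    registry: pd.DataFrame,
    series: list[MarkerSeries],
    directory,
) -> dict[str, Path]:
    """Write the CSV/JSON file set the pipeline readers consume.

    The candidate table is written blind (no truth column); ground truth
    goes to a separate JSON next to the generating parameters.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    blind = records.drop(columns=["truth"], errors="ignore")
    paths["candidates"] = directory / "candidates.csv"
    blind.to_csv(paths["candidates"], index=False)
    paths["prescriptions"] = directory / "prescriptions.csv"
    prescriptions.to_csv(paths["prescriptions"], index=False)
    paths["registry"] = directory / "registry.csv"
    registry.to_csv(paths["registry"], index=False)
    paths["leaflet"] = directory / "leaflet_kb.csv"
    world.leaflet.to_csv(paths["leaflet"], index=False)
    paths["marker_symptom_map"] = directory / "marker_symptom_map.csv"
    world.marker_symptom_map.to_csv(paths["marker_symptom_map"], index=False)

    lab_rows = [
        {
            "patient_id": s.patient_id,
            "marker": s.marker,
            "date": (s.start_date + pd.Timedelta(days=float(t))).date().isoformat(),
            "value": v,
        }
        for s in series
        for t, v in zip(s.times, s.values)
    ]
    paths["labs"] = directory / "labs.csv"
    pd.DataFrame(lab_rows, columns=["patient_id", "marker", "date", "value"]).to_csv(
        paths["labs"], index=False
    )

    truth = {"labels": dict(zip(records["record_id"], records.get("truth", "")))}
    if world.params is not None:
        truth["params"] = asdict(world.params)
    truth["true_adr_pairs"] = sorted(map(list, world.true_adr_pairs))
    truth["confound_pairs"] = sorted(map(list, world.confound_pairs))
    paths["ground_truth"] = directory / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def load_marker_series(labs: pd.DataFrame) -> list[MarkerSeries]:
    """Rebuild per-patient marker series from the labs CSV dialect."""
    labs = labs.copy()
    labs["date"] = pd.to_datetime(labs["date"])
    out = []
    for (pid, marker), grp in labs.groupby(["patient_id", "marker"], sort=True):
        grp = grp.sort_values("date")
        start = grp["date"].iloc[0]
        out.append(
            MarkerSeries(
                patient_id=pid,
                marker=marker,
                times=(grp["date"] - start).dt.days.to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                start_date=start,
            )
        )
    return out
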