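"""End-to-end orchestration: components, scenarios, benchmark, fusion.

The benchmark mirrors the method's evaluation protocol: the same random
forest is trained on three nested feature sets --

- ``base``: demographics, disease, symptom and binary drug-exposure
  indicators;
- ``base_ci``: base plus the correlation, effect-size and temporal
  credibility components and their PCA index;
- ``base_ci_bayes``: the above plus the Bayesian arc-strength component
  and the full four-component PCA index --

and judged by accuracy and macro precision/recall under stratified
k-fold cross-validation, repeated over independently generated worlds.
The target is the record's true cause {ADR, DISEASE, OTHER}, which the
synthetic generator knows; the paper's private-data analogue predicts
reactions, but cause discrimination is the claim the credibility index
exists to support, and only the simulator has ground truth for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import bayesnet, credibility, evidence, synthetic, temporal
from .dst import Frame, MassFunction, TotalConflictError

__all__ = [
    "SCENARIOS",
    "PipelineError",
    "MetricsReport",
    "patient_level_table",
    "contingency_tables",
    "compute_strength_table",
    "compute_components",
    "scenario_features",
    "compute_metrics",
    "run_benchmark",
    "run_fusion",
]

SCENARIOS = ("base", "base_ci", "base_ci_bayes")
CAUSE_FRAME = ("ADR", "DISEASE", "OTHER")


class PipelineError(ValueError):
    pass


@dataclass
class MCMCSettings:
    n_iter: int = 2000
    burn_in: int = 500
    max_parents: int = 3
    undirected_strength: bool = True  # MCMC rarely resolves Markov-equivalent orientations


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------


def patient_level_table(
    registry: pd.DataFrame, prescriptions: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """One row per patient: disease, drug-exposure and symptom indicators.

    Column names are the drug/symptom vocabulary itself so that arcs of
    the learned network can be looked up by name.
    """
    table = registry.set_index("patient_id")[["disease"]].copy()
    for drug in sorted(prescriptions["drug"].unique()):
        exposed = set(prescriptions.loc[prescriptions["drug"] == drug, "patient_id"])
        table[drug] = [1 if p in exposed else 0 for p in table.index]
    for symptom in sorted(records["symptom"].unique()):
        having = set(records.loc[records["symptom"] == symptom, "patient_id"])
        table[symptom] = [1 if p in having else 0 for p in table.index]
    return table.reset_index()


def contingency_tables(
    patient_table: pd.DataFrame, diseases: Iterable[str], symptoms: Iterable[str]
) -> dict[tuple[str, str], np.ndarray]:
    """2x2 patient counts (disease present/absent x symptom present/absent)."""
    out = {}
    dis = patient_table["disease"]
    for d in diseases:
        has_d = (dis == d).to_numpy()
        for s in symptoms:
            if s not in patient_table.columns:
                continue
            has_s = patient_table[s].to_numpy().astype(bool)
            out[(d, s)] = np.array(
                [
                    [int((has_d & has_s).sum()), int((has_d & ~has_s).sum())],
                    [int((~has_d & has_s).sum()), int((~has_d & ~has_s).sum())],
                ]
            )
    return out


def compute_strength_table(
    patient_table: pd.DataFrame, seed: int, settings: MCMCSettings = MCMCSettings()
) -> bayesnet.ArcStrengthTable:
    """Arc strengths from MCMC structure samples over the patient table."""
    samples = bayesnet.sample_structures_mcmc(
        patient_table.drop(columns=["patient_id"]),
        n_iter=settings.n_iter,
        burn_in=settings.burn_in,
        seed=seed,
        max_parents=settings.max_parents,
    )
    nodes = [c for c in patient_table.columns if c != "patient_id"]
    return bayesnet.arc_strength(samples, nodes=nodes)


def compute_components(
    records: pd.DataFrame,
    registry: pd.DataFrame,
    prescriptions: pd.DataFrame,
    series: Sequence[temporal.MarkerSeries],
    marker_symptom_map: pd.DataFrame,
    seed: int,
    *,
    mcmc: MCMCSettings = MCMCSettings(),
    alpha: float = temporal.DEFAULT_ALPHA,
    lag_days: float = temporal.DEFAULT_EXPOSURE_LAG_DAYS,
    correlation_direction: str = "one_minus_p",
) -> pd.DataFrame:
    """All four dependency components for every candidate record."""
    table = patient_level_table(registry, prescriptions, records)
    strength = compute_strength_table(table, seed, mcmc)
    conts = contingency_tables(table, registry["disease"].unique(), records["symptom"].unique())
    trends = []
    for s in series:
        if len(s.times) >= temporal.MIN_OBSERVATIONS and np.ptp(s.times) > 0:
            trends.append((s, temporal.fit_trend(s, alpha=alpha)))
    basis = temporal.build_temporality_basis(
        trends, prescriptions, marker_symptom_map, lag_days=lag_days
    )
    return credibility.assemble_components(
        records,
        strength,
        conts,
        basis,
        undirected_strength=mcmc.undirected_strength,
        correlation_direction=correlation_direction,
    )


def _base_features(records: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    # Covariates X only: demographics, polypharmacy, symptom and drug
    # indicators.  The disease code is the external factor W; it reaches
    # the model through the dependency components of the later scenarios.
    reg = registry.set_index("patient_id")
    feats = pd.DataFrame(index=records.index)
    feats["age"] = records["patient_id"].map(reg["age"]).astype(float)
    feats["sex_f"] = (records["patient_id"].map(reg["sex"]) == "F").astype(float)
    feats["n_drugs"] = records["n_drugs"].astype(float)
    for s in sorted(records["symptom"].unique()):
        feats[f"symptom={s}"] = (records["symptom"] == s).astype(float)
    drugs = sorted({d for lst in records["all_drugs"] for d in lst.split(";")})
    exploded = records["all_drugs"].str.split(";")
    for d in drugs:
        feats[f"drug={d}"] = exploded.map(lambda lst: d in lst).astype(float)
    return feats


def scenario_features(
    records: pd.DataFrame, registry: pd.DataFrame, components: pd.DataFrame, scenario: str
) -> pd.DataFrame:
    """Feature matrix for one benchmark scenario (feature sets are nested)."""
    if scenario not in SCENARIOS:
        raise PipelineError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    feats = _base_features(records, registry)
    if scenario == "base":
        return feats
    comp = components.set_index("record_id").loc[records["record_id"]].reset_index(drop=True)
    comp.index = records.index
    no_bayes = ("dep_correlation", "dep_effect_size", "dep_temporal")
    feats[list(no_bayes)] = comp[list(no_bayes)]
    feats["ic_pca"] = credibility.CredibilityIndexModel(comp, columns=no_bayes).fit().normalized
    if scenario == "base_ci_bayes":
        feats["dep_causal_strength"] = comp["dep_causal_strength"]
        feats["ic_pca_full"] = credibility.CredibilityIndexModel(comp).fit().normalized
    return feats


# ---------------------------------------------------------------------------
# metrics and benchmark
# ---------------------------------------------------------------------------


def compute_metrics(y_true: Sequence, y_pred: Sequence, *, average: str = "macro") -> dict:
    """Accuracy and averaged precision/recall from the confusion matrix."""
    from sklearn.metrics import accuracy_score, precision_score, recall_score

    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise PipelineError("empty label vector")
    if len(y_true) != len(y_pred):
        raise PipelineError(f"length mismatch: {len(y_true)} labels vs {len(y_pred)} predictions")
    labels = sorted(set(y_true) | set(y_pred))
    per_class = {
        lab: {
            "precision": float(precision_score(y_true, y_pred, labels=[lab], average=None, zero_division=0)[0]),
            "recall": float(recall_score(y_true, y_pred, labels=[lab], average=None, zero_division=0)[0]),
        }
        for lab in labels
    }
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, average=average, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, average=average, zero_division=0)),
        "per_class": per_class,
    }


@dataclass
class MetricsReport:
    """Per-seed and aggregated benchmark metrics with relative improvements."""

    per_seed: pd.DataFrame  # seed, scenario, accuracy, precision, recall
    baseline: str = "base"

    def summary(self) -> pd.DataFrame:
        rows = []
        means = self.per_seed.groupby("scenario", sort=False)[["accuracy", "precision", "recall"]]
        mean, std = means.mean(), means.std(ddof=1)
        base = mean.loc[self.baseline]
        for scenario in self.per_seed["scenario"].unique():
            row = {"scenario": scenario}
            for m in ("accuracy", "precision", "recall"):
                row[m] = mean.loc[scenario, m]
                row[f"{m}_sd"] = std.loc[scenario, m] if len(self.per_seed["seed"].unique()) > 1 else 0.0
                row[f"improve_{m}"] = (mean.loc[scenario, m] - base[m]) / base[m]
            rows.append(row)
        return pd.DataFrame(rows)

    def paired_pvalue(self, metric: str, scenario: str, *, against: str | None = None) -> float:
        """One-sided paired t-test that ``scenario`` beats the baseline on ``metric``."""
        against = against or self.baseline
        wide = self.per_seed.pivot(index="seed", columns="scenario", values=metric)
        a, b = wide[scenario], wide[against]
        if len(a) < 2:
            raise PipelineError("paired test needs >= 2 seeds")
        return float(stats.ttest_rel(a, b, alternative="greater").pvalue)


def _cv_predict(features: pd.DataFrame, y: np.ndarray, folds: int, seed: int, forest_params) -> np.ndarray:
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise PipelineError(
            f"class {counts.idxmin()!r} has {counts.min()} record(s); cannot stratify"
        )
    n_splits = int(min(folds, counts.min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    x = features.to_numpy(dtype=float)
    pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(x, y):
        model = evidence.train_bpa_model(features.iloc[train], y[train], seed, forest_params)
        pred[test] = model.predict(x[test])
    return pred


def run_benchmark(
    params: synthetic.WorldParams,
    *,
    scenarios: Sequence[str] = SCENARIOS,
    n_seeds: int = 10,
    folds: int = 5,
    mcmc: MCMCSettings = MCMCSettings(),
    forest_params: Mapping | None = None,
) -> MetricsReport:
    """Repeat generate -> components -> stratified-CV forest over seeds.

    Each repetition re-draws an entire synthetic world from
    ``params.seed + k`` so the comparison averages over causal
    structures, not just over data noise.
    """
    if len(scenarios) < 2:
        raise PipelineError("benchmark needs at least 2 scenarios")
    if n_seeds < 1:
        raise PipelineError("n_seeds must be >= 1")
    rows = []
    for k in range(n_seeds):
        seed_k = params.seed + k
        p = synthetic.WorldParams(**{**params.__dict__, "seed": seed_k})
        world = synthetic.generate_world(p)
        records, prescriptions, registry = synthetic.generate_records(world, p)
        series = synthetic.generate_marker_series(world, prescriptions, p)
        components = compute_components(
            records, registry, prescriptions, series, world.marker_symptom_map, seed_k, mcmc=mcmc
        )
        y = records["truth"].to_numpy()
        for scenario in scenarios:
            feats = scenario_features(records, registry, components, scenario)
            pred = _cv_predict(feats, y, folds, seed_k, forest_params)
            m = compute_metrics(y, pred)
            rows.append(
                {
                    "seed": seed_k,
                    "scenario": scenario,
                    "accuracy": m["accuracy"],
                    "precision": m["precision"],
                    "recall": m["recall"],
                }
            )
    return MetricsReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# fusion stage
# ---------------------------------------------------------------------------


def _external_mass(
    kb: evidence.LeafletKB, drug: str, symptom: str, frame: Frame, frame_mode: str
) -> MassFunction:
    if frame_mode == "symptom":
        return evidence.leaflet_mass(kb, drug, symptom, frame)
    c = kb.credibility(drug, symptom)
    if c is None or c == 0.0:
        return MassFunction.vacuous(frame)
    masses = {frame.mask(["ADR"]): c}
    if c < 1.0:
        masses[frame.full_mask] = 1.0 - c
    return MassFunction(frame, masses)


def run_fusion(
    records: pd.DataFrame,
    registry: pd.DataFrame,
    components: pd.DataFrame,
    kb: evidence.LeafletKB,
    seed: int,
    *,
    scenario: str = "base_ci_bayes",
    frame_mode: str = "cause",
    forest_params: Mapping | None = None,
    prune_low_ci: bool = False,
) -> pd.DataFrame:
    """Per-record fused beliefs: RF evidence discounted by CI, pooled with the leaflet.

    Records whose fusion fails (total conflict) are flagged, not dropped;
    ``prune_low_ci`` drops records at or below the first-quartile index
    before training, reproducing the low-credibility cut.
    """
    if frame_mode not in ("cause", "symptom"):
        raise PipelineError(f"unknown frame_mode {frame_mode!r}")
    target_col = "truth" if frame_mode == "cause" else "symptom"
    if target_col not in records.columns:
        raise PipelineError(f"run_fusion needs a {target_col!r} column to train the evidence model")
    comp = components.set_index("record_id").loc[records["record_id"]].reset_index(drop=True)
    comp.index = records.index
    ci = credibility.CredibilityIndexModel(comp).fit()
    index = pd.Series(ci.normalized, index=records.index)
    cutoff = ci.low_credibility_cutoff()

    keep = records.index if not prune_low_ci else records.index[index > cutoff]
    feats = scenario_features(records, registry, components, scenario)
    if frame_mode == "symptom":  # the symptom is the target, not a feature
        feats = feats.drop(columns=[c for c in feats.columns if c.startswith("symptom=")])
    y = records[target_col].to_numpy()
    model = evidence.train_bpa_model(feats.loc[keep], y[records.index.get_indexer(keep)], seed, forest_params)
    classes = [str(c) for c in model.classes_]
    frame = Frame(classes)

    probs = model.predict_proba(feats.to_numpy(dtype=float))
    rows = []
    for i, rec in enumerate(records.itertuples(index=False)):
        bpa = evidence.bpa_from_probabilities(probs[i], classes, float(index.iloc[i]), frame)
        external = _external_mass(kb, rec.drug, rec.symptom, frame, frame_mode)
        row = {
            "record_id": rec.record_id,
            "ci": float(index.iloc[i]),
            "low_credibility": bool(index.iloc[i] <= cutoff),
            "conflict": np.nan,
            "flagged": False,
        }
        try:
            fused = evidence.fuse(bpa, external)
            row["conflict"] = fused.conflict
            for h, b in fused.beliefs.items():
                row[f"bel_{h}"] = b
        except TotalConflictError:
            row["flagged"] = True
            for h in frame.hypotheses:
                row[f"bel_{h}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
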