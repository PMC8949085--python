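# credfuse

Credibility-conditioned Dempster–Shafer evidence fusion for
adverse-drug-reaction (ADR) signal discrimination in electronic health
records.

## The problem

When a patient on medication reports a symptom, three explanations
compete: the drug caused it (a true ADR), the underlying disease caused
it (confounding by indication), or it is unrelated noise. Classifiers
trained on raw EHR features conflate the first two, because the disease
that motivated the prescription often produces the very symptoms that
mimic reactions. `credfuse` scores each candidate (patient, drug,
symptom) record with a *credibility index* built from four dependency
analyses, and uses that score to temper machine-generated evidence
before fusing it with pharmacological knowledge.

## The model

Evidence lives on a frame of discernment Θ (e.g. {ADR, DISEASE, OTHER})
as a basic probability assignment m: 2^Θ → [0, 1] with m(∅) = 0 and
Σ_A m(A) = 1. Belief is Bel(A) = Σ_{X⊆A} m(X). Two independent sources
combine by Dempster's rule,

    (m₁ ⊕ m₂)(A) = Σ_{B∩C=A} m₁(B) m₂(C) / (1 − K),
    K = Σ_{B∩C=∅} m₁(B) m₂(C),

where K is the conflict between them.

Each candidate record z carries the component vector
V(z) = (DepCausalStrength, DepCorrelation, DepEffectSize, DepTemporal):

- **DepCausalStrength** — posterior support of the drug→symptom arc,
  the fraction of DAG structures containing it in an MCMC sample from
  the BDeu posterior over discrete Bayesian networks of the
  disease/drug/symptom variables;
- **DepCorrelation** — 1 − p from the Pearson chi-square independence
  test on the record's disease × symptom contingency table;
- **DepEffectSize** — 1/n for n concurrently administered drugs;
- **DepTemporal** — 1 iff a statistically significant lab-marker trend
  (OLS of marker value on time, two-sided test of β₁ = 0 at α = 0.05)
  overlaps the drug's exposure window and is expert-linked to the
  symptom.

The index is the projection onto the first eigenvector e of
S = Var(V),

    IC-PCA(z) = e₁·DepCausalStrength + e₂·DepCorrelation
              + e₃·DepEffectSize + e₄·DepTemporal,

min–max normalised to [0, 1]; records at or below the first quartile
form the low-credibility zone. A random forest produces class
probabilities p_k per record which become the conditioned BPA
m({k}) = CI·p_k, m(Θ) = 1 − CI, and that BPA is fused with medicine
leaflet knowledge (m({reaction}) = c for a known pair with source
credibility c) by Dempster's rule.

Because real hospital EHRs are private, the package ships a synthetic
generator with ground-truth causal structure (true ADR pairs,
disease-confounded symptoms, polypharmacy, drug-induced marker
trends), so every stage is testable by parameter recovery.

## Worked example

```python
from credfuse import Frame, MassFunction, dempster_combine, belief, plausibility

frame = Frame(["ADR", "DIS", "OTH"])
doctor_a = MassFunction.from_labels(frame, {("ADR",): 0.8, ("ADR", "DIS", "OTH"): 0.2})
doctor_b = MassFunction.from_labels(frame, {("DIS",): 0.7, ("ADR",): 0.2,
                                            ("ADR", "DIS", "OTH"): 0.1})
result = dempster_combine(doctor_a, doctor_b)
```

Doctor A gives the drug an 80% chance of having caused the bleeding and
leaves 20% open; doctor B blames the disease at 70%, the drug at 20%.
The orthogonal sum prints:

```
conflict K = 0.56
m(ADR) = 0.6364
m(DIS) = 0.3182
m(ADR|DIS|OTH) = 0.0455
Bel(ADR) = 0.6364
Pl(ADR)  = 0.6818
```

More than half the joint mass (K = 0.56) fell on contradictions and was
renormalised away; the pooled view backs the drug at 64% committed
belief with 68% plausibility.

Fitting the credibility index on a simulated cohort:

```python
from credfuse import (WorldParams, generate_world, generate_records,
                      generate_marker_series, CredibilityIndexModel)
from credfuse.pipeline import compute_components

params = WorldParams(seed=7, n_patients=300)
world = generate_world(params)
records, prescriptions, registry = generate_records(world, params)
series = generate_marker_series(world, prescriptions, params)
components = compute_components(records, registry, prescriptions, series,
                                world.marker_symptom_map, seed=7)
print(CredibilityIndexModel(components).fit().summary())
```

```
Credibility index (first principal component of the dependency components)
  records: 617    explained direction loadings:
    dep_causal_strength    +0.5038
    dep_correlation        -0.2715
    dep_effect_size        -0.0910
    dep_temporal           +0.8150
  raw range: [-0.3624, 1.2580]
  low-credibility cutoff (first quartile): 0.0600
```

The index loads positively on the causal-arc and temporal evidence and
negatively on the disease–symptom correlation: records whose symptom is
well explained by the disease score low. The cutoff 0.06 bounds the
low-credibility quartile for this cohort (it is recomputed per dataset,
never hard-coded).

The same stages are scriptable from the shell:

```sh
credfuse simulate --seed 7 --out ehr/
credfuse ci --seed 7 --data ehr/ --out components.csv
credfuse benchmark --seed 7 --out bench.csv
credfuse fuse --seed 7 --data ehr/ --components components.csv --out fused.csv
```

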