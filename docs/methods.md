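# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `credfuse`, and what the synthetic
experiments do and do not establish.

## Evidence calculus

Subsets of a frame of discernment are held as bitmasks over the frame's
hypothesis order, so set operations are exact and mass-map lookups never
depend on label ordering. The three BPA axioms are enforced at
construction: masses in [0, 1], zero mass on the empty set, and total
mass 1 within 1e-9 (sums inside that tolerance but beyond 1e-15 are
renormalised; deviations below floating-point resolution are left
untouched so JSON serialisation round-trips bit-exactly). Dempster
combination refuses to normalise when the conflict K reaches 1 within
1e-12 — fully contradictory sources have no orthogonal sum. Masses below
1e-15 are pruned after combination to keep focal sets sparse. Fusion of
more than two sources is a left fold of pairwise combinations; the
normalised rule is associative and commutative, so fold order matters
only at floating-point level. Discounting by a credibility c scales all
committed mass by c and moves 1 − c to the frame, so c = 1 is the
identity and c = 0 total ignorance.

## Bayesian network and arc strength

Networks over the disease/drug/symptom indicators are discrete and
small by design; inference is exact enumeration and no approximate
engine is provided. CPTs are Laplace-smoothed relative frequencies
(one pseudo-count per cell) so small strata never produce hard zeros.

Structure uncertainty is explored with a Metropolis–Hastings walk over
DAGs scored by the BDeu marginal likelihood with equivalent sample size
10 — the standard score for discrete networks when no prior structure
knowledge exists. Proposals are keyed by a uniformly drawn ordered node
pair: an existing edge is deleted or reversed with probability 1/2
each, a free pair proposes an addition, and the factor-two asymmetry
between add and delete proposal probabilities enters the Hastings
ratio. Moves creating a cycle or exceeding the parent cap (3 by
default, since drug/disease/symptom networks are sparse) are rejected
in place, so the chain never visits an invalid graph. Acceptance uses
only the score differences of the one or two families a move touches,
making the walk invariant to any constant added to the score and cheap
per iteration. The chain starts from the empty graph; every post-burn-in
state contributes one sample (thinning 1). The pipeline default is
2 000 iterations with 500 burn-in per cohort, enough for the ~12-node
patient tables used here; both numbers are configuration values.

Arc strength is the sampled frequency of an edge. Because Markov
equivalence often leaves the orientation of an adjacency undetermined,
the pipeline reads strength *undirected* by default (sum of both
orientations, capped at 1) while the directed lookup remains available.
The causal credibility component is the strength of the record's
drug→symptom arc; the disease→symptom strength is available separately
through the same table should a consumer want it as a penalty.

## Credibility components

- **Correlation.** The chi-square independence test (no continuity
  correction) on the 2×2 patient-level disease × symptom table. The
  component is 1 − p: a strong disease–symptom association scores near
  one. The opposite reading (credibility = p, "independence not
  rejected means the disease is not the explanation") is defensible;
  it is exposed as `direction="p"` but the 1 − p convention is the
  implemented default. Degenerate margins raise rather than guess.
- **Effect size.** 1/n over the n drugs whose exposure windows contain
  the symptom date — a reaction several drugs could explain is less
  believable than an isolated exposure.
- **Temporal.** Per patient × marker series, OLS of value on days since
  first observation; two-sided t-test of zero slope at α = 0.05
  (equivalently the regression F-test with one numerator df). Series
  need at least three observations and non-constant times; shorter
  series simply contribute no temporal evidence rather than erroring.
  A significant trend supports a (patient, drug, symptom) triple when
  the trend window's midpoint lies inside [exposure start, exposure
  end + 30 days] and an expert-supplied (marker, direction) → symptom
  map links them. The map is an explicit CSV input, never inferred.
  No multiplicity correction is applied across the patient × marker
  tests: each series is per-record evidence, not a family-wise
  discovery procedure; a Benjamini–Hochberg hook would be a natural
  extension but is deliberately off.

## PCA integration

The index projects the component matrix onto the first eigenvector of
its covariance matrix — covariance, not correlation, so components with
more variance carry more weight; `standardize=True` switches to the
correlation matrix. The eigenvector sign is fixed by requiring a
non-negative coordinate sum (first non-zero coordinate positive on a
zero sum), and eigenvalue ties within 1e-9 are broken by the
lexicographically larger oriented eigenvector, making the fit
deterministic. Normalisation is min–max over the fitted batch; the
bounds persist with the loadings so held-out records are mapped with
the training bounds and clipped to [0, 1]. The low-credibility zone is
bounded by the first quartile (type-7 linear-interpolation quantile,
the common default) of the normalised index, recomputed per dataset.

## Evidence generation and fusion

The evidence model is a random forest (500 trees, sqrt features per
split, fixed seed) — enough trees that per-seed variance is small at
these data sizes. During evaluation, probabilities come from stratified
5-fold cross-validation so masses are never optimistic in-sample; at
inference the full model is used. Generated BPAs put mass only on
singletons and the frame (m({k}) = CI·p_k, m(Θ) = 1 − CI); composite
focal sets remain fully supported for external sources. The credibility
index enters both as m(Θ) = 1 − CI and as a feature of the forest; each
path can be disabled. The frame is either the cause set
{ADR, DISEASE, OTHER} (default — this is what the synthetic ground
truth labels) or the symptom vocabulary (`frame_mode="symptom"`).
Leaflet knowledge contributes m({supported hypothesis}) = c,
m(Θ) = 1 − c for a known (drug, reaction) pair with source credibility
c; absent pairs contribute vacuous evidence. Records whose fusion is
fully conflicting are flagged and reported, never silently dropped.

## Synthetic worlds

The generator emulates the statistical structure the method assumes:
one disease per patient; a truncated-Poisson number of drugs
(mean 2.5, max 6) with month-scale exposure windows inside a one-year
horizon; symptoms emitted by the disease (confounded pairs, emission
probability 0.5), by exposure to a true-ADR drug (probability 0.4), or
as background noise (0.05 per symptom) — emission probabilities in the
range of published drug-reaction conditional-probability tables. With
the default vocabulary (6 drugs × 5 symptoms, 4 diseases), 20% of
drug–symptom pairs are true ADRs and 30% of disease–symptom pairs are
confounded, so confounding is strong enough that base features alone
cannot separate causes. Half of the true ADR mechanisms act through a
blood marker: exposed patients' series (five routine markers with
realistic baselines and noise, sampled monthly with jitter) drift
linearly during exposure to a cumulative amplitude of eight noise
standard deviations per year and plateau afterwards — no washout within
the observation year. The leaflet knowledge base covers 70% of true ADR
pairs with source credibilities drawn from U(0.6, 0.95), so fusion is
testable on both covered and uncovered reactions. All randomness flows
through per-stage child streams of one seed; identical seeds reproduce
every table bit for bit.

What the generator does **not** emulate: comorbidities (one disease per
patient), free-text clinical notes, dose–response and washout
pharmacokinetics, correlated marker panels, measurement dropout, and
coding errors. Passing recovery tests therefore shows the pipeline
exploits the dependency structure it models, not that it is robust to
everything real EHR data contains.

## Benchmark protocol

Three nested feature sets: `base` (age, sex, polypharmacy count,
symptom and drug indicators — the covariates X), `base_ci` (plus
correlation, effect-size and temporal components and their
three-component PCA index), `base_ci_bayes` (plus arc strength and the
full four-component index). The disease code is deliberately absent
from `base`: it is the external factor W whose influence the dependency
components are supposed to capture, and that separation is what the
benchmark measures. The target is the record's true cause. Metrics are
accuracy and macro-averaged precision/recall (micro available) under
stratified 5-fold cross-validation, repeated over ten independently
regenerated worlds (seeds s, s+1, …); improvements are relative to
`base` and scenario comparisons use one-sided paired t-tests across
seeds. At these sizes (1 000 patients, ≈2 000 candidate records per
world) the full protocol runs in a few minutes on one CPU; the
acceptance script uses exactly these sizes.

## Known limitations

- Arc strength is a structure-sample frequency, not a causal effect
  size; with few MCMC samples it is coarse-grained.
- The 1 − p correlation component saturates at 1 for any strong
  association regardless of effect size.
- Min–max normalisation is sensitive to single extreme records; a
  robust (quantile-based) alternative is not implemented.
- The temporality basis links trends to symptoms only through the
  expert map; unmapped mechanisms are invisible to DepTemporal.
- Exact inference limits networks to a handful of variables; the
  pipeline's patient tables stay within that by construction.
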