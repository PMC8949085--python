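"""Discrete Bayesian networks over disease/drug/symptom variables.

Two roles.  First, a small exact engine: conditional probability tables
(CPTs) estimated from categorical records with Laplace smoothing, the
chain-rule joint P(X1..Xn) = prod_i P(Xi | parents(Xi)), and conditional
queries by full enumeration (the networks here are small by design).

Second, structure uncertainty: a Metropolis-Hastings walk over DAGs
scored by the BDeu marginal likelihood.  The per-edge *arc strength* --
the fraction of sampled structures containing an edge -- is the causal
component of the credibility index: a drug->symptom arc that survives in
most sampled structures is strong evidence that the association is not
an artefact of the disease confounder.

Proposals are single-edge moves keyed by an ordered node pair (u, v):
if u->v exists the move deletes or reverses it (probability 1/2 each),
if neither direction exists the move adds u->v, and pairs whose reverse
edge exists propose nothing.  Add and delete proposal probabilities
differ by a factor two, which enters the Hastings ratio; cyclic or
over-parented proposals are rejected in place, so the chain never
visits an invalid graph.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DiscreteBayesNet",
    "ArcStrengthTable",
    "BayesNetError",
    "fit_cpts",
    "joint_probability",
    "conditional_query",
    "bdeu_score",
    "sample_structures_mcmc",
    "arc_strength",
    "dep_causal_strength",
]

DEFAULT_ESS = 10.0
DEFAULT_MAX_PARENTS = 3


class BayesNetError(ValueError):
    pass


@dataclass
class DiscreteBayesNet:
    """A discrete Bayesian network: nodes, DAG edges and per-node CPTs.

    ``cpts[v]`` has shape ``(*parent_cardinalities, cardinality_of_v)``
    with parent axes in ``parents[v]`` order; each row (fixed parent
    configuration) sums to one.
    """

    states: dict[str, tuple]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise BayesNetError("edge set contains a cycle")
        for v, cpt in self.cpts.items():
            rows = cpt.reshape(-1, len(self.states[v]))
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise BayesNetError(f"CPT rows for {v!r} do not sum to 1")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.states)

    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset((p, v) for v, ps in self.parents.items() for p in ps)

    def lookup(self, node: str, assignment: Mapping[str, object]) -> float:
        """P(node = assignment[node] | parent values from assignment)."""
        idx = []
        for p in self.parents[node]:
            idx.append(self.states[p].index(assignment[p]))
        try:
            idx.append(self.states[node].index(assignment[node]))
        except ValueError:
            raise BayesNetError(f"unknown state {assignment[node]!r} for node {node!r}") from None
        return float(self.cpts[node][tuple(idx)])

    # CSV dialect: parent_node, parent_state, node, state, probability,
    # with multiple parents joined by '|'.
    def to_csv(self, path) -> None:
        rows = []
        for v in self.nodes:
            ps = self.parents[v]
            cards = [len(self.states[p]) for p in ps]
            for cfg in itertools.product(*(range(c) for c in cards)):
                for k, s in enumerate(self.states[v]):
                    rows.append({
                        "parent_node": "|".join(ps),
                        "parent_state": "|".join(str(self.states[p][j]) for p, j in zip(ps, cfg)),
                        "node": v,
                        "state": s,
                        "probability": float(self.cpts[v][cfg + (k,)]),
                    })
        pd.DataFrame(rows, columns=["parent_node", "parent_state", "node", "state", "probability"]).to_csv(
            path, index=False
        )


def _check_dag(edges: Iterable[tuple[str, str]], columns: Sequence[str]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(columns)
    for u, v in edges:
        if u not in columns or v not in columns:
            raise BayesNetError(f"edge ({u!r}, {v!r}) references a node absent from the data")
        g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise BayesNetError("edge set contains a cycle")
    return g


def fit_cpts(data: pd.DataFrame, dag: Iterable[tuple[str, str]], alpha: float = 1.0) -> DiscreteBayesNet:
    """Estimate CPTs as Laplace-smoothed relative frequencies.

    With ``alpha`` pseudo-counts per cell the estimate for a binary node
    observed 51 times out of 100 is (51+1)/(100+2); small strata in
    EHR-like data never yield hard zeros.
    """
    if data.empty:
        raise BayesNetError("data is empty")
    g = _check_dag(dag, list(data.columns))
    states = {c: tuple(sorted(data[c].unique().tolist())) for c in data.columns}
    parents = {v: tuple(sorted(g.predecessors(v))) for v in data.columns}
    cpts = {}
    for v in data.columns:
        ps = parents[v]
        card = len(states[v])
        cards = tuple(len(states[p]) for p in ps)
        counts = np.zeros(cards + (card,))
        codes = [pd.Categorical(data[p], categories=states[p]).codes for p in ps]
        vcode = pd.Categorical(data[v], categories=states[v]).codes
        np.add.at(counts, tuple(codes) + (vcode,), 1.0)
        counts += alpha
        cpts[v] = counts / counts.sum(axis=-1, keepdims=True)
    return DiscreteBayesNet(states, parents, cpts)


def joint_probability(net: DiscreteBayesNet, assignment: Mapping[str, object]) -> float:
    """Chain rule: product of CPT lookups along the full assignment."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise BayesNetError(f"assignment missing nodes {sorted(missing)!r}")
    p = 1.0
    for v in net.nodes:
        p *= net.lookup(v, assignment)
    return p


def conditional_query(
    net: DiscreteBayesNet, target: str, evidence: Mapping[str, object] | None = None
) -> dict:
    """Exact P(target | evidence) by summing the joint over hidden nodes."""
    evidence = dict(evidence or {})
    if target not in net.nodes:
        raise BayesNetError(f"unknown target node {target!r}")
    for v, s in evidence.items():
        if v not in net.nodes or s not in net.states[v]:
            raise BayesNetError(f"invalid evidence {v!r}={s!r}")
    hidden = [v for v in net.nodes if v != target and v not in evidence]
    scores = {}
    for t_state in net.states[target]:
        total = 0.0
        for cfg in itertools.product(*(net.states[h] for h in hidden)):
            assignment = dict(evidence)
            assignment[target] = t_state
            assignment.update(zip(hidden, cfg))
            total += joint_probability(net, assignment)
        scores[t_state] = total
    z = sum(scores.values())
    if z <= 0.0:
        raise BayesNetError("impossible evidence (zero marginal probability)")
    return {s: v / z for s, v in scores.items()}


# ---------------------------------------------------------------------------
# BDeu scoring and MCMC over structures
# ---------------------------------------------------------------------------


def _encode(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = list(data.columns)
    codes = np.empty((len(data), len(cols)), dtype=np.int64)
    cards = np.empty(len(cols), dtype=np.int64)
    for j, c in enumerate(cols):
        cat = pd.Categorical(data[c])
        if len(cat.categories) < 2:
            raise BayesNetError(f"column {c!r} is constant; structure learning needs variation")
        codes[:, j] = cat.codes
        cards[j] = len(cat.categories)
    return codes, cards, cols


def _family_score(codes: np.ndarray, cards: np.ndarray, v: int, pa: tuple[int, ...], ess: float) -> float:
    """BDeu local marginal-likelihood score of node v with parent set pa."""
    r = int(cards[v])
    q = int(np.prod([cards[p] for p in pa])) if pa else 1
    idx = codes[:, v].copy()
    mult = r
    for p in pa:
        idx += mult * codes[:, p]
        mult *= int(cards[p])
    counts = np.bincount(idx, minlength=q * r).reshape(q, r).astype(float)
    a_j = ess / q
    a_jk = ess / (q * r)
    n_j = counts.sum(axis=1)
    score = np.sum(gammaln(a_j) - gammaln(a_j + n_j))
    score += np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    return float(score)


def bdeu_score(data: pd.DataFrame, edges: Iterable[tuple[str, str]], ess: float = DEFAULT_ESS) -> float:
    """Total BDeu score of a DAG (sum of family scores)."""
    codes, cards, cols = _encode(data)
    index = {c: j for j, c in enumerate(cols)}
    parents: dict[int, list[int]] = {j: [] for j in range(len(cols))}
    for u, v in edges:
        parents[index[v]].append(index[u])
    _check_dag(edges, cols)
    return sum(
        _family_score(codes, cards, v, tuple(sorted(pa)), ess) for v, pa in parents.items()
    )


def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    """DFS reachability src -> dst along directed edges."""
    stack, seen = [src], {src}
    while stack:
        node = stack.pop()
        if node == dst:
            return True
        for nxt in children[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def sample_structures_mcmc(
    data: pd.DataFrame,
    n_iter: int,
    burn_in: int,
    seed: int,
    *,
    ess: float = DEFAULT_ESS,
    max_parents: int = DEFAULT_MAX_PARENTS,
) -> list[frozenset[tuple[str, str]]]:
    """Metropolis-Hastings walk over DAG structures under the BDeu posterior.

    Starts from the empty graph; every post-burn-in state contributes one
    edge-set sample (thinning 1).  Acceptance uses score *differences* of
    the one or two families a move touches, so the walk is invariant to
    any constant added to the score.  Deterministic given ``seed``.
    """
    if n_iter <= burn_in:
        raise BayesNetError(f"n_iter ({n_iter}) must exceed burn_in ({burn_in})")
    if burn_in < 0:
        raise BayesNetError("burn_in must be >= 0")
    codes, cards, cols = _encode(data)
    n = len(cols)
    if n < 2:
        raise BayesNetError("structure learning needs at least 2 variables")
    rng = np.random.default_rng(seed)

    parent_masks = [0] * n  # bitmask of parents per node
    children: list[set[int]] = [set() for _ in range(n)]
    cache: dict[tuple[int, int], float] = {}

    def fam(v: int, mask: int) -> float:
        key = (v, mask)
        if key not in cache:
            pa = tuple(p for p in range(n) if mask >> p & 1)
            cache[key] = _family_score(codes, cards, v, pa, ess)
        return cache[key]

    node_score = [fam(v, 0) for v in range(n)]
    log2 = np.log(2.0)
    samples: list[frozenset[tuple[str, str]]] = []

    pairs = rng.integers(0, n, size=(n_iter, 2))
    coin = rng.random(n_iter)
    unif = rng.random(n_iter)

    for it in range(n_iter):
        u, v = int(pairs[it, 0]), int(pairs[it, 1])
        if u != v:
            has_uv = parent_masks[v] >> u & 1
            has_vu = parent_masks[u] >> v & 1
            if has_uv:
                if coin[it] < 0.5:  # delete u -> v
                    new_mask = parent_masks[v] & ~(1 << u)
                    delta = fam(v, new_mask) - node_score[v]
                    if np.log(unif[it]) < delta + log2:  # reverse proposal is an add
                        parent_masks[v] = new_mask
                        children[u].discard(v)
                        node_score[v] = fam(v, new_mask)
                else:  # reverse u -> v to v -> u
                    if bin(parent_masks[u]).count("1") < max_parents:
                        children[u].discard(v)
                        cyclic = _has_path(children, u, v)
                        children[u].add(v)
                        if not cyclic:
                            mv = parent_masks[v] & ~(1 << u)
                            mu = parent_masks[u] | (1 << v)
                            delta = fam(v, mv) - node_score[v] + fam(u, mu) - node_score[u]
                            if np.log(unif[it]) < delta:
                                parent_masks[v], parent_masks[u] = mv, mu
                                children[u].discard(v)
                                children[v].add(u)
                                node_score[v], node_score[u] = fam(v, mv), fam(u, mu)
            elif not has_vu:  # add u -> v
                if bin(parent_masks[v]).count("1") < max_parents and not _has_path(children, v, u):
                    new_mask = parent_masks[v] | (1 << u)
                    delta = fam(v, new_mask) - node_score[v]
                    if np.log(unif[it]) < delta - log2:  # reverse proposal is a delete
                        parent_masks[v] = new_mask
                        children[u].add(v)
                        node_score[v] = fam(v, new_mask)
        if it >= burn_in:
            samples.append(
                frozenset(
                    (cols[p], cols[c]) for c in range(n) for p in range(n) if parent_masks[c] >> p & 1
                )
            )
    return samples


@dataclass
class ArcStrengthTable:
    """Per-edge posterior support: the fraction of sampled DAGs containing it."""

    entries: dict[tuple[str, str], float]
    n_samples: int
    nodes: frozenset[str] = field(default_factory=frozenset)

    def strength(self, u: str, v: str, *, undirected: bool = False) -> float:
        if u not in self.nodes or v not in self.nodes:
            raise BayesNetError(f"unknown node in arc ({u!r}, {v!r})")
        s = self.entries.get((u, v), 0.0)
        if undirected:
            s = min(1.0, s + self.entries.get((v, u), 0.0))
        return s

    def to_json(self, path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "nodes": sorted(self.nodes),
            "entries": [{"from": u, "to": v, "strength": s} for (u, v), s in sorted(self.entries.items())],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ArcStrengthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {(e["from"], e["to"]): e["strength"] for e in payload["entries"]},
            payload["n_samples"],
            frozenset(payload["nodes"]),
        )


def arc_strength(
    samples: Sequence[frozenset[tuple[str, str]]], nodes: Iterable[str] | None = None
) -> ArcStrengthTable:
    """Edge frequencies over MCMC structure samples.

    ``nodes`` declares the variable set when it is wider than the union
    of sampled edges (a never-connected node still has strength 0).
    """
    if not samples:
        raise BayesNetError("no structure samples")
    counts: dict[tuple[str, str], int] = {}
    seen: set[str] = set() if nodes is None else set(nodes)
    for s in samples:
        for e in s:
            counts[e] = counts.get(e, 0) + 1
            seen.update(e)
    n = len(samples)
    return ArcStrengthTable({e: c / n for e, c in counts.items()}, n, frozenset(seen))


def dep_causal_strength(
    drug: str, symptom: str, table: ArcStrengthTable, *, undirected: bool = False
) -> float:
    """Causal credibility component: posterior support of the drug->symptom arc."""
    return table.strength(drug, symptom, undirected=undirected)
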