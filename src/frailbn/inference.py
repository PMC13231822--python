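"""Maximum-likelihood CPT estimation and exact inference by variable elimination.

Factors are dense ndarrays with one axis per scope variable.  Evidence is
incorporated by slicing, variables are summed out in a min-fill order
(lexicographic tie-break, deterministic), and posteriors are normalized;
evidence with zero joint probability raises rather than returning NaN.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import CPT, NetworkSpec, NetworkValidationError
from .synthetic import Cohort

logger = logging.getLogger(__name__)


class ZeroEvidenceError(ValueError):
    """The supplied evidence has zero probability under the model."""


@dataclass
class Factor:
    """A non-negative table over the state product of ``scope``."""

    scope: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.scope = tuple(self.scope)
        self.table = np.asarray(self.table, dtype=float)
        if len(set(self.scope)) != len(self.scope):
            raise ValueError("factor scope variables must be distinct")
        if self.table.ndim != len(self.scope):
            raise ValueError("factor table rank must equal scope length")
        if np.any(self.table < 0):
            raise ValueError("factor values must be non-negative")


def _multiply(a: Factor, b: Factor) -> Factor:
    """Product of two factors over the union of their scopes."""
    scope = list(a.scope) + [v for v in b.scope if v not in a.scope]
    ta = a.table.reshape(a.table.shape + (1,) * (len(scope) - len(a.scope)))
    tb = b.table.reshape(b.table.shape + (1,) * (len(scope) - len(b.scope)))
    tb = np.moveaxis(
        tb, list(range(len(b.scope))), [scope.index(v) for v in b.scope]
    )
    return Factor(tuple(scope), ta * tb)


def _sum_out(factor: Factor, var: str) -> Factor:
    axis = factor.scope.index(var)
    scope = factor.scope[:axis] + factor.scope[axis + 1 :]
    return Factor(scope, factor.table.sum(axis=axis))


def _restrict(factor: Factor, evidence: Mapping[str, int]) -> Factor:
    """Slice evidence variables down to their observed state index."""
    index: list = []
    scope = []
    for axis, var in enumerate(factor.scope):
        if var in evidence:
            index.append(evidence[var])
        else:
            index.append(slice(None))
            scope.append(var)
    return Factor(tuple(scope), factor.table[tuple(index)])


def model_factors(spec: NetworkSpec) -> list[Factor]:
    """One factor per categorical node: P(node | parents)."""
    factors = []
    for node in spec.categorical_nodes:
        cpt = spec.cpts[node]
        factors.append(Factor(cpt.parent_order + (node,), spec.cpt_matrix(node)))
    return factors


def min_fill_order(
    factors: Sequence[Factor], keep: Iterable[str] = ()
) -> list[str]:
    """Min-fill elimination order with lexicographic tie-break."""
    keep = set(keep)
    adj: dict[str, set[str]] = {}
    for f in factors:
        for v in f.scope:
            adj.setdefault(v, set()).update(u for u in f.scope if u != v)
    order: list[str] = []
    remaining = sorted(v for v in adj if v not in keep)
    while remaining:
        best, best_fill = None, None
        for v in remaining:
            neigh = [u for u in adj[v] if u in adj]
            fill = sum(
                1
                for a, b in itertools.combinations(neigh, 2)
                if b not in adj[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        neigh = [u for u in adj[best] if u in adj]
        for a, b in itertools.combinations(neigh, 2):
            adj[a].add(b)
            adj[b].add(a)
        for u in adj[best]:
            adj[u].discard(best)
        del adj[best]
        order.append(best)
        remaining.remove(best)
    return order


def eliminate(
    factors: Sequence[Factor],
    query: str,
    evidence: Mapping[str, int] | None = None,
    order: Sequence[str] | None = None,
) -> np.ndarray:
    """Posterior distribution of ``query`` given index-coded ``evidence``.

    ``evidence`` maps variable names to *state indices*; use
    :func:`posterior` for a label-level interface on a NetworkSpec.
    """
    evidence = dict(evidence or {})
    if query in evidence:
        raise ValueError("query variable cannot also be evidence")
    work = [_restrict(f, evidence) for f in factors]
    hidden = {v for f in work for v in f.scope} - {query}
    if order is None:
        order = min_fill_order(work, keep=[query])
    else:
        order = [v for v in order if v in hidden]
    for var in order:
        bucket = [f for f in work if var in f.scope]
        work = [f for f in work if var not in f.scope]
        if not bucket:
            continue
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _multiply(prod, f)
        work.append(_sum_out(prod, var))
    result = Factor((), np.ones(()))
    for f in work:
        result = _multiply(result, f)
    if result.scope != (query,):
        raise ValueError(
            f"query {query!r} not determined by the factors (scope {result.scope})"
        )
    total = float(result.table.sum())
    if total <= 0.0:
        raise ZeroEvidenceError("evidence has zero probability under the model")
    return result.table / total


def posterior(
    spec: NetworkSpec, query: str, evidence: Mapping[str, str] | None = None
) -> pd.Series:
    """P(query | evidence) with evidence given as state labels."""
    ev_idx: dict[str, int] = {}
    for var, state in (evidence or {}).items():
        states = spec.states_of(var)
        if state not in states:
            raise NetworkValidationError(f"{var}: unknown state {state!r}")
        ev_idx[var] = states.index(state)
    dist = eliminate(model_factors(spec), query, ev_idx)
    return pd.Series(dist, index=list(spec.states_of(query)), name=query)


def fit_cpts(
    data: Cohort | pd.DataFrame,
    spec: NetworkSpec,
    dag_edges: Sequence[tuple[str, str]] | None = None,
    pseudocount: float = 0.0,
) -> dict[str, CPT]:
    """Maximum-likelihood (optionally Laplace-smoothed) CPTs from data.

    ``spec`` supplies node names and state spaces; ``dag_edges`` overrides
    the spec's edge set (e.g. a learned structure).  Each row equals
    ``(count + pseudocount) / (total + pseudocount * n_states)``; with
    ``pseudocount=0`` an unobserved parent configuration yields a uniform
    row and a logged warning.
    """
    frame = data.records if isinstance(data, Cohort) else data
    edges = list(spec.edges) if dag_edges is None else [tuple(e) for e in dag_edges]
    nodes = spec.categorical_nodes
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise NetworkValidationError("dag_edges contain a cycle")

    out: dict[str, CPT] = {}
    for node in nodes:
        parents = tuple(sorted(g.predecessors(node)))
        states = spec.states_of(node)
        k = len(states)
        rows: dict[tuple[str, ...], np.ndarray] = {}
        counts: dict[tuple[str, ...], np.ndarray] = {}
        grouped: dict[tuple[str, ...], np.ndarray] = {}
        if parents:
            table = (
                frame.groupby(list(parents) + [node], observed=False)
                .size()
                .unstack(node, fill_value=0)
                .reindex(columns=list(states), fill_value=0)
            )
            for config, row in table.iterrows():
                key = (config,) if len(parents) == 1 else tuple(config)
                grouped[key] = row.to_numpy(dtype=float)
        else:
            vc = frame[node].value_counts()
            grouped[()] = np.array([float(vc.get(s, 0)) for s in states])
        for config in itertools.product(*(spec.states_of(p) for p in parents)):
            c = grouped.get(config, np.zeros(k))
            total = c.sum() + pseudocount * k
            if total == 0:
                logger.warning(
                    "CPT[%s]%r: unobserved parent configuration, using uniform row",
                    node,
                    config,
                )
                rows[config] = np.full(k, 1.0 / k)
            else:
                rows[config] = (c + pseudocount) / total
            counts[config] = c
        out[node] = CPT(node, parents, rows, counts=counts)
    return out


def conditional_table(
    spec: NetworkSpec, node: str, given: Sequence[str] | None = None
) -> pd.DataFrame:
    """P(node | each configuration of ``given``) by exact inference.

    ``given`` defaults to the node's parents, in which case the result
    equals the node's CPT.  Conditioning variables may be any ancestor set.
    """
    given = tuple(given) if given is not None else spec.parents(node)
    factors = model_factors(spec)
    records = []
    for config in itertools.product(*(spec.states_of(v) for v in given)):
        ev = {
            v: spec.states_of(v).index(s) for v, s in zip(given, config)
        }
        dist = eliminate(factors, node, ev)
        records.append(dict(zip(given, config)) | dict(zip(spec.states_of(node), dist)))
    return pd.DataFrame(records)


def predict_proba(
    spec: NetworkSpec,
    cohort: Cohort | pd.DataFrame,
    target: str | None = None,
) -> np.ndarray:
    """Per-record posterior P(target = yes | observed variables).

    Evidence is every categorical model variable present in the cohort
    except the target; identical evidence rows are deduplicated before
    inference.  Unknown state labels raise with the offending record index.
    """
    frame = cohort.records if isinstance(cohort, Cohort) else cohort
    target = target if target is not None else spec.outcome
    ev_vars = [
        v for v in spec.categorical_nodes if v != target and v in frame.columns
    ]
    if len(frame) == 0:
        return np.empty(0)
    for var in ev_vars:
        states = set(spec.states_of(var))
        bad = ~frame[var].isin(states)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise NetworkValidationError(
                f"record {idx}: unseen state {frame[var].iloc[idx]!r} for {var!r}"
            )
    factors = model_factors(spec)
    yes_idx = spec.states_of(target).index("yes")
    encoded = np.column_stack(
        [
            frame[v].map({s: i for i, s in enumerate(spec.states_of(v))}).to_numpy()
            for v in ev_vars
        ]
    ).astype(np.int64)
    unique, inverse = np.unique(encoded, axis=0, return_inverse=True)
    probs = np.empty(len(unique))
    for i, row in enumerate(unique):
        ev = dict(zip(ev_vars, (int(x) for x in row)))
        probs[i] = eliminate(factors, target, ev)[yes_idx]
    return probs[inverse]


def with_cpts(spec: NetworkSpec, cpts: Mapping[str, CPT]) -> NetworkSpec:
    """A copy of ``spec`` re-parameterized (and re-wired) by ``cpts``."""
    edges = [
        (p, node) for node, cpt in cpts.items() for p in cpt.parent_order
    ]
    new = NetworkSpec(
        list(spec.variables), edges, dict(cpts), metadata=dict(spec.metadata)
    )
    new.validate()
    return new
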