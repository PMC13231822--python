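"""Hybrid Bayesian-network structure learning (max-min hill climbing).

Constraint phase: G-squared conditional-independence tests drive a max-min
parents-and-children (MMPC) skeleton search.  Score phase: greedy
hill climbing over add/delete/reverse moves restricted to the skeleton
(plus whitelisted edges), maximizing a decomposable BIC, never violating
the blacklist or acyclicity.  All tie-breaking is deterministic: candidate
order is lexicographic, moves are enumerated add < delete < reverse.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import CyclicGraphError, dag_from_edges
from .synthetic import Cohort

#: default significance level of the CI tests
DEFAULT_ALPHA = 0.05

#: default cap on the conditioning-set size (tractability guard)
DEFAULT_MAX_COND = 3

#: default cap on parents per node during hill climbing
DEFAULT_MAX_PARENTS = 5

#: minimum score gain accepted as an improvement (guards fp noise)
_SCORE_EPS = 1e-9


class ConstraintError(ValueError):
    """Whitelist/blacklist constraints are inconsistent."""


@dataclass(frozen=True)
class EdgeConstraints:
    """Expert edge edits: edges that must appear and edges that must not."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "whitelist", frozenset(map(tuple, self.whitelist)))
        object.__setattr__(self, "blacklist", frozenset(map(tuple, self.blacklist)))
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ConstraintError(f"edges both white- and blacklisted: {sorted(overlap)}")
        nodes = {v for e in self.whitelist for v in e}
        try:
            dag_from_edges(nodes, self.whitelist)
        except CyclicGraphError as exc:
            raise ConstraintError("whitelist alone is cyclic") from exc


@dataclass
class CITestRecord:
    pair: tuple[str, str]
    conditioning: tuple[str, ...]
    statistic: float
    df: int
    p: float


@dataclass
class LearnedStructure:
    """Result of a structure-learning run."""

    edges: list[tuple[str, str]]
    score: float
    skeleton: dict[str, set[str]]
    ci_test_log: list[CITestRecord] = field(default_factory=list)

    def graph(self) -> nx.DiGraph:
        nodes = set(self.skeleton) | {v for e in self.edges for v in e}
        return dag_from_edges(nodes, self.edges)


class _Encoded:
    """Integer-coded categorical data with a G-squared test cache."""

    def __init__(self, data: Cohort | pd.DataFrame, variables: Sequence[str] | None = None):
        frame = data.records if isinstance(data, Cohort) else data
        if variables is None:
            variables = [
                c
                for c in frame.columns
                if not pd.api.types.is_numeric_dtype(frame[c])
            ]
        self.variables: list[str] = list(variables)
        self.n = len(frame)
        self.codes: dict[str, np.ndarray] = {}
        self.cards: dict[str, int] = {}
        for v in self.variables:
            levels = sorted(frame[v].dropna().unique())
            mapping = {s: i for i, s in enumerate(levels)}
            self.codes[v] = frame[v].map(mapping).to_numpy(dtype=np.int64)
            self.cards[v] = len(levels)
        self._g2_cache: dict = {}
        self._family_cache: dict = {}
        self.ci_log: list[CITestRecord] = []

    # -- G-squared CI test -------------------------------------------------

    def g2(self, x: str, y: str, z: Iterable[str] = ()) -> tuple[float, int, float]:
        z = tuple(sorted(z))
        key = (min(x, y), max(x, y), z)
        hit = self._g2_cache.get(key)
        if hit is not None:
            return hit
        r, c = self.cards[x], self.cards[y]
        zcard = 1
        zcode = np.zeros(self.n, dtype=np.int64)
        for v in z:
            zcode = zcode * self.cards[v] + self.codes[v]
            zcard *= self.cards[v]
        joint = (zcode * r + self.codes[x]) * c + self.codes[y]
        counts = np.bincount(joint, minlength=zcard * r * c).reshape(zcard, r, c)
        totals = counts.sum(axis=(1, 2))
        stat = 0.0
        df = 0
        for s in np.flatnonzero(totals):
            obs = counts[s]
            rows = obs.sum(axis=1, keepdims=True)
            cols = obs.sum(axis=0, keepdims=True)
            expected = rows * cols / totals[s]
            nz = obs > 0
            stat += 2.0 * float((obs[nz] * np.log(obs[nz] / expected[nz])).sum())
            df += (r - 1) * (c - 1)
        p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
        result = (stat, df, p)
        self._g2_cache[key] = result
        self.ci_log.append(CITestRecord((x, y), z, stat, df, p))
        return result

    # -- decomposable BIC --------------------------------------------------

    def family_score(self, node: str, parents: Iterable[str]) -> float:
        parents = tuple(sorted(parents))
        key = (node, parents)
        hit = self._family_cache.get(key)
        if hit is not None:
            return hit
        k = self.cards[node]
        pcard = 1
        pcode = np.zeros(self.n, dtype=np.int64)
        for v in parents:
            pcode = pcode * self.cards[v] + self.codes[v]
            pcard *= self.cards[v]
        joint = pcode * k + self.codes[node]
        counts = np.bincount(joint, minlength=pcard * k).reshape(pcard, k)
        totals = counts.sum(axis=1)
        nz = counts > 0
        ll = float(
            (counts[nz] * np.log(counts[nz] / totals[:, None].repeat(k, 1)[nz])).sum()
        )
        n_params = (k - 1) * pcard
        score = ll - 0.5 * math.log(self.n) * n_params
        self._family_cache[key] = score
        return score


def g2_ci_test(
    data: Cohort | pd.DataFrame, x: str, y: str, z: Iterable[str] = ()
) -> tuple[float, int, float]:
    """G-squared test of X independent of Y given Z on categorical data.

    ``G2 = 2 sum O ln(O / E)`` over the X x Y table within each Z stratum,
    summed across strata; ``df`` accumulates ``(r - 1)(c - 1)`` over strata
    with data; p from the chi-square survival function.
    """
    z = tuple(z)
    if x in z or y in z or x == y:
        raise ValueError("x, y and z must be distinct")
    return _Encoded(data).g2(x, y, z)


def bic_score(
    data: Cohort | pd.DataFrame, edges: Iterable[tuple[str, str]],
    nodes: Sequence[str] | None = None,
) -> float:
    """Network BIC: sum over nodes of ML log-likelihood minus (k/2) ln N.

    Higher is better; the score decomposes over node-parent families.
    """
    enc = _Encoded(data, variables=nodes)
    g = dag_from_edges(enc.variables, edges)
    return sum(enc.family_score(v, tuple(g.predecessors(v))) for v in enc.variables)


def _subsets(items: Sequence[str], max_size: int) -> Iterable[tuple[str, ...]]:
    for size in range(min(len(items), max_size) + 1):
        yield from itertools.combinations(items, size)


def _mmpc_target(
    enc: _Encoded, target: str, alpha: float, max_cond: int
) -> set[str]:
    candidates = sorted(v for v in enc.variables if v != target)
    cpc: list[str] = []
    # per-candidate running max p-value (min association) and df tie-break
    maxp: dict[str, tuple[float, int]] = {}
    alive = list(candidates)
    for x in alive:
        stat, df, p = enc.g2(x, target)
        maxp[x] = (p, df)
    alive = [x for x in alive if maxp[x][0] < alpha]
    while alive:
        # max-min choice: minimize the max p over tested subsets
        best = min(alive, key=lambda x: (maxp[x][0], maxp[x][1], x))
        cpc.append(best)
        alive.remove(best)
        survivors = []
        for x in alive:
            p_max, df_max = maxp[x]
            # only subsets containing the newest CPC member are new
            rest = [v for v in cpc if v != best]
            for sub in _subsets(rest, max_cond - 1):
                z = tuple(sorted(sub + (best,)))
                if len(z) > max_cond:
                    continue
                stat, df, p = enc.g2(x, target, z)
                if p > p_max or (p == p_max and df < df_max):
                    p_max, df_max = p, df
                if p_max >= alpha:
                    break
            maxp[x] = (p_max, df_max)
            if p_max < alpha:
                survivors.append(x)
        alive = survivors
    # backward phase: drop members separated by some subset of the others
    for x in sorted(cpc):
        others = [v for v in cpc if v != x]
        for z in _subsets(others, max_cond):
            if not z:
                continue
            _, _, p = enc.g2(x, target, tuple(z))
            if p >= alpha:
                cpc.remove(x)
                break
    return set(cpc)


def mmpc(
    data: Cohort | pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    max_cond: int = DEFAULT_MAX_COND,
    variables: Sequence[str] | None = None,
    _encoded: "_Encoded | None" = None,
) -> dict[str, set[str]]:
    """Max-min parents-and-children skeleton discovery.

    Forward phase adds the candidate maximizing the minimum association
    (1 - p of the G-squared test) over subsets of the current set;
    the backward phase prunes conditionally independent members; symmetry
    is enforced by intersection (X in PC(Y) and Y in PC(X)).
    """
    enc = _encoded if _encoded is not None else _Encoded(data, variables)
    if len(enc.variables) < 2:
        raise ValueError("need at least two variables")
    raw = {t: _mmpc_target(enc, t, alpha, max_cond) for t in enc.variables}
    return {
        t: {x for x in raw[t] if t in raw[x]} for t in enc.variables
    }


def _would_cycle(g: nx.DiGraph, u: str, v: str) -> bool:
    return g.has_node(u) and g.has_node(v) and nx.has_path(g, v, u)


def hill_climb(
    data: Cohort | pd.DataFrame,
    skeleton: dict[str, set[str]] | None = None,
    constraints: EdgeConstraints | None = None,
    alpha: float = DEFAULT_ALPHA,
    max_cond: int = DEFAULT_MAX_COND,
    max_parents: int = DEFAULT_MAX_PARENTS,
    variables: Sequence[str] | None = None,
) -> LearnedStructure:
    """Greedy BIC hill climbing restricted to the skeleton plus whitelist.

    Moves are add/delete/reverse; the search starts from the whitelist,
    never violates the blacklist or acyclicity, and picks the
    best-improving move with ties broken by a fixed enumeration order
    (add < delete < reverse, lexicographic edges), so the result is
    deterministic.  ``skeleton`` defaults to an MMPC run on the data.
    """
    constraints = constraints or EdgeConstraints()
    enc = _Encoded(data, variables)
    nodes = enc.variables
    for a, b in constraints.whitelist | constraints.blacklist:
        if a not in enc.cards or b not in enc.cards:
            raise ConstraintError(f"constraint edge ({a}, {b}) references unknown node")
    if skeleton is None:
        skeleton = mmpc(data, alpha=alpha, max_cond=max_cond, _encoded=enc)

    allowed_pairs = {
        frozenset((a, b)) for a, nbrs in skeleton.items() for b in nbrs
    } | {frozenset(e) for e in constraints.whitelist}

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.whitelist)
    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - guarded upstream
        raise ConstraintError("whitelist alone is cyclic")

    def family(node: str) -> float:
        return enc.family_score(node, tuple(g.predecessors(node)))

    while True:
        best_delta = 0.0
        best_move = None
        # adds
        for u, v in sorted(itertools.permutations(nodes, 2)):
            if g.has_edge(u, v) or (u, v) in constraints.blacklist:
                continue
            if frozenset((u, v)) not in allowed_pairs:
                continue
            if g.in_degree(v) >= max_parents or _would_cycle(g, u, v):
                continue
            parents = tuple(g.predecessors(v))
            delta = enc.family_score(v, parents + (u,)) - enc.family_score(v, parents)
            if delta > best_delta + _SCORE_EPS:
                best_delta, best_move = delta, ("add", u, v)
        # deletes
        for u, v in sorted(g.edges()):
            if (u, v) in constraints.whitelist:
                continue
            parents = tuple(g.predecessors(v))
            reduced = tuple(p for p in parents if p != u)
            delta = enc.family_score(v, reduced) - enc.family_score(v, parents)
            if delta > best_delta + _SCORE_EPS:
                best_delta, best_move = delta, ("delete", u, v)
        # reversals
        for u, v in sorted(g.edges()):
            if (u, v) in constraints.whitelist or (v, u) in constraints.blacklist:
                continue
            if g.in_degree(u) >= max_parents:
                continue
            g.remove_edge(u, v)
            cyclic = _would_cycle(g, v, u)
            g.add_edge(u, v)
            if cyclic:
                continue
            pv = tuple(g.predecessors(v))
            pu = tuple(g.predecessors(u))
            delta = (
                enc.family_score(v, tuple(p for p in pv if p != u))
                - enc.family_score(v, pv)
                + enc.family_score(u, pu + (v,))
                - enc.family_score(u, pu)
            )
            if delta > best_delta + _SCORE_EPS:
                best_delta, best_move = delta, ("reverse", u, v)
        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            g.add_edge(u, v)
        elif kind == "delete":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)

    score = sum(family(v) for v in nodes)
    return LearnedStructure(
        edges=sorted(g.edges()),
        score=score,
        skeleton=skeleton,
        ci_test_log=list(enc.ci_log),
    )


def mmhc(
    data: Cohort | pd.DataFrame,
    constraints: EdgeConstraints | None = None,
    alpha: float = DEFAULT_ALPHA,
    max_cond: int = DEFAULT_MAX_COND,
    max_parents: int = DEFAULT_MAX_PARENTS,
    variables: Sequence[str] | None = None,
) -> LearnedStructure:
    """Max-min hill climbing: MMPC skeleton, then restricted hill climbing."""
    return hill_climb(
        data,
        skeleton=None,
        constraints=constraints,
        alpha=alpha,
        max_cond=max_cond,
        max_parents=max_parents,
        variables=variables,
    )


def shd(
    edges_a: Iterable[tuple[str, str]],
    edges_b: Iterable[tuple[str, str]],
    skeleton_only: bool = False,
) -> int:
    """Structural Hamming distance between two DAG edge sets.

    Counts undirected adjacencies present in exactly one graph, plus (when
    ``skeleton_only`` is false) shared adjacencies whose orientation
    differs.
    """
    a = {tuple(e) for e in edges_a}
    b = {tuple(e) for e in edges_b}
    ska = {frozenset(e) for e in a}
    skb = {frozenset(e) for e in b}
    distance = len(ska ^ skb)
    if not skeleton_only:
        for pair in ska & skb:
            u, v = tuple(pair)
            if ((u, v) in a) != ((u, v) in b):
                distance += 1
    return distance
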