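"""Discrete Bayesian-network data model.

Variables with finite state spaces, conditional probability tables (CPTs),
and the :class:`NetworkSpec` container tying them together, with JSON and
DOT serialization.  A network is valid when its directed graph is acyclic,
every non-root categorical node carries a CPT whose parent axes match its
incoming edges, and every CPT row sums to one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

#: absolute tolerance for a CPT row to be accepted as a distribution
ROW_SUM_TOL = 1e-9

#: separator used to key parent-state configurations in JSON
_KEY_SEP = "|"


class NetworkValidationError(ValueError):
    """The network specification violates a structural invariant."""


class CyclicGraphError(NetworkValidationError):
    """The directed graph of the network contains a cycle."""


@dataclass(frozen=True)
class StratumGaussian:
    """Gaussian parameters for a continuous auxiliary within one outcome stratum."""

    mean: float
    sd: float

    def to_json(self) -> dict:
        return {"mean": self.mean, "sd": self.sd}


@dataclass(frozen=True)
class VariableSpec:
    """One modelled variable: name, ordered state labels and its role.

    ``kind`` is ``"categorical"`` for network nodes and
    ``"continuous-auxiliary"`` for covariates generated outside the graph
    (Gaussian per outcome stratum, held in ``stratum_params``).
    """

    name: str
    states: tuple[str, ...] = ()
    role: str = "internal"  # root | internal | outcome
    kind: str = "categorical"  # categorical | continuous-auxiliary
    stratum_params: Mapping[str, StratumGaussian] | None = None

    def __post_init__(self) -> None:
        if self.role not in ("root", "internal", "outcome"):
            raise NetworkValidationError(f"{self.name}: unknown role {self.role!r}")
        if self.kind == "categorical":
            if len(self.states) < 2:
                raise NetworkValidationError(f"{self.name}: needs >= 2 states")
            if len(set(self.states)) != len(self.states):
                raise NetworkValidationError(f"{self.name}: duplicate state labels")
            if self.role == "outcome" and tuple(self.states) != ("no", "yes"):
                raise NetworkValidationError(
                    f"{self.name}: outcome must be binary with states ('no', 'yes')"
                )
        elif self.kind == "continuous-auxiliary":
            if not self.stratum_params:
                raise NetworkValidationError(
                    f"{self.name}: continuous auxiliary needs stratum_params"
                )
        else:
            raise NetworkValidationError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class CPT:
    """Conditional probability table of ``node`` given ``parent_order``.

    ``rows`` maps each parent-state configuration (a tuple ordered like
    ``parent_order``; the empty tuple for root nodes) to a probability
    vector over the node's states.  ``counts`` optionally retains the raw
    counts behind each estimated row.
    """

    node: str
    parent_order: tuple[str, ...]
    rows: dict[tuple[str, ...], np.ndarray]
    counts: dict[tuple[str, ...], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.parent_order = tuple(self.parent_order)
        self.rows = {tuple(k): np.asarray(v, dtype=float) for k, v in self.rows.items()}

    def row(self, config: tuple[str, ...]) -> np.ndarray:
        return self.rows[tuple(config)]

    def validate(self, spec: "NetworkSpec") -> None:
        var = spec.variable(self.node)
        expected = set(
            itertools.product(*(spec.variable(p).states for p in self.parent_order))
        )
        got = set(self.rows)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise NetworkValidationError(
                f"CPT[{self.node}]: parent configurations mismatch "
                f"(missing={sorted(missing)!r}, extra={sorted(extra)!r})"
            )
        for config, p in self.rows.items():
            if p.shape != (var.n_states,):
                raise NetworkValidationError(
                    f"CPT[{self.node}]{config}: length {p.shape} != {var.n_states}"
                )
            if np.any(p < -ROW_SUM_TOL) or np.any(p > 1 + ROW_SUM_TOL):
                raise NetworkValidationError(
                    f"CPT[{self.node}]{config}: probabilities outside [0, 1]"
                )
            if abs(float(p.sum()) - 1.0) > ROW_SUM_TOL:
                raise NetworkValidationError(
                    f"CPT[{self.node}]{config}: row sums to {p.sum():.12f}, not 1"
                )


@dataclass
class NetworkSpec:
    """A discrete Bayesian network: variables, directed edges and CPTs."""

    variables: list[VariableSpec]
    edges: list[tuple[str, str]]
    cpts: dict[str, CPT] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [tuple(e) for e in self.edges]
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise NetworkValidationError("duplicate variable names")

    # -- accessors ---------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise NetworkValidationError(f"unknown variable {name!r}") from None

    @property
    def categorical_nodes(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "categorical"]

    @property
    def auxiliary_variables(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.kind == "continuous-auxiliary"]

    @property
    def outcome(self) -> str:
        names = [v.name for v in self.variables if v.role == "outcome"]
        if len(names) != 1:
            raise NetworkValidationError("network must declare exactly one outcome")
        return names[0]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.categorical_nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        cpt = self.cpts.get(node)
        if cpt is not None:
            return cpt.parent_order
        return tuple(sorted(p for p, c in self.edges if c == node))

    def states_of(self, node: str) -> tuple[str, ...]:
        return self.variable(node).states

    def parent_configs(self, node: str) -> Iterator[tuple[str, ...]]:
        yield from itertools.product(
            *(self.states_of(p) for p in self.parents(node))
        )

    def topological_order(self) -> list[str]:
        """Lexicographically smallest topological order (deterministic)."""
        try:
            return list(nx.lexicographical_topological_sort(self.graph()))
        except nx.NetworkXUnfeasible:
            raise CyclicGraphError("network graph contains a cycle") from None

    def cpt_matrix(self, node: str) -> np.ndarray:
        """CPT as an ndarray of shape (*parent_cards, n_states)."""
        cpt = self.cpts[node]
        parent_cards = [self.variable(p).n_states for p in cpt.parent_order]
        out = np.empty(parent_cards + [self.variable(node).n_states])
        for config, p in cpt.rows.items():
            idx = tuple(
                self.states_of(par).index(s) for par, s in zip(cpt.parent_order, config)
            )
            out[idx] = p
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        nodes = set(self.categorical_nodes)
        for parent, child in self.edges:
            if parent not in nodes or child not in nodes:
                raise NetworkValidationError(
                    f"edge ({parent}, {child}) references unknown categorical node"
                )
        if len(set(self.edges)) != len(self.edges):
            raise NetworkValidationError("duplicate edges")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise CyclicGraphError("network graph contains a cycle")
        incoming = {n: tuple(sorted(p for p, c in self.edges if c == n)) for n in nodes}
        for name in nodes:
            cpt = self.cpts.get(name)
            if cpt is None:
                raise NetworkValidationError(f"node {name!r} has no CPT")
            if tuple(sorted(cpt.parent_order)) != incoming[name]:
                raise NetworkValidationError(
                    f"CPT[{name}] parents {cpt.parent_order} != edges {incoming[name]}"
                )
            cpt.validate(self)
        for aux in self.auxiliary_variables:
            outcome_states = self.states_of(self.outcome)
            if set(aux.stratum_params) != set(outcome_states):
                raise NetworkValidationError(
                    f"{aux.name}: stratum_params must cover outcome states"
                )

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        variables = []
        for v in self.variables:
            entry: dict = {"name": v.name, "role": v.role, "kind": v.kind}
            if v.kind == "categorical":
                entry["states"] = list(v.states)
            else:
                entry["stratum_params"] = {
                    k: g.to_json() for k, g in v.stratum_params.items()
                }
            variables.append(entry)
        cpts = {}
        for name, cpt in self.cpts.items():
            cpts[name] = {
                "parent_order": list(cpt.parent_order),
                "rows": {
                    _KEY_SEP.join(config): [float(x) for x in p]
                    for config, p in sorted(cpt.rows.items())
                },
            }
        out = {
            "variables": variables,
            "edges": [list(e) for e in self.edges],
            "cpts": cpts,
        }
        if self.metadata:
            out["metadata"] = self.metadata
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json_dict(cls, data: Mapping) -> "NetworkSpec":
        variables = []
        for entry in data["variables"]:
            params = None
            if entry.get("stratum_params"):
                params = {
                    k: StratumGaussian(float(g["mean"]), float(g["sd"]))
                    for k, g in entry["stratum_params"].items()
                }
            variables.append(
                VariableSpec(
                    name=entry["name"],
                    states=tuple(entry.get("states", ())),
                    role=entry.get("role", "internal"),
                    kind=entry.get("kind", "categorical"),
                    stratum_params=params,
                )
            )
        edges = [tuple(e) for e in data.get("edges", [])]
        cpts = {}
        for name, block in data.get("cpts", {}).items():
            rows = {
                tuple(key.split(_KEY_SEP)) if key else (): np.asarray(vec, dtype=float)
                for key, vec in block["rows"].items()
            }
            cpts[name] = CPT(name, tuple(block["parent_order"]), rows)
        spec = cls(variables, edges, cpts, metadata=dict(data.get("metadata", {})))
        return spec

    @classmethod
    def from_json(cls, source: str | Path) -> "NetworkSpec":
        path = Path(source)
        text = path.read_text(encoding="utf-8") if path.exists() else str(source)
        spec = cls.from_json_dict(json.loads(text))
        spec.validate()
        return spec

    def to_dot(self, path: str | Path | None = None) -> str:
        lines = ["digraph network {", "  rankdir=LR;"]
        outcome = {v.name for v in self.variables if v.role == "outcome"}
        for node in self.categorical_nodes:
            shape = "doublecircle" if node in outcome else "ellipse"
            lines.append(f'  "{node}" [shape={shape}];')
        for parent, child in self.edges:
            lines.append(f'  "{parent}" -> "{child}";')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def dag_from_edges(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build a DiGraph and fail fast if it is cyclic."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise CyclicGraphError("edge set contains a cycle")
    return g
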