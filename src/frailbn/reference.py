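"""Construction of the reference ground-truth network.

The published study prints only the outcome node's CPT, the root-level
marginal counts, and a prose description of the 12-node / 15-edge
structure.  This module compiles those constants into a fully
parameterized :class:`~frailbn.network.NetworkSpec`:

* the outcome CPT is taken verbatim from the published table;
* root priors equal the published marginal proportions;
* internal-node CPTs use a calibrated logistic link — per-state baseline
  scores ``log(marginal proportion)`` plus signed per-parent-state
  log-odds shifts (default magnitude ±0.8) — so that simulated marginals
  stay close to the published ones while respecting edge directions.

The calibration constants are recorded in the spec's ``metadata`` block so
a serialized network documents its own construction.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import fixtures
from .network import CPT, NetworkSpec, StratumGaussian, VariableSpec

#: the 15 directed edges of the reference structure
REFERENCE_EDGES: tuple[tuple[str, str], ...] = (
    ("polypharmacy", "oral_frailty"),
    ("malnutrition", "oral_frailty"),
    ("eating_alone", "oral_frailty"),
    ("general_frailty", "oral_frailty"),
    ("malnutrition", "general_frailty"),
    ("social_support", "eating_alone"),
    ("eating_alone", "dietary_pattern"),
    ("eating_alone", "malnutrition"),
    ("dietary_pattern", "malnutrition"),
    ("age", "general_frailty"),
    ("age", "dietary_pattern"),
    ("education", "monthly_income"),
    ("monthly_income", "malnutrition"),
    ("depression", "poor_oral_health"),
    ("poor_oral_health", "general_frailty"),
)

#: effect sign per edge: +1 pushes the child toward its later states when the
#: parent is in a later state, -1 is protective (e.g. high support -> less
#: eating alone, higher income -> less malnutrition)
EDGE_SIGNS: dict[tuple[str, str], int] = {
    ("malnutrition", "general_frailty"): +1,
    ("social_support", "eating_alone"): -1,
    ("eating_alone", "dietary_pattern"): +1,
    ("eating_alone", "malnutrition"): +1,
    ("dietary_pattern", "malnutrition"): +1,
    ("age", "general_frailty"): +1,
    ("age", "dietary_pattern"): +1,
    ("education", "monthly_income"): +1,
    ("monthly_income", "malnutrition"): -1,
    ("depression", "poor_oral_health"): +1,
    ("poor_oral_health", "general_frailty"): +1,
}

#: default magnitude of the per-parent log-odds shift
DEFAULT_SHIFT = 0.8

_OUTCOME = "oral_frailty"

_ROOTS = ("age", "education", "social_support", "polypharmacy", "depression")
_INTERNAL = (
    "monthly_income",
    "eating_alone",
    "dietary_pattern",
    "malnutrition",
    "poor_oral_health",
    "general_frailty",
)


def _state_scores(n: int) -> np.ndarray:
    """Signed positions of a variable's states on [-1, 1]."""
    if n == 1:
        return np.zeros(1)
    return 2.0 * np.arange(n) / (n - 1) - 1.0


def _config_shifts(
    node: str,
    parents: tuple[str, ...],
    states: dict[str, tuple[str, ...]],
    shift: float,
) -> dict[tuple[str, ...], float]:
    """Total signed log-odds shift contributed by each parent configuration."""
    out: dict[tuple[str, ...], float] = {}
    for config in itertools.product(*(states[p] for p in parents)):
        total = 0.0
        for parent, state in zip(parents, config):
            sign = EDGE_SIGNS[(parent, node)]
            pos = _state_scores(len(states[parent]))[states[parent].index(state)]
            total += sign * shift * pos
        out[config] = total
    return out


def _parent_joint(
    parents: tuple[str, ...],
    states: dict[str, tuple[str, ...]],
    built: dict[str, CPT],
) -> dict[tuple[str, ...], float]:
    """Exact joint distribution of ``parents`` under the CPTs built so far.

    Enumerates the full joint over every built node (the reference graph is
    small enough that this costs well under 30k configurations).
    """
    names = list(built)
    joint: dict[tuple[str, ...], float] = {}
    for assignment in itertools.product(*(states[n] for n in names)):
        env = dict(zip(names, assignment))
        p = 1.0
        for name in names:
            cpt = built[name]
            config = tuple(env[q] for q in cpt.parent_order)
            p *= cpt.row(config)[states[name].index(env[name])]
        key = tuple(env[q] for q in parents)
        joint[key] = joint.get(key, 0.0) + p
    return joint


def _calibrated_cpt(
    node: str,
    parents: tuple[str, ...],
    states: dict[str, tuple[str, ...]],
    marginal: np.ndarray,
    shift: float,
    built: dict[str, CPT],
) -> CPT:
    """Softmax CPT whose implied marginal matches the published one.

    Rows are ``softmax(baseline + total_shift(config) * state_position)``;
    the baseline is solved by fixed-point iteration so that, under the
    exact joint distribution of the parents given the already-built
    ancestor CPTs, the node's marginal equals ``marginal``.
    """
    target = np.clip(marginal, 1e-12, None)
    target = target / target.sum()
    child_pos = _state_scores(len(states[node]))
    shifts = _config_shifts(node, parents, states, shift)
    joint = _parent_joint(parents, states, built)

    def rows_for(baseline: np.ndarray) -> dict[tuple[str, ...], np.ndarray]:
        rows = {}
        for config, total in shifts.items():
            scores = baseline + total * child_pos
            p = np.exp(scores - scores.max())
            rows[config] = p / p.sum()
        return rows

    baseline = np.log(target)
    for _ in range(500):
        rows = rows_for(baseline)
        implied = np.zeros_like(target)
        for config, w in joint.items():
            implied += w * rows[config]
        if np.max(np.abs(implied - target)) < 1e-12:
            break
        baseline += np.log(target) - np.log(np.clip(implied, 1e-300, None))
    return CPT(node, parents, rows_for(baseline))


def build_reference_network(shift: float = DEFAULT_SHIFT) -> NetworkSpec:
    """Compile the published constants into the 12-node reference network.

    Parameters
    ----------
    shift
        Magnitude of the per-parent-state log-odds shift used to calibrate
        the internal-node CPTs (the outcome CPT and root priors are fixed
        by the published tables regardless of this value).
    """
    states: dict[str, tuple[str, ...]] = {
        name: fixtures.TABLE1[name].row_labels for name in _ROOTS + _INTERNAL
    }
    states[_OUTCOME] = ("no", "yes")

    variables = [
        VariableSpec(name, states[name], role="root") for name in _ROOTS
    ]
    variables += [
        VariableSpec(name, states[name], role="internal") for name in _INTERNAL
    ]
    variables.append(VariableSpec(_OUTCOME, states[_OUTCOME], role="outcome"))
    for aux, strata in fixtures.CONTINUOUS_SUMMARIES.items():
        variables.append(
            VariableSpec(
                aux,
                role="internal",
                kind="continuous-auxiliary",
                stratum_params={
                    outcome_state: StratumGaussian(mean, sd)
                    for outcome_state, (mean, sd, _n) in strata.items()
                },
            )
        )

    parents_of: dict[str, tuple[str, ...]] = {}
    for name in _ROOTS + _INTERNAL + (_OUTCOME,):
        parents_of[name] = tuple(p for p, c in REFERENCE_EDGES if c == name)

    cpts: dict[str, CPT] = {}
    for name in _ROOTS:
        cpts[name] = CPT(name, (), {(): fixtures.marginal_proportions(name)})
    for name in _INTERNAL:  # _INTERNAL is listed in a topological order
        cpts[name] = _calibrated_cpt(
            name,
            parents_of[name],
            states,
            fixtures.marginal_proportions(name),
            shift,
            cpts,
        )
    cpts[_OUTCOME] = CPT(
        _OUTCOME,
        fixtures.TABLE3_PARENTS,
        {config: np.asarray(p) for config, p in fixtures.TABLE3.items()},
    )

    spec = NetworkSpec(
        variables,
        list(REFERENCE_EDGES),
        cpts,
        metadata={
            "calibration": {
                "method": "softmax(log marginal + signed parent log-odds shifts)",
                "shift": shift,
                "edge_signs": {f"{p}->{c}": s for (p, c), s in EDGE_SIGNS.items()},
            }
        },
    )
    spec.validate()
    return spec
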