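"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (full-joint enumeration, pair
counting) and shares no code with the implementation paths it checks.
"""

import itertools

import numpy as np

from frailbn.network import CPT, NetworkSpec, VariableSpec


def brute_posterior(spec, query, evidence=None):
    """P(query | evidence) by enumerating the full joint, label-level."""
    evidence = evidence or {}
    names = spec.categorical_nodes
    qstates = spec.states_of(query)
    out = np.zeros(len(qstates))
    for assignment in itertools.product(*(spec.states_of(n) for n in names)):
        env = dict(zip(names, assignment))
        if any(env[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for n in names:
            cpt = spec.cpts[n]
            config = tuple(env[q] for q in cpt.parent_order)
            p *= cpt.row(config)[spec.states_of(n).index(env[n])]
        out[qstates.index(env[query])] += p
    total = out.sum()
    if total == 0:
        raise ZeroDivisionError("evidence has zero probability")
    return out / total


def random_network(rng, n_nodes=6, max_states=3, max_parents=3):
    """A random DAG with Dirichlet CPT rows (parents drawn among earlier nodes)."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    cards = rng.integers(2, max_states + 1, size=n_nodes)
    variables = [
        VariableSpec(name, tuple(f"s{j}" for j in range(card)), role="internal")
        for name, card in zip(names, cards)
    ]
    edges = []
    cpts = {}
    for i, var in enumerate(variables):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parent_idx = sorted(rng.choice(i, size=k, replace=False)) if k else []
        parents = tuple(names[j] for j in parent_idx)
        edges.extend((p, var.name) for p in parents)
        rows = {}
        for config in itertools.product(
            *(variables[j].states for j in parent_idx)
        ):
            rows[config] = rng.dirichlet(np.ones(cards[i]))
        cpts[var.name] = CPT(var.name, parents, rows)
    spec = NetworkSpec(variables, edges, cpts)
    spec.validate()
    return spec


def mann_whitney_u_bruteforce(x, y):
    """U as the exhaustive count of (x > y) pairs plus half the ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def auc_rank_formula(predicted, observed):
    """AUC as the midrank Mann-Whitney statistic over case/control pairs."""
    from scipy.stats import rankdata

    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ranks = rankdata(predicted)
    n_pos = int(observed.sum())
    n_neg = len(observed) - n_pos
    r_pos = ranks[observed == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
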