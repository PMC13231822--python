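"""Synthetic cohort generation by ancestral sampling.

Records are drawn node by node in the lexicographically smallest
topological order of the network, each node from its CPT row given the
already-sampled parents; continuous auxiliaries are drawn afterwards from
their per-outcome-stratum Gaussians.  A single integer seed drives one
generator instance, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkSpec


class EmptyCohortError(ValueError):
    """Operation requires a non-empty cohort."""


@dataclass
class Cohort:
    """A patient-level table plus the provenance needed to regenerate it."""

    records: pd.DataFrame
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls(pd.read_csv(path, encoding="utf-8"))


def sample_cohort(
    spec: NetworkSpec,
    n: int,
    seed: int,
    missing_rate: float = 0.0,
) -> Cohort:
    """Draw ``n`` records from ``spec`` by ancestral sampling.

    Parameters
    ----------
    spec
        Validated network specification (cyclic specs raise).
    n
        Number of records, >= 1.
    seed
        Integer seed; identical seeds yield byte-identical cohorts.
    missing_rate
        Optional MCAR missingness fraction applied to categorical cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)

    order = spec.topological_order()
    columns: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for node in order:
        cpt = spec.cpts[node]
        matrix = spec.cpt_matrix(node).reshape(-1, spec.variable(node).n_states)
        # row index of each record within the flattened parent-config axis
        row_idx = np.zeros(n, dtype=np.int64)
        for parent in cpt.parent_order:
            row_idx = row_idx * spec.variable(parent).n_states + codes[parent]
        probs = matrix[row_idx]
        u = rng.random(n)
        drawn = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        codes[node] = drawn
        states = np.asarray(spec.states_of(node), dtype=object)
        columns[node] = states[drawn]

    outcome_codes = codes[spec.outcome]
    outcome_states = spec.states_of(spec.outcome)
    aux_columns: dict[str, np.ndarray] = {}
    for aux in sorted(spec.auxiliary_variables, key=lambda v: v.name):
        values = np.empty(n)
        for state_idx, state in enumerate(outcome_states):
            mask = outcome_codes == state_idx
            params = aux.stratum_params[state]
            values[mask] = rng.normal(params.mean, params.sd, size=int(mask.sum()))
        aux_columns[aux.name] = values

    ordered_names = [v.name for v in spec.variables]
    frame = pd.DataFrame({**columns, **aux_columns})[ordered_names]
    if missing_rate > 0.0:
        if not 0.0 <= missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        cat = spec.categorical_nodes
        mask = rng.random((n, len(cat))) < missing_rate
        frame[cat] = frame[cat].mask(pd.DataFrame(mask, columns=cat, index=frame.index))
    return Cohort(frame, seed=seed)


def empirical_marginals(
    cohort: Cohort, spec: NetworkSpec | None = None
) -> dict[str, pd.Series]:
    """Per-variable relative state frequencies of a cohort.

    When ``spec`` is given, categorical frequencies are reindexed to the
    declared state order (absent states get frequency 0) and continuous
    auxiliaries are skipped.
    """
    if cohort.n == 0:
        raise EmptyCohortError("cannot compute marginals of an empty cohort")
    out: dict[str, pd.Series] = {}
    for column in cohort.records.columns:
        if spec is not None:
            var = spec.variable(column)
            if var.kind != "categorical":
                continue
            freq = cohort.records[column].value_counts(normalize=True)
            freq = freq.reindex(var.states, fill_value=0.0)
        else:
            if pd.api.types.is_numeric_dtype(cohort.records[column]):
                continue
            freq = cohort.records[column].value_counts(normalize=True)
        freq.name = column
        out[column] = freq
    return out
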