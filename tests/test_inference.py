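import time

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_posterior, random_network
from frailbn import fixtures
from frailbn.inference import (
    Factor,
    ZeroEvidenceError,
    conditional_table,
    eliminate,
    fit_cpts,
    min_fill_order,
    model_factors,
    posterior,
    predict_proba,
    with_cpts,
)
from frailbn.network import CPT, NetworkSpec, NetworkValidationError, VariableSpec
from frailbn.synthetic import Cohort, sample_cohort


# --------------------------------------------------------------------- factors


def test_factor_scope_must_match_rank():
    with pytest.raises(ValueError):
        Factor(("a", "b"), np.ones(3))


def test_factor_rejects_negative_values():
    with pytest.raises(ValueError):
        Factor(("a",), np.array([0.5, -0.1]))


def test_min_fill_order_deterministic(reference):
    factors = model_factors(reference)
    assert min_fill_order(factors) == min_fill_order(factors)


# ------------------------------------------------------------------- eliminate


def test_published_scenario(reference):
    post = posterior(
        reference,
        "oral_frailty",
        {
            "polypharmacy": "yes",
            "malnutrition": "yes",
            "eating_alone": "yes",
            "general_frailty": "yes",
        },
    )
    assert post["yes"] == pytest.approx(0.9246, abs=1e-9)


def test_root_prior_without_evidence(reference):
    post = posterior(reference, "polypharmacy")
    np.testing.assert_allclose(
        post.to_numpy(), fixtures.marginal_proportions("polypharmacy"), atol=1e-12
    )


def test_posterior_sums_to_one(reference):
    post = posterior(reference, "oral_frailty", {"age": "≥60", "social_support": "Low"})
    assert post.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_eliminate_equals_enumeration_random_networks(seed):
    rng = np.random.default_rng(seed)
    spec = random_network(rng, n_nodes=int(rng.integers(3, 8)))
    names = spec.categorical_nodes
    query = names[int(rng.integers(0, len(names)))]
    evidence = {}
    for other in names:
        if other != query and rng.random() < 0.3:
            states = spec.states_of(other)
            evidence[other] = states[int(rng.integers(0, len(states)))]
    try:
        expected = brute_posterior(spec, query, evidence)
    except ZeroDivisionError:
        with pytest.raises(ZeroEvidenceError):
            posterior(spec, query, evidence)
        return
    np.testing.assert_allclose(
        posterior(spec, query, evidence).to_numpy(), expected, atol=1e-9
    )


def test_eliminate_with_explicit_order_matches_default(reference):
    factors = model_factors(reference)
    ev = {"polypharmacy": 1}
    default = eliminate(factors, "oral_frailty", ev)
    explicit = eliminate(
        factors,
        "oral_frailty",
        ev,
        order=sorted(n for n in reference.categorical_nodes if n != "oral_frailty"),
    )
    np.testing.assert_allclose(default, explicit, atol=1e-12)


def test_zero_probability_evidence_raises():
    variables = [
        VariableSpec("a", ("no", "yes"), role="root"),
        VariableSpec("b", ("no", "yes")),
    ]
    cpts = {
        "a": CPT("a", (), {(): np.array([1.0, 0.0])}),
        "b": CPT(
            "b",
            ("a",),
            {("no",): np.array([0.5, 0.5]), ("yes",): np.array([0.5, 0.5])},
        ),
    }
    spec = NetworkSpec(variables, [("a", "b")], cpts)
    with pytest.raises(ZeroEvidenceError):
        posterior(spec, "b", {"a": "yes"})


def test_unknown_evidence_state(reference):
    with pytest.raises(NetworkValidationError):
        posterior(reference, "oral_frailty", {"age": "ancient"})


def test_markov_property_screens_off_nondescendants(reference):
    """Conditioning on the outcome's parents makes other ancestors irrelevant."""
    parents = dict(zip(fixtures.TABLE3_PARENTS, ("yes", "yes", "no", "yes")))
    base = posterior(reference, "oral_frailty", parents)["yes"]
    extended = dict(parents, age="≥60", social_support="Low", depression="yes")
    with_more = posterior(reference, "oral_frailty", extended)["yes"]
    assert with_more == pytest.approx(base, abs=1e-9)
    assert base == pytest.approx(
        reference.cpts["oral_frailty"].row(("yes", "yes", "no", "yes"))[1], abs=1e-12
    )


# -------------------------------------------------------------------- fit_cpts


def _toy_spec():
    variables = [
        VariableSpec("p", ("no", "yes"), role="root"),
        VariableSpec("x", ("no", "yes")),
    ]
    return NetworkSpec(variables, [("p", "x")], {})


def test_fit_cpts_direct_frequencies():
    frame = pd.DataFrame(
        {"p": ["yes"] * 4 + ["no"] * 2, "x": ["yes", "yes", "yes", "no", "no", "no"]}
    )
    cpts = fit_cpts(frame, _toy_spec(), dag_edges=[("p", "x")])
    np.testing.assert_allclose(cpts["x"].row(("yes",)), [0.25, 0.75])


def test_fit_cpts_laplace_unseen_configuration():
    frame = pd.DataFrame({"p": ["no", "no"], "x": ["no", "yes"]})
    cpts = fit_cpts(frame, _toy_spec(), dag_edges=[("p", "x")], pseudocount=1.0)
    np.testing.assert_allclose(cpts["x"].row(("yes",)), [0.5, 0.5])


def test_fit_cpts_uniform_warning_without_pseudocount(caplog):
    frame = pd.DataFrame({"p": ["no", "no"], "x": ["no", "yes"]})
    with caplog.at_level("WARNING"):
        cpts = fit_cpts(frame, _toy_spec(), dag_edges=[("p", "x")])
    np.testing.assert_allclose(cpts["x"].row(("yes",)), [0.5, 0.5])
    assert any("unobserved parent configuration" in m for m in caplog.messages)


def test_fit_cpts_round_trip(reference, cohort20k):
    cpts = fit_cpts(cohort20k, reference)
    refit = with_cpts(reference, cpts)
    # high-mass rows converge to the generating CPT
    np.testing.assert_allclose(
        refit.cpts["eating_alone"].row(("High",)),
        reference.cpts["eating_alone"].row(("High",)),
        atol=0.05,
    )
    np.testing.assert_allclose(
        refit.cpts["polypharmacy"].row(()),
        reference.cpts["polypharmacy"].row(()),
        atol=0.05,
    )


def test_fit_cpts_rejects_cyclic_edges(reference, cohort680):
    with pytest.raises(NetworkValidationError):
        fit_cpts(
            cohort680,
            reference,
            dag_edges=[("age", "general_frailty"), ("general_frailty", "age")],
        )


# ----------------------------------------------------------- conditional table


def test_conditional_table_reproduces_published_rows(reference):
    table = conditional_table(reference, "oral_frailty")
    assert len(table) == 16
    for _, row in table.iterrows():
        config = tuple(row[p] for p in fixtures.TABLE3_PARENTS)
        assert row["yes"] == pytest.approx(fixtures.TABLE3[config][1], abs=5e-5)


def test_conditional_table_rootless_node(reference):
    table = conditional_table(reference, "age")
    assert len(table) == 1
    np.testing.assert_allclose(
        table[list(reference.states_of("age"))].iloc[0].to_numpy(),
        fixtures.marginal_proportions("age"),
        atol=1e-12,
    )


def test_conditional_table_non_parent_ancestors(reference):
    table = conditional_table(reference, "oral_frailty", given=("age", "depression"))
    assert len(table) == 4
    for _, row in table.iterrows():
        expected = brute_posterior(
            reference,
            "oral_frailty",
            {"age": row["age"], "depression": row["depression"]},
        )
        assert row["yes"] == pytest.approx(expected[1], abs=1e-9)


# --------------------------------------------------------------- predict_proba


def test_predict_empty_cohort(reference):
    probs = predict_proba(reference, pd.DataFrame(columns=reference.categorical_nodes))
    assert probs.shape == (0,)


def test_predict_full_evidence_uses_markov_blanket(reference, cohort680):
    frame = cohort680.records
    mask = np.ones(len(frame), dtype=bool)
    for parent in fixtures.TABLE3_PARENTS:
        mask &= (frame[parent] == "yes").to_numpy()
    assert mask.any()
    probs = predict_proba(reference, frame, "oral_frailty")
    np.testing.assert_allclose(probs[mask], 0.9246, atol=1e-9)


def test_predict_unseen_state_names_record(reference, cohort680):
    frame = cohort680.records.head(5).copy()
    frame.loc[frame.index[2], "age"] = "ancient"
    with pytest.raises(NetworkValidationError, match="record 2"):
        predict_proba(reference, frame, "oral_frailty")


def test_predict_680_records_under_ten_seconds(reference, cohort680):
    start = time.time()
    probs = predict_proba(reference, cohort680, "oral_frailty")
    assert time.time() - start < 10.0
    assert probs.shape == (680,)
    assert np.all((probs >= 0) & (probs <= 1))
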