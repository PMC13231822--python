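"""Published aggregate tables shipped as machine-readable fixtures.

These are the printed study aggregates: per-variable contingency counts of
each characteristic against the binary outcome (columns = non-case, case),
summary statistics for the continuous covariates, and the outcome node's
conditional probability table.  They seed the reference network and anchor
the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: column totals of every contingency fixture: (non-case, case)
GROUP_SIZES = (388, 292)

#: overall cohort size
COHORT_SIZE = sum(GROUP_SIZES)


@dataclass(frozen=True)
class ContingencyFixture:
    """One categorical row block: state labels, counts and printed statistics."""

    variable: str
    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]  # (non-case, case) per state
    printed_chi2: float
    printed_p: str
    significant: bool

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


# Counts transcribed verbatim from the published characteristics table.
# NOTE: the depression row's printed chi-square (13.294) is inconsistent with
# its own printed counts, which give ~24.498; `printed_chi2` keeps the printed
# value, and `chi2_from_counts_differs` flags the row.
TABLE1: dict[str, ContingencyFixture] = {
    f.variable: f
    for f in [
        ContingencyFixture(
            "age", ("<60", "≥60"), ((229, 93), (159, 199)), 49.341, "<0.001", True
        ),
        ContingencyFixture(
            "sex", ("Male", "Female"), ((223, 178), (165, 114)), 0.836, "0.360", False
        ),
        ContingencyFixture(
            "polypharmacy", ("no", "yes"), ((224, 61), (164, 231)), 92.887, "<0.001", True
        ),
        ContingencyFixture(
            "bmi",
            ("Underweight", "Normal weight", "Overweight", "Obese"),
            ((58, 43), (194, 146), (99, 73), (37, 30)),
            0.115,
            "0.990",
            False,
        ),
        ContingencyFixture(
            "poor_oral_health",
            ("no", "yes"),
            ((120, 46), (268, 246)),
            20.791,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "malnutrition", ("no", "yes"), ((235, 61), (153, 231)), 106.701, "<0.001", True
        ),
        ContingencyFixture(
            "smoking", ("no", "yes"), ((300, 230), (88, 62)), 0.203, "0.652", False
        ),
        ContingencyFixture(
            "drinking", ("no", "yes"), ((299, 222), (89, 70)), 0.100, "0.752", False
        ),
        ContingencyFixture(
            "eating_alone", ("no", "yes"), ((222, 109), (166, 183)), 26.378, "<0.001", True
        ),
        ContingencyFixture(
            "dietary_pattern",
            ("Balanced", "Meat-dominant", "Vegetable-dominant"),
            ((226, 136), (81, 100), (81, 56)),
            15.692,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "general_frailty",
            ("no", "yes"),
            ((109, 22), (279, 270)),
            45.276,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "depression", ("no", "yes"), ((314, 187), (74, 105)), 13.294, "<0.001", True
        ),
        ContingencyFixture(
            "anxiety", ("no", "yes"), ((273, 191), (115, 101)), 1.883, "0.170", False
        ),
        ContingencyFixture(
            "marital_status",
            ("Single/Unmarried", "Married", "Divorced/Widowed"),
            ((22, 14), (327, 234), (39, 44)),
            4.023,
            "0.134",
            False,
        ),
        ContingencyFixture(
            "living_status",
            ("Not alone", "Alone"),
            ((338, 253), (50, 39)),
            0.032,
            "0.857",
            False,
        ),
        ContingencyFixture(
            "social_support",
            ("Low", "Moderate", "High"),
            ((3, 38), (93, 159), (292, 95)),
            136.615,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "education",
            ("Primary school or below", "Secondary school", "College or above"),
            ((73, 123), (215, 160), (100, 9)),
            84.934,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "monthly_income",
            ("<1000", "1000–3000", "3001–5000", ">5000"),
            ((59, 145), (96, 104), (129, 30), (104, 13)),
            158.602,
            "<0.001",
            True,
        ),
        ContingencyFixture(
            "medical_reimbursement",
            ("Urban employee", "Urban resident", "NCMS", "Out-of-pocket"),
            ((189, 135), (75, 48), (111, 102), (13, 7)),
            3.626,
            "0.305",
            False,
        ),
    ]
}

#: rows whose printed chi-square does not reproduce from their printed counts
CHI2_FROM_COUNTS_DIFFERS = ("depression",)

#: continuous summaries used for the auxiliary covariates: per-stratum
#: (non-case, case) -> (mean, sd, n).  The grip-strength row is printed as
#: median (P25, P75); the Gaussian sd approximates IQR / 1.349.
CONTINUOUS_SUMMARIES = {
    "ultrafiltration_volume": {
        "no": (2.23, 0.81, 388),
        "yes": (2.12, 0.85, 292),
    },
    "grip_strength": {
        "no": (22.0, (25.0 - 18.0) / 1.349, 388),
        "yes": (18.0, (20.0 - 16.0) / 1.349, 292),
    },
}

#: parent order of the outcome node's published CPT
TABLE3_PARENTS = ("polypharmacy", "malnutrition", "eating_alone", "general_frailty")

#: published conditional probabilities of the outcome given its four parents,
#: stored to four decimals as (P(no), P(yes)); keys ordered like TABLE3_PARENTS
TABLE3: dict[tuple[str, str, str, str], tuple[float, float]] = {
    ("no", "no", "no", "no"): (0.9167, 0.0833),
    ("no", "no", "no", "yes"): (0.8250, 0.1750),
    ("no", "no", "yes", "no"): (0.9211, 0.0789),
    ("no", "no", "yes", "yes"): (0.8934, 0.1066),
    ("no", "yes", "no", "no"): (0.7917, 0.2083),
    ("no", "yes", "no", "yes"): (0.6698, 0.3302),
    ("no", "yes", "yes", "no"): (0.9118, 0.0882),
    ("no", "yes", "yes", "yes"): (0.5566, 0.4434),
    ("yes", "no", "no", "no"): (0.9211, 0.0789),
    ("yes", "no", "no", "yes"): (0.7250, 0.2750),
    ("yes", "no", "yes", "no"): (0.8611, 0.1389),
    ("yes", "no", "yes", "yes"): (0.5000, 0.5000),
    ("yes", "yes", "no", "no"): (0.7955, 0.2045),
    ("yes", "yes", "no", "yes"): (0.3842, 0.6158),
    ("yes", "yes", "yes", "no"): (0.2500, 0.7500),
    ("yes", "yes", "yes", "yes"): (0.0754, 0.9246),
}


def marginal_counts(variable: str) -> np.ndarray:
    """Row sums of the variable's contingency fixture (counts per state)."""
    return TABLE1[variable].as_array().sum(axis=1)


def marginal_proportions(variable: str) -> np.ndarray:
    counts = marginal_counts(variable)
    return counts / counts.sum()


def outcome_prevalence() -> float:
    """Case fraction of the published cohort (cases / total)."""
    return GROUP_SIZES[1] / COHORT_SIZE


def load_fixtures() -> dict:
    """Packaged aggregates keyed for programmatic access.

    Returns a dict with ``"table1"`` (variable -> ContingencyFixture),
    ``"table3"`` (parent configuration -> probability pair),
    ``"table3_parents"``, ``"group_sizes"`` and ``"continuous"``.
    """
    return {
        "table1": dict(TABLE1),
        "table3": dict(TABLE3),
        "table3_parents": TABLE3_PARENTS,
        "group_sizes": GROUP_SIZES,
        "continuous": dict(CONTINUOUS_SUMMARIES),
    }
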