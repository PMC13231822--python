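"""Model validation and node-level sensitivity analysis.

ROC/AUC with a Youden operating point, decile calibration, the
Hosmer-Lemeshow test, and two documented sensitivity indices (max-swing
and mutual information) computed by exact inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import eliminate, model_factors, predict_proba
from .logistic import hosmer_lemeshow
from .network import NetworkSpec
from .synthetic import Cohort


class SingleClassError(ValueError):
    """AUC is undefined when only one outcome class is observed."""


@dataclass
class SensitivityResult:
    """Influence of one node on the target under a documented index.

    ``max-swing`` is the largest absolute change in P(target = yes) across
    pairs of the node's states; ``mutual-information`` is I(node; target)
    in nats.  Both are zero iff the node is marginally independent of the
    target.  (Neither replicates the unspecified index of the original
    GUI software.)
    """

    node: str
    index: float
    method: str


@dataclass
class ValidationReport:
    roc_points: list[tuple[float, float]]
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    calibration_bins: list[tuple[float, float]]
    hl: tuple[float, int, float]


def sensitivity_index(
    spec: NetworkSpec, target: str, node: str, method: str = "max-swing"
) -> SensitivityResult:
    """Sensitivity of ``target`` to ``node``, by exact inference."""
    if node == target:
        raise ValueError("node must differ from target")
    factors = model_factors(spec)
    t_states = spec.states_of(target)
    n_states = spec.states_of(node)
    yes = t_states.index("yes") if "yes" in t_states else len(t_states) - 1
    cond = np.array(
        [
            eliminate(factors, target, {node: i})
            for i in range(len(n_states))
        ]
    )
    if method == "max-swing":
        p_yes = cond[:, yes]
        index = float(
            max(
                abs(a - b)
                for a, b in itertools.combinations(p_yes, 2)
            )
        )
    elif method == "mutual-information":
        p_node = eliminate(factors, node)
        joint = cond * p_node[:, None]
        p_target = joint.sum(axis=0)
        nz = joint > 0
        index = float(
            (
                joint[nz]
                * np.log(joint[nz] / np.outer(p_node, p_target)[nz])
            ).sum()
        )
        index = max(index, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SensitivityResult(node, index, method)


def sensitivity_table(
    spec: NetworkSpec, target: str | None = None, method: str = "max-swing"
) -> pd.DataFrame:
    """Sensitivity index of every other categorical node, largest first."""
    target = target if target is not None else spec.outcome
    rows = [
        sensitivity_index(spec, target, node, method)
        for node in spec.categorical_nodes
        if node != target
    ]
    frame = pd.DataFrame(
        [{"node": r.node, "index": r.index, "method": r.method} for r in rows]
    )
    return frame.sort_values("index", ascending=False, kind="stable").reset_index(
        drop=True
    )


def roc_curve(
    predicted: np.ndarray,
    observed: np.ndarray,
    calibration_groups: int = 10,
    hl_groups: int = 10,
) -> ValidationReport:
    """ROC sweep over unique predictions plus calibration diagnostics.

    AUC is the trapezoidal area under the (FPR, TPR) points (equal to the
    midrank Mann-Whitney statistic over case/control pairs); the Youden
    threshold maximizes TPR - FPR with ties resolved toward the lower
    threshold; calibration bins are equal-count prediction deciles.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n_pos = int(observed.sum())
    n_neg = len(observed) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("need at least one positive and one negative")

    order = np.argsort(-predicted, kind="stable")
    sorted_pred = predicted[order]
    sorted_obs = observed[order]
    # group ties: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(sorted_pred)) if len(sorted_pred) > 1 else np.array([], dtype=int)
    cut = np.concatenate([distinct, [len(sorted_pred) - 1]])
    tp = np.cumsum(sorted_obs)[cut]
    fp = (cut + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = sorted_pred[cut]
    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr[1:] - fpr[1:]
    # ties toward the lower threshold: last maximal index in descending order
    best = len(youden) - 1 - int(np.argmax(youden[::-1]))
    youden_threshold = float(thresholds[best])
    sens = float(tpr[best + 1])
    spec_ = 1.0 - float(fpr[best + 1])

    asc = np.argsort(predicted, kind="stable")
    bins = np.array_split(asc, calibration_groups)
    calibration = [
        (float(predicted[b].mean()), float(observed[b].mean()))
        for b in bins
        if len(b) > 0
    ]
    hl = hosmer_lemeshow(predicted, observed, groups=hl_groups)
    return ValidationReport(
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        youden_threshold=youden_threshold,
        sensitivity=sens,
        specificity=spec_,
        calibration_bins=calibration,
        hl=hl,
    )


def validate_model(
    spec: NetworkSpec, cohort: Cohort | pd.DataFrame, target: str | None = None
) -> ValidationReport:
    """Score the cohort with the model and assemble one validation report."""
    frame = cohort.records if isinstance(cohort, Cohort) else cohort
    target = target if target is not None else spec.outcome
    if target not in frame.columns:
        raise KeyError(f"cohort lacks target column {target!r}")
    predicted = predict_proba(spec, frame, target)
    observed = (frame[target] == "yes").to_numpy(dtype=float)
    return roc_curve(predicted, observed)


def report_to_dict(report: ValidationReport) -> dict:
    return {
        "auc": report.auc,
        "youden_threshold": report.youden_threshold,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "hl_chi2": report.hl[0],
        "hl_df": report.hl[1],
        "hl_p": report.hl[2],
        "roc_points": report.roc_points,
        "calibration_bins": report.calibration_bins,
    }


def plot_validation(report: ValidationReport, path) -> None:
    """ROC and calibration side by side to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fpr, tpr = zip(*report.roc_points)
    ax1.plot(fpr, tpr, color="steelblue")
    ax1.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title(f"ROC (AUC = {report.auc:.3f})")
    mean_pred, obs_freq = zip(*report.calibration_bins)
    ax2.plot(mean_pred, obs_freq, marker="o", color="darkorange")
    ax2.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax2.set_xlabel("mean predicted probability")
    ax2.set_ylabel("observed frequency")
    ax2.set_title("Calibration")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sensitivity(table: pd.DataFrame, path) -> None:
    """Tornado-style horizontal bar chart of sensitivity indices."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1))
    ordered = table.sort_values("index")
    ax.barh(ordered["node"], ordered["index"], color="steelblue")
    ax.set_xlabel(f"sensitivity index ({table['method'].iloc[0]})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
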