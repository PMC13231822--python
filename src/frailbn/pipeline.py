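"""End-to-end study pipeline with config, logging and a run manifest.

Stages: simulate (or load) a cohort -> univariate screening -> logistic
regression -> node selection -> structure learning with expert constraints
-> maximum-likelihood CPTs -> conditional table and scenario inference ->
sensitivity analysis -> validation.  Outputs are plain-text artifacts plus
a manifest recording seed, config hash and library versions, so a run is
reproducible bit for bit (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .inference import conditional_table, fit_cpts, posterior, with_cpts
from .logistic import build_design, collinearity, fit_logistic, regression_frame
from .network import NetworkSpec
from .reference import build_reference_network
from .screening import screen, screening_frame
from .structure import EdgeConstraints, mmhc
from .synthetic import Cohort, sample_cohort
from .validation import (
    report_to_dict,
    sensitivity_table,
    validate_model,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "screen",
    "regress",
    "learn",
    "fit",
    "infer",
    "sensitivity",
    "validate",
)


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: str = "pipeline-out"
    seed: int = 0
    n: int = 680
    alpha: float = 0.05
    cohort_path: str | None = None
    network_path: str | None = None
    constraints_path: str | None = None
    node_selection: str = "regression"  # regression | reference
    pseudocount: float = 0.0
    scenario_evidence: dict[str, str] = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise PipelineConfigError("seed must be an integer")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise PipelineConfigError("nothing to run: all stages toggled off")
        if self.node_selection not in ("regression", "reference"):
            raise PipelineConfigError("node_selection must be regression|reference")
        for path_attr in ("cohort_path", "network_path", "constraints_path"):
            value = getattr(self, path_attr)
            if value is not None and not Path(value).exists():
                raise PipelineConfigError(f"{path_attr} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


@dataclass
class StudyReport:
    """In-memory results of a pipeline run plus where they were written."""

    config: PipelineConfig
    cohort: Cohort | None = None
    screening: pd.DataFrame | None = None
    regression: pd.DataFrame | None = None
    vif: pd.DataFrame | None = None
    selected_nodes: list[str] | None = None
    structure_edges: list[tuple[str, str]] | None = None
    fitted_network: NetworkSpec | None = None
    conditional: pd.DataFrame | None = None
    scenario: dict | None = None
    sensitivity: pd.DataFrame | None = None
    validation: dict | None = None
    manifest: dict | None = None


def _load_constraints(path: str | None) -> EdgeConstraints:
    if path is None:
        return EdgeConstraints()
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return EdgeConstraints(
        whitelist=frozenset(tuple(e) for e in data.get("whitelist", [])),
        blacklist=frozenset(tuple(e) for e in data.get("blacklist", [])),
    )


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the configured stages; any failure aborts with the stage name.

    Partial outputs written before a failure are retained in ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = StudyReport(config=config)
    stage = "setup"
    try:
        network = (
            NetworkSpec.from_json(config.network_path)
            if config.network_path
            else build_reference_network()
        )
        outcome = network.outcome
        reference_levels = {
            v.name: v.states[0]
            for v in network.variables
            if v.kind == "categorical"
        }

        stage = "simulate"
        if config.cohort_path is not None:
            cohort = Cohort.from_csv(config.cohort_path)
            logger.info("loaded cohort of %d records", cohort.n)
        elif "simulate" in config.stages:
            cohort = sample_cohort(network, config.n, seed=config.seed)
            cohort.to_csv(outdir / "cohort.csv")
            logger.info("simulated cohort of %d records (seed=%d)", cohort.n, config.seed)
        else:
            raise PipelineConfigError(
                "no cohort: provide cohort_path or enable the simulate stage"
            )
        report.cohort = cohort

        selected = [v for v in network.categorical_nodes if v != outcome]
        if "screen" in config.stages:
            stage = "screen"
            results = screen(cohort, outcome, alpha=config.alpha)
            frame = screening_frame(results)
            frame.to_csv(outdir / "screening.tsv", sep="\t", index=False)
            frame.to_json(outdir / "screening.json", orient="records", indent=2)
            report.screening = frame
            screened = [r.variable for r in results if r.selected]
            selected = [v for v in selected if v in screened] or selected
            logger.info("screening selected %d variables", len(screened))

        if "regress" in config.stages:
            stage = "regress"
            design = build_design(cohort, selected, reference_levels)
            fit = fit_logistic(
                design, (cohort.records[outcome] == "yes").to_numpy(dtype=float)
            )
            frame = regression_frame(fit)
            frame.to_csv(outdir / "regression.tsv", sep="\t", index=False)
            frame.to_json(outdir / "regression.json", orient="records", indent=2)
            report.regression = frame
            coll = collinearity(design)
            report.vif = pd.DataFrame(
                {"term": coll.terms, "tolerance": coll.tolerance, "vif": coll.vif}
            )
            report.vif.to_csv(outdir / "collinearity.tsv", sep="\t", index=False)
            if config.node_selection == "regression":
                keep = {
                    e.term.split("=", 1)[0]
                    for e in fit.effects
                    if e.term != "intercept" and e.p < config.alpha
                }
                selected = [v for v in selected if v in keep] or selected

        if config.node_selection == "reference":
            selected = [v for v in network.categorical_nodes if v != outcome]
        nodes = selected + [outcome]
        report.selected_nodes = nodes

        edges = list(network.edges)
        if "learn" in config.stages:
            stage = "learn"
            constraints = _load_constraints(config.constraints_path)
            learned = mmhc(
                cohort.records[nodes], constraints=constraints, alpha=config.alpha
            )
            edges = [e for e in learned.edges]
            structure_spec = {
                "variables": [
                    {
                        "name": v.name,
                        "states": list(v.states),
                        "role": v.role,
                        "kind": v.kind,
                    }
                    for v in network.variables
                    if v.name in nodes
                ],
                "edges": [list(e) for e in edges],
                "cpts": {},
                "metadata": {"bic": learned.score},
            }
            (outdir / "structure.json").write_text(
                json.dumps(structure_spec, indent=2, ensure_ascii=False),
                encoding="utf-8",
            )
            report.structure_edges = edges
            logger.info("learned %d edges (BIC=%.2f)", len(edges), learned.score)

        model = network
        if "fit" in config.stages:
            stage = "fit"
            sub = NetworkSpec(
                [v for v in network.variables if v.kind != "categorical" or v.name in nodes],
                [e for e in edges if e[0] in nodes and e[1] in nodes],
                {},
            )
            cpts = fit_cpts(
                cohort, sub, dag_edges=sub.edges, pseudocount=config.pseudocount
            )
            model = with_cpts(sub, cpts)
            model.to_json(outdir / "network_fitted.json")
            model.to_dot(outdir / "network_fitted.dot")
            report.fitted_network = model

        if "infer" in config.stages:
            stage = "infer"
            # condition on the input network's designated direct-influence set
            # (falls back to the fitted structure's parents if any is absent)
            designated = network.parents(outcome)
            nodes_set = set(model.categorical_nodes)
            given = (
                designated
                if designated and set(designated) <= nodes_set
                else model.parents(outcome)
            )
            table = conditional_table(model, outcome, given=given)
            table.to_csv(outdir / "conditional_table.tsv", sep="\t", index=False)
            report.conditional = table
            evidence = dict(config.scenario_evidence)
            if not evidence:
                evidence = {
                    p: "yes" for p in given if "yes" in model.states_of(p)
                }
            post = posterior(model, outcome, evidence)
            report.scenario = {
                "evidence": evidence,
                "posterior": {k: float(v) for k, v in post.items()},
            }
            (outdir / "scenario.json").write_text(
                json.dumps(report.scenario, indent=2, ensure_ascii=False),
                encoding="utf-8",
            )

        if "sensitivity" in config.stages:
            stage = "sensitivity"
            table = sensitivity_table(model, outcome)
            table.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
            report.sensitivity = table

        if "validate" in config.stages:
            stage = "validate"
            vreport = validate_model(model, cohort, outcome)
            report.validation = report_to_dict(vreport)
            (outdir / "validation.json").write_text(
                json.dumps(report.validation, indent=2), encoding="utf-8"
            )

        stage = "manifest"
        report.manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": _config_hash(config),
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "stages_run": [s for s in ALL_STAGES if s in config.stages],
        }
        (outdir / "manifest.json").write_text(
            json.dumps(report.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
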