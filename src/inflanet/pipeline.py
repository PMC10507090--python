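"""End-to-end study orchestration: the four-network analysis design.

Stages: acute-inflammation screening (CRP >= 10 mg/L exclusion), node-set
assembly per network recipe, EBIC-glasso estimation, centrality and
influential-cytokine selection, spinglass community consensus, bootstrap
accuracy/stability, and permutation comparison between treatment arms —
with every artifact persisted and a run manifest recording settings and
seeds.

Network recipes (the study design):

1. all cytokines — estimation, strength centrality, influential selection,
   edge bootstrap, CS-coefficient;
2. influential cytokines + all symptom items + covariates — estimation,
   spinglass consensus, edge bootstrap; defines "relevant symptoms" (those
   in a community receiving a nonzero edge from an influential cytokine);
3. treatment node (1=placebo / 2=active) + influential cytokines +
   relevant symptoms + covariates + baseline overall-severity node —
   estimation, edge bootstrap;
4. per-arm networks of influential cytokines + relevant symptoms +
   covariates — baseline between-arm NCT, within-arm paired NCTs
   (baseline vs follow-up), between-arm follow-up NCT, with post-hoc
   strength-centrality and edge-invariance tests when significant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities as comm
from . import compare as cmp
from . import metrics, stability
from .cohort import ROLE_ORDER, CohortTable, CohortError, VariableMeta
from .estimate import EstimatorSettings, estimate_network
from .synth import StudyCohorts, make_study_cohorts


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# screening filter
# ---------------------------------------------------------------------------


def exclude_acute_inflammation(
    cohort: CohortTable,
    threshold: float = 10.0,
    missing_policy: str = "error",
    column: str | None = None,
) -> tuple[CohortTable, dict]:
    """Remove subjects whose screening CRP is at or above ``threshold`` mg/L.

    The boundary value is excluded (>= rule). ``missing_policy``: "error"
    fails listing subjects with missing CRP, "drop" excludes them, "keep"
    retains them. Returns the filtered cohort and an exclusion report with
    the percentage excluded to one decimal.
    """
    if threshold <= 0:
        raise PipelineError("filter", "threshold must be positive")
    if column is None:
        screening = cohort.names_with(role="screening")
        if not screening:
            raise PipelineError("filter", "no screening CRP column present")
        column = screening[0]
    elif column not in cohort.variables:
        raise PipelineError("filter", f"CRP column {column!r} absent")
    crp = cohort.data[column]
    missing = crp.isna()
    if missing.any():
        if missing_policy == "error":
            ids = list(cohort.data.index[missing])
            raise PipelineError("filter", f"missing CRP for subjects {ids}")
        if missing_policy not in ("drop", "keep"):
            raise PipelineError("filter", f"unknown missing policy {missing_policy!r}")
    excluded_mask = (crp >= threshold) | (missing if missing_policy == "drop" else False)
    keep = ~excluded_mask
    total = len(cohort.data)
    excluded = int(excluded_mask.sum())
    report = {
        "column": column,
        "threshold": threshold,
        "total": total,
        "excluded": excluded,
        "retained": total - excluded,
        "percent_excluded": round(100.0 * excluded / total, 1) if total else 0.0,
    }
    return cohort.subset(rows=cohort.data.index[keep]), report


# ---------------------------------------------------------------------------
# node assembly
# ---------------------------------------------------------------------------


@dataclass
class NodeRecipe:
    """Which variables enter a network, by role/instrument.

    ``cytokines`` is a list of names or ``"all"``; ``symptom_instruments``
    a list of instrument tags or ``"all"`` or ``[]``; ``symptom_items``
    optionally names explicit items instead.
    """

    cytokines: list[str] | str = "all"
    symptom_instruments: list[str] | str = ()
    symptom_items: list[str] = field(default_factory=list)
    covariates: bool = False
    treatment: bool = False
    severity: bool = False
    severity_name: str = "PANSS_total"


def compute_severity(cohort: CohortTable, instruments: tuple[str, ...] = ("PANSS_P", "PANSS_N")) -> pd.Series:
    """Overall severity as the raw PANSS total (sum of available subscales)."""
    items: list[str] = []
    for ins in instruments:
        items += cohort.names_with(role="symptom", instrument=ins)
    if not items:
        raise PipelineError("assemble", "no PANSS items available for the severity node")
    return cohort.data[items].sum(axis=1)


def assemble_node_set(
    cohort: CohortTable,
    recipe: NodeRecipe,
    severity_source: CohortTable | None = None,
) -> CohortTable:
    """Column-ordered analysis table for one network recipe.

    Ordering is deterministic: cytokines, symptoms by instrument,
    covariates, treatment, severity. The severity node is computed from
    ``severity_source`` (e.g. the baseline table) when given, else from
    the cohort itself, aligned by subject id.
    """
    cols: list[str] = []
    if recipe.cytokines == "all":
        cols += cohort.names_with(role="cytokine")
    else:
        for c in recipe.cytokines:
            if c not in cohort.variables:
                raise PipelineError("assemble", f"cytokine {c!r} absent from cohort")
            cols.append(c)
    if recipe.symptom_items:
        for s in recipe.symptom_items:
            if s not in cohort.variables:
                raise PipelineError("assemble", f"symptom item {s!r} absent from cohort")
            cols.append(s)
    else:
        instruments = recipe.symptom_instruments
        if instruments == "all":
            instruments = sorted(
                {m.instrument for m in cohort.meta if m.role == "symptom"},
                key=lambda ins: cohort.variables.index(
                    cohort.names_with(role="symptom", instrument=ins)[0]
                ),
            )
        for ins in instruments:
            items = cohort.names_with(role="symptom", instrument=ins)
            if not items:
                raise PipelineError("assemble", f"no symptom items for instrument {ins!r}")
            cols += items
    if recipe.covariates:
        cols += cohort.names_with(role="covariate")
    if recipe.treatment:
        treat = cohort.names_with(role="treatment")
        if not treat:
            raise PipelineError("assemble", "treatment node requested but absent")
        cols += treat
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise PipelineError("assemble", f"duplicate variables requested: {dupes}")
    out = cohort.subset(columns=cols)
    if recipe.severity:
        src = severity_source or cohort
        sev = compute_severity(src).reindex(out.data.index)
        if sev.isna().any():
            raise PipelineError("assemble", "severity source missing some subjects")
        df = out.data.copy()
        df[recipe.severity_name] = sev
        meta = list(out.meta) + [
            VariableMeta(recipe.severity_name, "severity", "continuous")
        ]
        out = CohortTable(df, meta, timepoint=out.timepoint)
    return out


# ---------------------------------------------------------------------------
# study configuration and report
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """All pipeline knobs; YAML/JSON loadable."""

    seed: int = 0
    output_dir: str = "inflanet_run"
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    crp_threshold: float = 10.0
    crp_missing_policy: str = "error"
    bootstrap_B: int = 1000
    stability_B: int = 1000
    drop_grid: tuple[float, ...] = stability.DEFAULT_DROP_GRID
    consensus_runs: int = 1000
    nct_permutations: int = 1000
    nct_alpha: float = 0.05
    posthoc_adjustment: str = "holm"
    influence_rule: str = "z_threshold"
    influence_param: float = 1.0
    networks: tuple[int, ...] = (1, 2, 3, 4)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        est = raw.pop("estimator", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.estimator = EstimatorSettings(**est)
        cfg.drop_grid = tuple(cfg.drop_grid)
        cfg.networks = tuple(cfg.networks)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _round_weights(w: np.ndarray, nd: int = 2) -> list:
    return np.round(w, nd).tolist()


class StudyReport(dict):
    """Plain dict with a manifest of written artifact files."""

    def __init__(self):
        super().__init__()
        self["artifacts"] = []

    def add_artifact(self, path: Path) -> None:
        self["artifacts"].append(str(path))


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def _relevant_symptoms(
    net, assignment: comm.CommunityAssignment, influential: list[str], cohort: CohortTable
) -> list[str]:
    """Symptoms in communities receiving a nonzero influential-cytokine edge."""
    symptoms = set(cohort.names_with(role="symptom"))
    labels = dict(zip(assignment.node_names, assignment.labels))
    relevant_communities = set()
    for c in influential:
        i = net.node_names.index(c)
        for j, name in enumerate(net.node_names):
            if name in symptoms and net.weights[i, j] != 0:
                relevant_communities.add(labels[name])
    return [s for s in cohort.names_with(role="symptom") if labels.get(s) in relevant_communities]


def run_study_pipeline(
    config: StudyConfig,
    cohorts: StudyCohorts | None = None,
) -> StudyReport:
    """Execute the configured study on the given (or freshly simulated) cohorts.

    Writes weight matrices (CSV), edge lists (TSV), GraphML networks,
    centrality/community/bootstrap tables (CSV), NCT results (JSON), and a
    run manifest. Stage failures are re-raised with the stage name after a
    failure manifest is written; artifacts produced so far are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = StudyReport()
    report["config"] = config.to_dict()
    if cohorts is None:
        cohorts = make_study_cohorts(seed=config.seed)
    stage = "setup"
    try:
        # ------------------------------------------------------------ filter
        stage = "filter"
        baseline, excl = exclude_acute_inflammation(
            cohorts.baseline, config.crp_threshold, config.crp_missing_policy
        )
        followup = cohorts.followup.subset(
            rows=[i for i in baseline.data.index if i in cohorts.followup.data.index]
        )
        report["filter"] = excl

        est = config.estimator
        results: dict = {}
        influential: list[str] = []
        relevant: list[str] = []

        # --------------------------------------------------------- network 1
        if 1 in config.networks:
            stage = "network1"
            tbl1 = assemble_node_set(baseline, NodeRecipe(cytokines="all"))
            net1 = estimate_network(tbl1, settings=est, gamma=est.gamma)
            cent1 = metrics.strength_centrality(net1)
            sel = metrics.select_influential(cent1, config.influence_rule, config.influence_param)
            influential = sel.nodes
            boot1 = stability.nonparametric_edge_bootstrap(
                tbl1, config.bootstrap_B, est, seed=config.seed + 11
            )
            cs1 = stability.case_dropping_stability(
                tbl1, config.drop_grid, config.stability_B, est, seed=config.seed + 12
            )
            for path in (
                net1.to_matrix_csv(out / "network1_weights.csv"),
                net1.to_edge_tsv(out / "network1_edges.tsv"),
                net1.to_graphml(out / "network1.graphml"),
            ):
                report.add_artifact(path)
            cent_path = out / "network1_centrality.csv"
            cent1.to_csv(cent_path)
            report.add_artifact(cent_path)
            report.add_artifact(boot1.to_json(out / "network1_bootstrap.json"))
            report.add_artifact(cs1.to_json(out / "network1_stability.json"))
            results["network1"] = {
                "nodes": net1.node_names,
                "edge_count": net1.edge_count,
                "global_strength": round(metrics.global_strength(net1), 2),
                "influential": sel.to_dict(),
                "cs_coefficient": cs1.cs_coefficient,
                "selected_lambda": net1.selected_lambda,
            }

        # --------------------------------------------------------- network 2
        if 2 in config.networks:
            stage = "network2"
            if not influential:
                raise PipelineError(stage, "no influential cytokines selected by network 1")
            rec2 = NodeRecipe(
                cytokines=influential, symptom_instruments="all", covariates=True
            )
            tbl2 = assemble_node_set(baseline, rec2)
            net2 = estimate_network(tbl2, settings=est, gamma=est.gamma)
            median, rep_seed, assign = comm.consensus_community_count(
                net2, runs=config.consensus_runs, seed=config.seed + 21
            )
            boot2 = stability.nonparametric_edge_bootstrap(
                tbl2, config.bootstrap_B, est, seed=config.seed + 22
            )
            relevant = _relevant_symptoms(net2, assign, influential, baseline)
            for path in (
                net2.to_matrix_csv(out / "network2_weights.csv"),
                net2.to_edge_tsv(out / "network2_edges.tsv"),
                net2.to_graphml(out / "network2.graphml"),
            ):
                report.add_artifact(path)
            comm_path = out / "network2_communities.csv"
            assign.to_frame().to_csv(comm_path, index=False)
            report.add_artifact(comm_path)
            report.add_artifact(boot2.to_json(out / "network2_bootstrap.json"))
            cyto_sympt = [
                r
                for _, r in boot2.edge_table().iterrows()
                if (r["node_a"] in influential) != (r["node_b"] in influential)
                and r["observed"] != 0
            ]
            results["network2"] = {
                "nodes": net2.node_names,
                "edge_count": net2.edge_count,
                "median_communities": median,
                "reproducing_seed": rep_seed,
                "community_params": asdict(assign.params),
                "relevant_symptoms": relevant,
                "cytokine_symptom_edges": [
                    {
                        "node_a": r["node_a"],
                        "node_b": r["node_b"],
                        "weight": round(float(r["observed"]), 2),
                        "inclusion_proportion": float(r["inclusion_proportion"]),
                        "reliable": bool(r["reliable"]),
                    }
                    for r in cyto_sympt
                ],
            }

        # --------------------------------------------------------- network 3
        if 3 in config.networks:
            stage = "network3"
            if not influential:
                raise PipelineError(stage, "network 3 requires influential cytokines")
            rec3 = NodeRecipe(
                cytokines=influential,
                symptom_items=relevant,
                covariates=True,
                treatment=True,
                severity=True,
            )
            tbl3 = assemble_node_set(followup, rec3, severity_source=baseline)
            net3 = estimate_network(tbl3, settings=est, gamma=est.gamma)
            boot3 = stability.nonparametric_edge_bootstrap(
                tbl3, config.bootstrap_B, est, seed=config.seed + 31
            )
            for path in (
                net3.to_matrix_csv(out / "network3_weights.csv"),
                net3.to_edge_tsv(out / "network3_edges.tsv"),
                net3.to_graphml(out / "network3.graphml"),
            ):
                report.add_artifact(path)
            report.add_artifact(boot3.to_json(out / "network3_bootstrap.json"))
            treat_name = followup.names_with(role="treatment")[0]
            treat_edges = [
                {
                    "node_a": r["node_a"],
                    "node_b": r["node_b"],
                    "weight": round(float(r["observed"]), 2),
                    "inclusion_proportion": float(r["inclusion_proportion"]),
                    "reliable": bool(r["reliable"]),
                }
                for _, r in boot3.edge_table().iterrows()
                if treat_name in (r["node_a"], r["node_b"]) and r["observed"] != 0
            ]
            results["network3"] = {
                "nodes": net3.node_names,
                "edge_count": net3.edge_count,
                "treatment_edges": treat_edges,
            }

        # --------------------------------------------------------- network 4
        if 4 in config.networks:
            stage = "network4"
            if not influential:
                raise PipelineError(stage, "network 4 requires influential cytokines")
            rec4 = NodeRecipe(cytokines=influential, symptom_items=relevant, covariates=True)
            treat_name = baseline.names_with(role="treatment")[0]

            def arm(cohort: CohortTable, code: int) -> CohortTable:
                rows = cohort.data.index[cohort.data[treat_name] == code]
                return assemble_node_set(cohort.subset(rows=rows), rec4)

            arms = {
                ("baseline", 1): arm(baseline, 1),
                ("baseline", 2): arm(baseline, 2),
                ("followup", 1): arm(followup, 1),
                ("followup", 2): arm(followup, 2),
            }
            ncts: dict[str, cmp.NCTResult] = {}
            ncts["baseline_between"] = cmp.nct(
                arms[("baseline", 1)], arms[("baseline", 2)],
                config.nct_permutations, est, "independent",
                seed=config.seed + 41, alpha=config.nct_alpha,
            )
            for code, label in ((1, "placebo"), (2, "active")):
                ncts[f"within_{label}"] = cmp.nct(
                    arms[("baseline", code)], arms[("followup", code)],
                    config.nct_permutations, est, "paired",
                    seed=config.seed + 42 + code, alpha=config.nct_alpha,
                )
            ncts["followup_between"] = cmp.nct(
                arms[("followup", 1)], arms[("followup", 2)],
                config.nct_permutations, est, "independent",
                seed=config.seed + 45, alpha=config.nct_alpha,
            )
            results["network4"] = {}
            for label, res in ncts.items():
                gs_a, gs_b = res.global_strengths()
                entry = {
                    "design": res.design,
                    "S": round(res.S_observed, 2),
                    "M": round(res.M_observed, 2),
                    "p_S": res.p_S,
                    "p_M": res.p_M,
                    "global_strength_a": round(gs_a, 2),
                    "global_strength_b": round(gs_b, 2),
                    "significant": res.significant,
                }
                report.add_artifact(res.to_json(out / f"nct_{label}.json"))
                if res.significant:
                    cent = cmp.posthoc_strength_centrality(res)
                    edges = cmp.posthoc_edge_invariance(res, config.posthoc_adjustment)
                    cent_p = out / f"nct_{label}_posthoc_centrality.csv"
                    edge_p = out / f"nct_{label}_posthoc_edges.csv"
                    cent.to_csv(cent_p)
                    edges.to_csv(edge_p, index=False)
                    report.add_artifact(cent_p)
                    report.add_artifact(edge_p)
                    entry["posthoc_centrality"] = str(cent_p)
                    entry["posthoc_edges"] = str(edge_p)
                results["network4"][label] = entry

        # ------------------------------------------------------------ report
        stage = "report"
        report["results"] = results
        used = set()
        for key in results:
            used.update(results[key].get("nodes", []))
        report["role_map"] = {
            "used_by_recipe": sorted(used & set(cohorts.baseline.variables)),
            "explicitly_dropped": sorted(set(cohorts.baseline.variables) - used),
        }
        report["seeds"] = {"root": config.seed}
        manifest = out / "manifest.json"
        manifest.write_text(json.dumps(report, indent=1, default=str))
        report.add_artifact(manifest)
        return report
    except PipelineError:
        _write_failure(out, report, stage)
        raise
    except Exception as exc:  # wrap with stage name
        _write_failure(out, report, stage)
        raise PipelineError(stage, str(exc)) from exc


def _write_failure(out: Path, report: StudyReport, stage: str) -> None:
    try:
        payload = dict(report)
        payload["failed_stage"] = stage
        (out / "failure_manifest.json").write_text(json.dumps(payload, indent=1, default=str))
    except Exception:  # pragma: no cover - best effort
        pass
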