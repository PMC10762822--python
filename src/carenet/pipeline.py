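"""End-to-end orchestration: ingest -> cohorts -> networks -> metrics ->
weight training -> validation scoring -> model comparison -> reports.

Two entry points:

- :func:`two_stage_analysis` runs the whole analysis in memory on loaded
  tables (the workhorse for simulation studies);
- :func:`run_pipeline` wraps it with file I/O, a run manifest and reports,
  driven by a validated :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import claims, metrics, network
from .estimation import (DesignMatrix, FCDModel, ModelComparison,
                         assemble_design, compare_models, estimate_fcd_weights,
                         relative_risk_by_decile, score_validation_year)
from .metrics import enumerate_connection_types, fit_tertile_cutpoints
from .quarters import Quarter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "two_stage_analysis", "run_pipeline",
           "render_comparison_report"]


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    input_dir: str
    out_dir: str
    seed: int = 0
    specialties: tuple[str, ...] = claims.DEFAULT_SPECIALTIES
    column_map: dict[str, str] = Field(default_factory=dict)
    cohort_code_groups: tuple[str, ...] = ("schizophrenia", "depression",
                                           "substance_abuse", "anxiety")
    subcohort_code_group: str = "schizophrenia"
    index_year: int = 2015
    followup_start_offset: int = 4
    n_followup_quarters: int = 8
    min_w: int = 3
    lookback_length: int = 2
    quadrature_nodes: int = 15
    region_percentile: float = 0.95
    fixed_controls: tuple[str, ...] = ("age_z", "female", "comorb_depression",
                                       "comorb_substance")
    timevarying_controls: tuple[str, ...] = ("specialist_contacts",)
    #: skip weight training / comparison, only compute descriptive metrics
    baseline_only: bool = False
    log_level: str = "INFO"

    def claims_config(self) -> claims.ClaimsConfig:
        return claims.ClaimsConfig(
            specialties=self.specialties, column_map=self.column_map,
            cohort_code_groups=self.cohort_code_groups,
            subcohort_code_group=self.subcohort_code_group,
            index_year=self.index_year,
            followup_start_offset=self.followup_start_offset,
            n_followup_quarters=self.n_followup_quarters,
            lookback_length=self.lookback_length)


@dataclass
class AnalysisResult:
    """Everything the two-stage analysis produces."""

    registry: metrics.ConnectionTypeRegistry
    cutpoints: metrics.TertileCutpoints
    model: FCDModel
    comparison: Optional[ModelComparison]
    rr_by_decile: Optional[pd.DataFrame]
    training_table: pd.DataFrame
    validation_table: pd.DataFrame
    graphs: dict[int, network.ProviderSharingGraph] = field(repr=False, default=None)


def _controls_frame(patients: pd.DataFrame, timevarying: pd.DataFrame,
                    keys: pd.DataFrame, fixed: Sequence[str],
                    tv: Sequence[str]) -> pd.DataFrame:
    present_fixed = [c for c in fixed if c in patients.columns]
    out = keys.merge(patients[["patient_id"] + present_fixed],
                     on="patient_id", how="left")
    if tv:
        out = out.merge(timevarying[["patient_id", "year", "quarter"] + list(tv)],
                        on=["patient_id", "year", "quarter"], how="left")
    for c in present_fixed + list(tv):
        out[c] = out[c].astype(float)
    return out


def two_stage_analysis(visits: pd.DataFrame, diagnoses: pd.DataFrame,
                       patients: pd.DataFrame, timevarying: pd.DataFrame,
                       outcomes: pd.DataFrame, config: RunConfig,
                       compute_se: bool = True) -> AnalysisResult:
    """Run the full two-stage design on in-memory tables.

    Training year = follow-up quarters 1..4 (weights estimated on the 3k
    link dummies + controls); validation year = quarters 5..8 (frozen
    weights collapsed to one FCD score; baseline/+CD/+FCD comparison).
    """
    ccfg = config.claims_config()
    registry = enumerate_connection_types(config.specialties)

    validated = claims.validate_diagnoses(diagnoses, ccfg)
    cohorts = claims.assign_cohorts(validated, patients, ccfg)
    psychiatric = cohorts["patient_id"].tolist()
    sub = cohorts[cohorts["cohort"] == "schizophrenia_subcohort"]
    if sub.empty:
        raise ValueError("no subcohort members; cannot model outcomes")

    region_flags = dict.fromkeys(visits["provider_id"].unique(), True)
    retained = network.filter_providers(visits, region_flags,
                                        config.region_percentile)

    fu_by_pid = {
        r.patient_id: claims.followup_quarters(
            Quarter(int(r.index_year), int(r.index_quarter)), ccfg)
        for r in sub.itertuples()}
    years = sorted({q.year for fus in fu_by_pid.values() for q in fus}
                   | {claims.lookback_quarters(q, config.lookback_length)[-1].year
                      for fus in fu_by_pid.values() for q in fus})
    graphs = network.build_yearly_graphs(
        visits[visits["provider_id"].isin(retained)], psychiatric, years,
        min_w=config.min_w)

    n_train = config.n_followup_quarters // 2
    train_pq = [(pid, q) for pid, fus in sorted(fu_by_pid.items())
                for q in fus[:n_train]]
    valid_pq = [(pid, q) for pid, fus in sorted(fu_by_pid.items())
                for q in fus[n_train:]]
    nets_train = network.patient_networks_for_quarters(
        visits, train_pq, graphs, config.lookback_length, retained)
    nets_valid = network.patient_networks_for_quarters(
        visits, valid_pq, graphs, config.lookback_length, retained)

    sums_train = [metrics.decompose_sums(n, registry) for n in nets_train]
    cutpoints = fit_tertile_cutpoints(sums_train, registry)

    mt_train = metrics.metric_table(nets_train, registry, cutpoints)
    mt_valid = metrics.metric_table(nets_valid, registry, cutpoints)

    controls_train = _controls_frame(patients, timevarying, mt_train[
        ["patient_id", "year", "quarter"]], config.fixed_controls,
        config.timevarying_controls)
    controls_valid = _controls_frame(patients, timevarying, mt_valid[
        ["patient_id", "year", "quarter"]], config.fixed_controls,
        config.timevarying_controls)

    design_links = assemble_design(mt_train, controls_train, outcomes,
                                   "links", registry)
    model = estimate_fcd_weights(design_links, registry, cutpoints,
                                 quadrature_nodes=config.quadrature_nodes,
                                 seed=config.seed,
                                 training_window="follow-up quarters 1-4",
                                 compute_se=compute_se)

    mt_valid = score_validation_year(mt_valid, model)

    comparison = None
    rr = None
    if not config.baseline_only:
        designs = {
            "baseline": assemble_design(mt_valid, controls_valid, outcomes,
                                        "baseline"),
            "cd": assemble_design(mt_valid, controls_valid, outcomes, "cd"),
            "fcd": assemble_design(mt_valid, controls_valid, outcomes, "fcd"),
        }
        comparison = compare_models(designs, config.quadrature_nodes,
                                    compute_se=compute_se)
        fcd_fit = comparison.fits["fcd"]
        means = {c: float(designs["fcd"].X[c].mean())
                 for c in designs["fcd"].X.columns
                 if c not in ("const", "fcd_score")}
        try:
            rr = relative_risk_by_decile(mt_valid, fcd_fit, means)
        except ValueError as exc:
            logger.warning("skipping decile relative risks: %s", exc)

    return AnalysisResult(registry=registry, cutpoints=cutpoints, model=model,
                          comparison=comparison, rr_by_decile=rr,
                          training_table=mt_train, validation_table=mt_valid,
                          graphs=graphs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline run; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    t_start = time.time()
    in_dir, out = Path(config.input_dir), Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ccfg = config.claims_config()

    stage_times: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        stage_times[name] = time.time()

    try:
        _stage("ingest")
        visits = claims.read_visits(in_dir / "visits.csv", ccfg)
        diagnoses = claims.read_diagnoses(in_dir / "diagnoses.csv", ccfg)
        patients = claims.read_patients(in_dir / "patients.csv", ccfg)
        timevarying = claims.read_table(in_dir / "timevarying.csv")
        outcomes = claims.read_table(in_dir / "outcomes.csv")

        _stage("analysis")
        result = two_stage_analysis(visits, diagnoses, patients, timevarying,
                                    outcomes, config)

        _stage("artifacts")
        for year, g in (result.graphs or {}).items():
            g.write_edgelist(out / f"sharing_graph_{year}.csv")
        result.training_table.to_csv(out / "metrics_training.csv", index=False)
        result.validation_table.to_csv(out / "metrics_validation.csv", index=False)
        result.model.to_json(out / "fcd_model.json")
        shares_year = max(result.graphs) if result.graphs else None
        if shares_year is not None and result.graphs[shares_year].edges:
            shares = metrics.contribution_shares(result.graphs[shares_year],
                                                 result.registry)
            pd.DataFrame(
                [(result.registry.type_label(t), v) for t, v in shares.items()],
                columns=["connection_type", "share"],
            ).to_csv(out / "contribution_shares.csv", index=False)
            _write_lorenz(result.graphs[shares_year], result.registry,
                          out / "lorenz_by_connection_type.csv")
        if result.comparison is not None:
            text, as_json = render_comparison_report(result.comparison,
                                                     result.model)
            (out / "comparison.txt").write_text(text)
            (out / "comparison.json").write_text(json.dumps(as_json, indent=2))
        if result.rr_by_decile is not None:
            result.rr_by_decile.to_csv(out / "relative_risk_by_decile.csv",
                                       index=False)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted in stage {list(stage_times)[-1] if stage_times else 'setup'}: {exc}"
        ) from exc

    manifest = {
        "seed": config.seed,
        "config": config.model_dump(),
        "inputs": {f.name: _sha256(f) for f in sorted(in_dir.glob("*.csv"))},
        "versions": _versions(),
        "n_models": 0 if result.comparison is None else len(result.comparison.models),
        "has_comparison": result.comparison is not None,
        "stages": list(stage_times),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_lorenz(graph: network.ProviderSharingGraph,
                  registry: metrics.ConnectionTypeRegistry,
                  path: Path) -> None:
    """Lorenz points of edge-weight inequality, one curve per type."""
    by_type: dict[tuple[str, str], list[int]] = {}
    for (a, b), w in graph.edges.items():
        t = registry.type_of_pair(graph.provider_index[a],
                                  graph.provider_index[b])
        by_type.setdefault(t, []).append(w)
    rows = []
    for t, weights in sorted(by_type.items()):
        for pop, cum in metrics.lorenz_points(weights):
            rows.append((registry.type_label(t), pop, cum))
    pd.DataFrame(rows, columns=["connection_type", "cum_edge_fraction",
                                "cum_weight_fraction"]).to_csv(path,
                                                               index=False)


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__
    return {"carenet": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_comparison_report(comparison: ModelComparison,
                             model: FCDModel) -> tuple[str, dict]:
    """Human-readable comparison table plus a full-precision JSON twin.

    Lays out one column per model (baseline / +CD / +FCD) with coefficient
    estimates starred at p < .05 / .01 / .001, followed by -2 log L, AIC,
    BIC and the likelihood-ratio tests against the baseline.
    """
    order = [n for n in ("baseline", "cd", "fcd") if n in comparison.fits]
    fits = {n: comparison.fits[n] for n in order}
    rows: dict[str, dict[str, str]] = {}
    json_doc: dict = {"models": {}, "lrt": comparison.lrt}
    for name, fit in fits.items():
        frame = fit.summary_frame()
        json_doc["models"][name] = {
            "coefficients": {k: {"coef": float(frame.loc[k, "coef"]),
                                 "se": float(frame.loc[k, "se"]),
                                 "p": float(frame.loc[k, "p"])}
                             for k in frame.index},
            "sigma2": fit.sigma2,
            "minus2loglik": -2 * fit.loglik,
            "aic": fit.aic, "bic": fit.bic,
        }
        for k in frame.index:
            cell = f"{frame.loc[k, 'coef']:.2f}{_stars(frame.loc[k, 'p'])}"
            rows.setdefault(k, {})[name] = cell

    width = max(len(k) for k in rows) + 2
    header = "Variable".ljust(width) + "".join(f"{n:>16}" for n in order)
    lines = [header, "-" * len(header)]
    for k, per_model in rows.items():
        lines.append(k.ljust(width)
                     + "".join(f"{per_model.get(n, ''):>16}" for n in order))
    lines.append("-" * len(header))
    lines.append("sigma2 (subject)".ljust(width)
                 + "".join(f"{fits[n].sigma2:>16.3f}" for n in order))
    for label, attr in (("-2 Log Likelihood", "loglik"), ("AIC", "aic"),
                        ("BIC", "bic")):
        vals = [(-2 * fits[n].loglik if attr == "loglik"
                 else getattr(fits[n], attr)) for n in order]
        lines.append(label.ljust(width) + "".join(f"{v:>16.2f}" for v in vals))
    for name, t in comparison.lrt.items():
        lines.append(f"LRT {name} vs baseline: chi2({t['df']}) = "
                     f"{t['statistic']:.2f}, p = {t['p']:.3g}")
    lines.append("*p < .05, **p < .01, ***p < .001")
    return "\n".join(lines) + "\n", json_doc
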