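"""Two-stage FCD weight estimation, validation scoring and model comparison.

Stage one (training year): a random-intercept logit regresses quarterly
hospitalization on the 3k tertile link dummies plus controls; the fitted
coefficients are the connection-type weights and, together with the frozen
tertile cutpoints and training control means, form the :class:`FCDModel`.

Stage two (validation year): year-two networks are coded with the *frozen*
year-one cutpoints and collapsed to a single FCD score per patient-quarter
(controls fixed at training means, so the score carries network information
only).  Model comparison then asks whether adding care density (two
parameters: the value and an undefined-CD dummy) or the FCD score (one
parameter) improves a controls-only baseline, via likelihood-ratio tests,
AIC and BIC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .glmm import MixedLogitResult, fit_random_intercept_logit
from .metrics import (LINK_CATEGORIES, ConnectionTypeRegistry, TertileCutpoints,
                      dummy_column, link_dummy_columns)

__all__ = [
    "DesignMatrix",
    "FCDModel",
    "ModelComparison",
    "assemble_design",
    "estimate_fcd_weights",
    "score_validation_year",
    "compare_models",
    "relative_risk_by_decile",
]

KEY = ["patient_id", "year", "quarter"]


@dataclass
class DesignMatrix:
    """Patient-quarter design: outcome, covariate columns, subject ids."""

    y: np.ndarray
    X: pd.DataFrame
    subject_ids: np.ndarray
    keys: pd.DataFrame  # (patient_id, year, quarter) per row

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()][0]
            raise ValueError(f"design matrix contains missing cells (column {bad})")
        if len(set(self.X.columns)) != len(self.X.columns):
            raise ValueError("design matrix column names must be unique")

    @property
    def n_obs(self) -> int:
        return len(self.y)


def assemble_design(metric_table: pd.DataFrame, controls_table: pd.DataFrame,
                    outcomes: pd.DataFrame, coordination: str = "baseline",
                    registry: Optional[ConnectionTypeRegistry] = None,
                    ) -> DesignMatrix:
    """Join metrics, controls and outcomes into one model design.

    ``coordination`` selects which care-coordination columns enter:

    - ``"baseline"``: none (controls only);
    - ``"cd"``: care density (0-filled where undefined) plus the
      ``cd_undefined`` dummy flagging patients with fewer than two providers;
    - ``"fcd"``: the single ``fcd_score`` column;
    - ``"links"``: the 3k tertile dummies (training-year weight estimation).

    All tables must align exactly on (patient_id, year, quarter).
    """
    # every metric row needs exactly one control row and one outcome row;
    # the other tables may cover additional patient-quarters (e.g. the
    # outcome table spans both years)
    for name, tab in (("controls", controls_table), ("outcomes", outcomes)):
        merged_keys = metric_table[KEY].merge(tab[KEY].drop_duplicates(),
                                              on=KEY, how="left", indicator=True)
        off = merged_keys[merged_keys["_merge"] != "both"]
        if len(off):
            first = off.iloc[0]
            raise ValueError(
                f"{name} table misaligned with metric table; first offending key "
                f"({first.patient_id}, {first.year}Q{first.quarter})")

    df = metric_table.merge(controls_table, on=KEY).merge(
        outcomes[KEY + ["hospitalized"]], on=KEY)
    df = df.sort_values(KEY).reset_index(drop=True)

    control_cols = [c for c in controls_table.columns if c not in KEY]
    cols = ["const"] + control_cols
    df["const"] = 1.0
    if coordination == "baseline":
        pass
    elif coordination == "cd":
        df["cd_undefined"] = (~df["cd_defined"].astype(bool)).astype(float)
        cols += ["cd", "cd_undefined"]
    elif coordination == "fcd":
        if "fcd_score" not in df.columns:
            raise ValueError("metric table lacks fcd_score; score it first")
        cols += ["fcd_score"]
    elif coordination == "links":
        if registry is None:
            raise ValueError("registry required for the links design")
        cols += [c for c in link_dummy_columns(registry) if c in df.columns]
    else:
        raise ValueError(f"unknown coordination spec {coordination!r}")

    return DesignMatrix(
        y=df["hospitalized"].to_numpy(dtype=float),
        X=df[cols].astype(float),
        subject_ids=df["patient_id"].to_numpy(),
        keys=df[KEY].copy(),
    )


@dataclass
class FCDModel:
    """Trained FCD artifact: frozen cutpoints, weights, control means."""

    registry: ConnectionTypeRegistry
    cutpoints: TertileCutpoints
    beta0: float
    #: (connection type, category) -> coefficient; 3k entries, 0.0 for
    #: dummies never observed in training (unidentifiable, treated as null)
    link_weights: dict[tuple[tuple[str, str], str], float]
    link_ci: dict[tuple[tuple[str, str], str], tuple[float, float]]
    control_coefs: dict[str, dict[str, float]]  # name -> coef/se/lower/upper
    control_means: dict[str, float]
    sigma2: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    quadrature_nodes: int
    seed: Optional[int] = None
    training_window: Optional[str] = None

    def control_offset(self) -> float:
        """Control contribution with every control at its training mean."""
        return float(sum(self.control_coefs[c]["coef"] * self.control_means[c]
                         for c in self.control_coefs))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        reg = self.registry
        return {
            "provider_types": list(reg.provider_types),
            "cutpoints": {reg.type_label(t): list(v)
                          for t, v in self.cutpoints.cutpoints.items()},
            "beta0": self.beta0,
            "link_weights": {f"{reg.type_label(t)}|{c}": w
                             for (t, c), w in self.link_weights.items()},
            "link_ci": {f"{reg.type_label(t)}|{c}": list(v)
                        for (t, c), v in self.link_ci.items()},
            "control_coefs": self.control_coefs,
            "control_means": self.control_means,
            "sigma2": self.sigma2,
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "n_obs": self.n_obs, "n_subjects": self.n_subjects,
            "quadrature_nodes": self.quadrature_nodes,
            "seed": self.seed, "training_window": self.training_window,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FCDModel":
        from .metrics import enumerate_connection_types
        reg = enumerate_connection_types(d["provider_types"])
        label_to_type = {reg.type_label(t): t for t in reg.connection_types}

        def _key(s: str) -> tuple[tuple[str, str], str]:
            lab, cat = s.rsplit("|", 1)
            return (label_to_type[lab], cat)

        return cls(
            registry=reg,
            cutpoints=TertileCutpoints({label_to_type[k]: tuple(v)
                                        for k, v in d["cutpoints"].items()}),
            beta0=d["beta0"],
            link_weights={_key(k): v for k, v in d["link_weights"].items()},
            link_ci={_key(k): tuple(v) for k, v in d["link_ci"].items()},
            control_coefs=d["control_coefs"],
            control_means=d["control_means"],
            sigma2=d["sigma2"], loglik=d["loglik"], aic=d["aic"], bic=d["bic"],
            n_obs=d["n_obs"], n_subjects=d["n_subjects"],
            quadrature_nodes=d["quadrature_nodes"], seed=d.get("seed"),
            training_window=d.get("training_window"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FCDModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def estimate_fcd_weights(design: DesignMatrix, registry: ConnectionTypeRegistry,
                         cutpoints: TertileCutpoints,
                         quadrature_nodes: int = 15,
                         seed: Optional[int] = None,
                         training_window: Optional[str] = None,
                         compute_se: bool = True,
                         min_dummy_obs: int = 5) -> FCDModel:
    """Fit the training-year link-dummy model and wrap it as an FCDModel.

    A link weight is estimable only when its dummy fires often enough and
    its rows contain both events and non-events; otherwise the ML estimate
    is unbounded (quasi-separation) and a single wild coefficient would
    contaminate every downstream score.  Inestimable categories are folded
    into the missing reference (weight 0), the same treatment a category
    never observed in training receives.
    """
    all_dummies = set(link_dummy_columns(registry))
    present = [c for c in design.X.columns if c in all_dummies]
    control_cols = [c for c in design.X.columns
                    if c not in all_dummies and c != "const"]

    def _estimable(col: str) -> bool:
        mask = design.X[col].to_numpy() > 0
        if mask.sum() < min_dummy_obs:
            return False
        rate = design.y[mask].mean()
        return 0.0 < rate < 1.0

    nonzero = [c for c in present if _estimable(c)]
    X = design.X[["const"] + control_cols + nonzero]
    fit = fit_random_intercept_logit(design.y, X, design.subject_ids,
                                     quadrature_nodes=quadrature_nodes,
                                     compute_se=compute_se)
    ci = fit.conf_int()

    link_weights, link_ci = {}, {}
    for t in registry.connection_types:
        for cat in LINK_CATEGORIES:
            col = dummy_column(registry, t, cat)
            # |beta| > 10 on the log-odds scale signals residual
            # quasi-separation; treat as inestimable rather than propagate
            if col in nonzero and abs(fit.coef(col)) <= 10:
                link_weights[(t, cat)] = float(fit.coef(col))
                link_ci[(t, cat)] = (float(ci.loc[col, "lower"]),
                                     float(ci.loc[col, "upper"]))
            else:
                link_weights[(t, cat)] = 0.0
                link_ci[(t, cat)] = (float("nan"), float("nan"))

    control_coefs = {c: {"coef": float(fit.coef(c)),
                         "se": float(ci.loc[c, "se"]),
                         "lower": float(ci.loc[c, "lower"]),
                         "upper": float(ci.loc[c, "upper"])}
                     for c in control_cols}
    control_means = {c: float(design.X[c].mean()) for c in control_cols}

    return FCDModel(
        registry=registry, cutpoints=cutpoints,
        beta0=float(fit.coef("const")),
        link_weights=link_weights, link_ci=link_ci,
        control_coefs=control_coefs, control_means=control_means,
        sigma2=fit.sigma2, loglik=fit.loglik, aic=fit.aic, bic=fit.bic,
        n_obs=fit.n_obs, n_subjects=fit.n_subjects,
        quadrature_nodes=quadrature_nodes, seed=seed,
        training_window=training_window)


def score_validation_year(metric_table: pd.DataFrame,
                          model: FCDModel) -> pd.DataFrame:
    """Attach the frozen-weight FCD score to a (validation-year) metric table.

    The table's dummy columns must already be coded with the *training*
    cutpoints.  No refitting happens here; the score is a deterministic
    linear function of the dummies.
    """
    cols = link_dummy_columns(model.registry)
    missing = [c for c in cols if c not in metric_table.columns]
    if missing:
        raise ValueError(f"metric table lacks dummy column(s) {missing[:3]}; "
                         "registry mismatch or uncoded links")
    w = np.array([model.link_weights[(t, c)]
                  for t in model.registry.connection_types
                  for c in LINK_CATEGORIES])
    out = metric_table.copy()
    base = model.beta0 + model.control_offset()
    out["fcd_score"] = base + metric_table[cols].to_numpy(dtype=float) @ w
    return out


@dataclass
class ModelComparison:
    """Fit statistics for baseline / +CD / +FCD plus LRTs vs baseline."""

    models: dict[str, dict[str, float]]  # name -> loglik/aic/bic/n_params
    lrt: dict[str, dict[str, float]]     # name -> statistic/df/p
    fits: dict[str, MixedLogitResult] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"models": self.models, "lrt": self.lrt}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compare_models(designs: Mapping[str, DesignMatrix],
                   quadrature_nodes: int = 15,
                   compute_se: bool = True) -> ModelComparison:
    """Fit each design and run likelihood-ratio tests against ``baseline``.

    All designs must cover identical rows (same patient-quarters in the
    same order); they may differ only in their coordination columns.  LRT
    degrees of freedom are parameter-count differences, so +CD tests 2
    (value + undefined dummy) and +FCD tests 1 (single score).
    """
    if "baseline" not in designs:
        raise ValueError("a 'baseline' design is required")
    base = designs["baseline"]
    for name, d in designs.items():
        if not d.keys.reset_index(drop=True).equals(base.keys.reset_index(drop=True)):
            raise ValueError(f"design {name!r} rows differ from baseline rows")

    fits = {name: fit_random_intercept_logit(
                d.y, d.X, d.subject_ids, quadrature_nodes=quadrature_nodes,
                compute_se=compute_se)
            for name, d in designs.items()}

    models = {name: {"loglik": f.loglik, "aic": f.aic, "bic": f.bic,
                     "n_params": f.n_params}
              for name, f in fits.items()}
    lrt = {}
    fb = fits["baseline"]
    for name, f in fits.items():
        if name == "baseline":
            continue
        df = f.n_params - fb.n_params
        stat = max(0.0, 2.0 * (f.loglik - fb.loglik))
        p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
        if stat == 0.0:
            p = 1.0
        lrt[name] = {"statistic": stat, "df": df, "p": p}
    return ModelComparison(models=models, lrt=lrt, fits=fits)


def relative_risk_by_decile(scored: pd.DataFrame, fcd_fit: MixedLogitResult,
                            control_means: Optional[Mapping[str, float]] = None,
                            ) -> pd.DataFrame:
    """Predicted hospitalization risk by FCD-score decile, relative to median.

    Risk is predicted from the validation +FCD model for a population-median
    subject (random intercept 0) with controls at their means; deciles
    d1..d9 of the empirical score distribution are compared with the median
    (d5), whose relative risk is 1 by construction.
    """
    scores = scored["fcd_score"].to_numpy(dtype=float)
    if len(np.unique(scores)) < 10:
        raise ValueError("fewer than 10 distinct FCD scores; "
                         "use coarser quantiles instead of deciles")
    gamma_fcd = fcd_fit.coef("fcd_score")
    base = fcd_fit.coef("const")
    for name in fcd_fit.param_names:
        if name in ("const", "fcd_score"):
            continue
        mean = (control_means or {}).get(name)
        if mean is None:
            raise ValueError(f"no control mean supplied for {name!r}")
        base += fcd_fit.coef(name) * mean

    qs = np.quantile(scores, np.arange(1, 10) / 10)
    p_median = special.expit(base + gamma_fcd * qs[4])
    rows = []
    for d, s in enumerate(qs, start=1):
        p = special.expit(base + gamma_fcd * s)
        rr = 1.0 if d == 5 else float(p / p_median)
        rows.append({"decile": d, "fcd_score": float(s),
                     "risk": float(p), "relative_risk": rr})
    return pd.DataFrame(rows)
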