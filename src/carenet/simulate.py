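"""Synthetic claims bundles with known connection-type ground truth.

The generator emulates the structural features of statutory-insurer claims
that the pipeline depends on, without any real data:

- five provider specialties with strongly asymmetric patient volume
  (many busy GPs, few low-volume psychotherapists);
- community (practice-cluster) structure, which is what induces patient
  sharing between providers;
- persistent per-patient provider panels with quarterly visit behaviour,
  so networks evolve slowly over the follow-up;
- quarterly hospitalization outcomes drawn from the same random-intercept
  logistic law the estimator fits, with link effects applied to the very
  tertile dummies the estimator will construct (cutpoints computed on the
  generated training year), which makes the estimand exactly recoverable;
- a nested cohort: a fraction of patients carry only non-subcohort
  psychiatric diagnoses and contribute to patient sharing but not to
  outcome modelling.

Scenarios: ``null`` (no link effects, for type-I calibration), ``signal``
(protective GP-psychiatrist cross links, harmful weak same-specialty
links) and ``cd_confounded`` (a latent utilization trait drives both
network size and hospitalization risk with no true link effects, the
situation in which raw care density is misleading).

Every table draws from its own random stream split off the master seed, so
adding a table never perturbs earlier ones, and bundles are byte-identical
under a repeated (name, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import special

from .metrics import (LINK_CATEGORIES, decompose_sums, dummy_column,
                      enumerate_connection_types, fit_tertile_cutpoints,
                      metric_table)
from .network import build_yearly_graphs, patient_networks_for_quarters
from .quarters import Quarter, lookback_quarters

__all__ = ["ScenarioConfig", "ClaimsBundle", "generate_providers",
           "generate_visits", "generate_outcomes", "make_scenario",
           "SIGNAL_LINK_WEIGHTS"]

SPECIALTIES = ("GP", "PSY", "NEU", "NP", "PT")

#: Qualitative truth for the `signal` scenario: cross links between GPs and
#: (neuro)psychiatrists protect against hospitalization (the stronger the
#: link, the larger the protection), while weak same-specialty links —
#: several loosely connected providers of one type — increase risk.
SIGNAL_LINK_WEIGHTS: dict[str, float] = {
    "GP_PSY|weak": -0.05, "GP_PSY|moderate": -0.05, "GP_PSY|strong": -0.40,
    "GP_NP|weak": -0.05, "GP_NP|moderate": -0.05, "GP_NP|strong": -0.35,
    "GP_GP|weak": 0.50, "GP_GP|moderate": 0.25, "GP_GP|strong": 0.0,
    "GP_NEU|weak": 0.30, "GP_NEU|moderate": 0.10, "GP_NEU|strong": 0.15,
    "GP_PT|weak": 0.20, "GP_PT|moderate": 0.10,
    "NP_NP|weak": 0.45, "NP_NP|moderate": 0.10,
    "PSY_PSY|weak": 0.35, "PSY_PSY|moderate": 0.15,
    "PSY_NP|weak": 0.25, "PSY_NP|moderate": 0.10, "PSY_NP|strong": 0.10,
}

#: Control effects: age in SD units, two comorbidity flags and a
#: time-varying specialist-contact count, loosely in the range of typical
#: claims-based hospitalization models.
DEFAULT_CONTROL_EFFECTS: dict[str, float] = {
    "age_z": -0.30,
    "comorb_depression": -0.10,
    "comorb_substance": 0.45,
    "specialist_contacts": 0.10,
}


class ScenarioConfig(BaseModel):
    """All knobs of the generator; defaults define the study conditions."""

    seed: int
    name: str = "signal"
    n_patients: int = 2000
    n_providers: dict[str, int] = Field(
        default_factory=lambda: {"GP": 32, "PSY": 16, "NEU": 12, "NP": 16, "PT": 24})
    n_communities: int = 8
    index_year: int = 2015
    followup_start_offset: int = 4
    n_followup_quarters: int = 8
    min_w: int = 3
    lookback_length: int = 2
    #: "TYPE_A_TYPE_B|category" -> true log-odds effect of that link dummy
    true_link_weights: dict[str, float] = Field(default_factory=dict)
    control_effects: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CONTROL_EFFECTS))
    sigma2_true: float = 0.4
    target_rate: float = 0.07
    #: per-quarter probability that a panel provider is kept (vs replaced)
    retention: float = 0.92
    #: per-quarter probability of actually visiting each panel provider
    visit_prob: dict[str, float] = Field(
        default_factory=lambda: {"GP": 0.55, "PSY": 0.50, "NEU": 0.45,
                                 "NP": 0.50, "PT": 0.50})
    #: probability a patient's panel includes each specialist kind
    panel_probs: dict[str, float] = Field(
        default_factory=lambda: {"PSY": 0.38, "NEU": 0.22,
                                 "NP": 0.32, "PT": 0.15})
    #: distribution of the number of GPs beyond the primary one; multiple
    #: GPs are common (locums, practice partners, switching) and are what
    #: makes GP-GP connections carry the largest share of shared patients
    extra_gp_probs: tuple[float, ...] = (0.52, 0.28, 0.13, 0.07)
    #: chance of a second provider of an already-present specialist kind
    #: (dissatisfaction switching / parallel treatment)
    second_specialist_prob: float = 0.12
    #: chance a panel slot is filled inside the home community
    community_loyalty: float = 0.92
    #: chance a second GP is the primary GP's practice partner; group
    #: practices concentrate GP-GP sharing onto heavy within-practice edges,
    #: which is why GP-GP connections dominate total patient sharing
    practice_share: float = 0.85
    #: patients with only non-subcohort diagnoses (share patients only)
    psychiatric_only_frac: float = 0.10
    #: cd_confounded: effect of the latent utilization trait on the outcome
    confound_effect: float = 0.0
    #: latent-trait effect on panel size (cd_confounded only)
    confound_panel_shift: float = 0.0

    @field_validator("retention", "community_loyalty", "target_rate",
                     "psychiatric_only_frac")
    @classmethod
    def _prob(cls, v):
        if not 0 <= v <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("n_patients")
    @classmethod
    def _pos(cls, v):
        if v < 1:
            raise ValueError("n_patients must be >= 1")
        return v

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent random streams split from the master seed."""
        names = ["providers", "patients", "visits", "diagnoses", "outcomes"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class ClaimsBundle:
    """A complete synthetic claims extract plus its generating truth."""

    config: ScenarioConfig
    providers: pd.DataFrame
    patients: pd.DataFrame
    visits: pd.DataFrame
    diagnoses: pd.DataFrame
    timevarying: pd.DataFrame
    outcomes: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    @property
    def subcohort_ids(self) -> list[str]:
        return sorted(self.patients.loc[self.patients["subcohort"], "patient_id"])

    def followup_quarters(self) -> list[Quarter]:
        start = Quarter(self.config.index_year, 1) + self.config.followup_start_offset
        return [start + k for k in range(self.config.n_followup_quarters)]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("providers", "patients", "visits", "diagnoses",
                     "timevarying", "outcomes"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        truth = {k: v for k, v in self.ground_truth.items() if k != "u"}
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        (out / "scenario.json").write_text(self.config.model_dump_json(indent=2))


def generate_providers(config: ScenarioConfig,
                       rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Provider table: specialty, community, region flag, latent volume.

    Volume weights are lognormal with a specialty-level scale reproducing
    the field's volume asymmetry: GPs see many patients, psychotherapists
    few.  Providers are assigned to communities round-robin so every
    community has at least one GP.
    """
    rng = rng or config.streams()["providers"]
    scale = {"GP": 3.0, "PSY": 1.2, "NEU": 1.0, "NP": 1.2, "PT": 0.4}
    # heavy-tailed GP volume: a few very busy group practices generate
    # outlier edge weights, the inequality that makes raw shared-patient
    # counts a poor linear predictor
    sigma = {"GP": 1.2, "PSY": 0.5, "NEU": 0.5, "NP": 0.5, "PT": 0.5}
    rows = []
    for spec in SPECIALTIES:
        n = config.n_providers.get(spec, 0)
        if n < 1:
            raise ValueError(f"configuration error: no providers of specialty {spec}")
        comms = rng.permutation(
            [i % config.n_communities for i in range(n)])
        vols = scale[spec] * rng.lognormal(mean=0.0, sigma=sigma[spec], size=n)
        for i in range(n):
            rows.append({
                "provider_id": f"{spec}{i:03d}",
                "specialty": spec,
                "community": int(comms[i]),
                "in_region": True,
                "volume": float(vols[i]),
            })
    df = pd.DataFrame(rows)
    # pair up GPs within each community into two-physician group practices
    df["practice"] = -1
    gp = df["specialty"] == "GP"
    for comm, sub in df[gp].groupby("community"):
        ids = sub.index.to_numpy()
        for k, idx in enumerate(ids):
            df.loc[idx, "practice"] = comm * 1000 + k // 2
    return df


def _generate_patients(config: ScenarioConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    trait = rng.standard_normal(n)  # latent utilization propensity
    df = pd.DataFrame({
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "community": rng.integers(0, config.n_communities, n),
        "age_z": rng.standard_normal(n),
        "female": rng.random(n) < 0.5,
        "comorb_depression": rng.random(n) < 0.44,
        "comorb_substance": rng.random(n) < 0.15,
        "trait": trait,
        "subcohort": rng.random(n) >= config.psychiatric_only_frac,
    })
    return df


def _data_quarters(config: ScenarioConfig) -> list[Quarter]:
    first = Quarter(config.index_year - 1, 1)
    last = (Quarter(config.index_year, 1) + config.followup_start_offset
            + config.n_followup_quarters - 1)
    return list(first.range_to(last))


def generate_visits(providers: pd.DataFrame, patients: pd.DataFrame,
                    config: ScenarioConfig,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Quarterly visit records from persistent provider panels.

    Each patient holds a panel — a primary GP, possibly a second GP, and
    possibly one specialist of each kind — drawn preferentially from the
    home community with probability proportional to provider volume.  Per
    quarter every panel member is retained with probability ``retention``
    (otherwise replaced by a same-specialty provider) and actually visited
    with a specialty-specific probability, yielding realistic repeat visits
    and slowly drifting networks.
    """
    rng = rng or config.streams()["visits"]
    quarters = _data_quarters(config)

    by_spec_comm: dict[tuple[str, int], tuple[list[str], np.ndarray]] = {}
    by_spec: dict[str, tuple[list[str], np.ndarray]] = {}
    for spec, grp in providers.groupby("specialty"):
        ids, vol = list(grp["provider_id"]), grp["volume"].to_numpy()
        by_spec[spec] = (ids, vol / vol.sum())
        for comm, sub in grp.groupby("community"):
            ids_c, vol_c = list(sub["provider_id"]), sub["volume"].to_numpy()
            by_spec_comm[(spec, comm)] = (ids_c, vol_c / vol_c.sum())

    partner: dict[str, str] = {}
    if "practice" in providers.columns:
        for _, grp in providers[providers["practice"] >= 0].groupby("practice"):
            ids = list(grp["provider_id"])
            if len(ids) == 2:
                partner[ids[0]], partner[ids[1]] = ids[1], ids[0]

    def pick(spec: str, comm: int) -> str:
        pool = by_spec_comm.get((spec, comm))
        if pool is None or rng.random() > config.community_loyalty:
            pool = by_spec[spec]
        ids, p = pool
        return ids[rng.choice(len(ids), p=p)]

    rows = []
    pp = config.panel_probs
    for pat in patients.itertuples():
        shift = config.confound_panel_shift * pat.trait
        def has(kind: str) -> bool:
            return rng.random() < min(0.95, max(0.0, pp[kind] + shift))
        gp1 = pick("GP", pat.community)
        panel = [("GP", gp1)]
        p_extra = np.asarray(config.extra_gp_probs, dtype=float)
        n_extra = int(rng.choice(len(p_extra), p=p_extra / p_extra.sum()))
        if config.confound_panel_shift:
            n_extra += int(rng.random() < min(0.9, max(
                0.0, config.confound_panel_shift * pat.trait)))
        for j in range(n_extra):
            if j == 0 and gp1 in partner and rng.random() < config.practice_share:
                panel.append(("GP", partner[gp1]))
            else:
                panel.append(("GP", pick("GP", pat.community)))
        for spec in ("PSY", "NEU", "NP", "PT"):
            if has(spec):
                panel.append((spec, pick(spec, pat.community)))
                if rng.random() < config.second_specialist_prob:
                    panel.append((spec, pick(spec, pat.community)))
        for q in quarters:
            panel = [(s, p) if rng.random() < config.retention
                     else (s, pick(s, pat.community)) for s, p in panel]
            for spec, prov in panel:
                if rng.random() < config.visit_prob[spec]:
                    n_serv = 1 + rng.poisson(2.0 if spec == "GP" else 1.0)
                    rows.append((pat.patient_id, prov, spec, q.year, q.q, n_serv))
    return pd.DataFrame(rows, columns=["patient_id", "provider_id", "specialty",
                                       "year", "quarter", "n_services"])


def _generate_diagnoses(patients: pd.DataFrame, config: ScenarioConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Hospital-source subcohort diagnoses at the index quarter; psychiatric-
    only patients get confirmed two-quarter outpatient depression instead."""
    rows = []
    iq = Quarter(config.index_year, 1)
    for pat in patients.itertuples():
        if pat.subcohort:
            rows.append((pat.patient_id, "schizophrenia", iq.year, iq.q,
                         "hospital_or_clinic"))
            if pat.comorb_depression:
                src = "specialist" if rng.random() < 0.5 else "other_outpatient"
                rows.append((pat.patient_id, "depression", iq.year, iq.q, src))
                if src == "other_outpatient":  # confirm in the next quarter
                    nq = iq + 1
                    rows.append((pat.patient_id, "depression", nq.year, nq.q, src))
        else:
            rows.append((pat.patient_id, "depression", iq.year, iq.q,
                         "specialist"))
        # noise: unconfirmed single outpatient diagnoses that must be dropped
        if rng.random() < 0.15:
            q = iq + int(rng.integers(0, 4))
            rows.append((pat.patient_id, "anxiety", q.year, q.q,
                         "other_outpatient"))
    return pd.DataFrame(rows, columns=["patient_id", "code_group", "year",
                                       "quarter", "source"])


def _specialist_contacts(visits: pd.DataFrame, subcohort: list[str],
                         quarters: list[Quarter], lookback: int) -> pd.DataFrame:
    """Time-varying control: number of specialist visits (any non-GP) in the
    lookback window before each follow-up quarter."""
    spec_visits = visits[visits["specialty"] != "GP"]
    qidx = spec_visits["year"] * 4 + (spec_visits["quarter"] - 1)
    counts = (spec_visits.assign(_q=qidx).groupby(["patient_id", "_q"])
              .size().to_dict())
    rows = []
    for pid in subcohort:
        for q in quarters:
            window = [w.index for w in lookback_quarters(q, lookback)]
            c = sum(counts.get((pid, w), 0) for w in window)
            rows.append((pid, q.year, q.q, c))
    return pd.DataFrame(rows, columns=["patient_id", "year", "quarter",
                                       "specialist_contacts"])


def generate_outcomes(visits: pd.DataFrame, patients: pd.DataFrame,
                      timevarying: pd.DataFrame, config: ScenarioConfig,
                      rng: Optional[np.random.Generator] = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Draw quarterly hospitalizations from the ground-truth logistic law.

    The linear predictor applies the configured link effects to the same
    tertile dummies the estimator will build: networks come from the
    thresholded sharing graphs of the generated visits, and cutpoints are
    fitted on the training-year (first four follow-up quarters) subcohort
    observations, then frozen for the validation year.  The intercept is
    centered so the population-average event rate matches ``target_rate``.
    """
    rng = rng or config.streams()["outcomes"]
    registry = enumerate_connection_types(SPECIALTIES)
    subcohort = sorted(patients.loc[patients["subcohort"], "patient_id"])
    fu = [Quarter(config.index_year, 1) + config.followup_start_offset + k
          for k in range(config.n_followup_quarters)]

    years = sorted({lookback_quarters(q, config.lookback_length)[-1].year
                    for q in fu})
    graphs = build_yearly_graphs(visits, patients["patient_id"], years,
                                 min_w=config.min_w)
    pq = [(pid, q) for pid in subcohort for q in fu]
    networks = patient_networks_for_quarters(visits, pq, graphs,
                                             config.lookback_length)
    all_sums = [decompose_sums(net, registry) for net in networks]
    n_train = config.n_followup_quarters // 2
    train_sums = [s for s, (pid, q) in zip(all_sums, pq) if q in fu[:n_train]]
    cutpoints = fit_tertile_cutpoints(train_sums, registry)

    mt = metric_table(networks, registry, cutpoints)
    dummy_cols = [dummy_column(registry, t, c)
                  for t in registry.connection_types for c in LINK_CATEGORIES]
    w = np.array([config.true_link_weights.get(
        f"{registry.type_label(t)}|{c}", 0.0)
        for t in registry.connection_types for c in LINK_CATEGORIES])
    link_part = mt[dummy_cols].to_numpy(dtype=float) @ w

    pat = patients.set_index("patient_id")
    tv = timevarying.set_index(["patient_id", "year", "quarter"])
    x_controls = np.zeros(len(mt))
    eff = config.control_effects
    ctrl_cols = {}
    for name in ("age_z", "comorb_depression", "comorb_substance"):
        vals = pat.loc[mt["patient_id"], name].to_numpy(dtype=float)
        ctrl_cols[name] = vals
        x_controls = x_controls + eff.get(name, 0.0) * vals
    sc = tv.loc[list(zip(mt["patient_id"], mt["year"], mt["quarter"])),
                "specialist_contacts"].to_numpy(dtype=float)
    ctrl_cols["specialist_contacts"] = sc
    x_controls = x_controls + eff.get("specialist_contacts", 0.0) * sc
    confound = config.confound_effect * pat.loc[mt["patient_id"],
                                                "trait"].to_numpy(dtype=float)

    contrib = link_part + x_controls + confound
    beta0 = float(special.logit(config.target_rate) - contrib.mean())
    u_by_pid = {pid: rng.normal(0.0, np.sqrt(config.sigma2_true))
                for pid in subcohort}
    u = np.array([u_by_pid[pid] for pid in mt["patient_id"]])
    eta = beta0 + contrib + u
    y = rng.binomial(1, special.expit(eta))

    outcomes = mt[["patient_id", "year", "quarter"]].copy()
    outcomes["hospitalized"] = y.astype(int)
    truth = {
        "beta0": beta0,
        "link_weights": {f"{registry.type_label(t)}|{c}":
                         config.true_link_weights.get(
                             f"{registry.type_label(t)}|{c}", 0.0)
                         for t in registry.connection_types
                         for c in LINK_CATEGORIES},
        "control_effects": dict(eff),
        "sigma2": config.sigma2_true,
        "confound_effect": config.confound_effect,
        "cutpoints": {registry.type_label(t): list(v)
                      for t, v in cutpoints.cutpoints.items()},
        "realized_rate": float(y.mean()),
        "u": u_by_pid,
    }
    return outcomes, truth


def make_scenario(name: str, seed: int, **overrides) -> ClaimsBundle:
    """Generate a full claims bundle for a named scenario.

    ``null``: no link effects (type-I error checks).  ``signal``: the
    default ground-truth link-weight pattern.  ``cd_confounded``: no link
    effects, but a latent utilization trait inflates both panel size (hence
    care density) and hospitalization risk.
    """
    if name == "null":
        cfg = ScenarioConfig(seed=seed, name=name, true_link_weights={},
                             **overrides)
    elif name == "signal":
        cfg = ScenarioConfig(seed=seed, name=name,
                             true_link_weights=dict(SIGNAL_LINK_WEIGHTS),
                             **overrides)
    elif name == "cd_confounded":
        cfg = ScenarioConfig(seed=seed, name=name, true_link_weights={},
                             confound_effect=0.5, confound_panel_shift=0.12,
                             **overrides)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return generate_bundle(cfg)


def generate_bundle(config: ScenarioConfig) -> ClaimsBundle:
    streams = config.streams()
    providers = generate_providers(config, streams["providers"])
    patients = _generate_patients(config, streams["patients"])
    visits = generate_visits(providers, patients, config, streams["visits"])
    diagnoses = _generate_diagnoses(patients, config, streams["diagnoses"])
    subcohort = sorted(patients.loc[patients["subcohort"], "patient_id"])
    fu = [Quarter(config.index_year, 1) + config.followup_start_offset + k
          for k in range(config.n_followup_quarters)]
    timevarying = _specialist_contacts(visits, subcohort, fu,
                                       config.lookback_length)
    outcomes, truth = generate_outcomes(visits, patients, timevarying, config,
                                        streams["outcomes"])
    return ClaimsBundle(config=config, providers=providers, patients=patients,
                        visits=visits, diagnoses=diagnoses,
                        timevarying=timevarying, outcomes=outcomes,
                        ground_truth=truth)
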