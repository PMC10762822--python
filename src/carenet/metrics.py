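"""Care density, its connection-type decomposition, and link coding.

Care density of patient ``p`` averages the shared-patient counts over all
``m = n_p(n_p-1)/2`` pairs of the patient's ``n_p`` providers::

    C_p = sum_i w_i / (n_p (n_p - 1) / 2)

Fragmented care density decomposes the numerator by *connection type* — the
unordered pair of provider specialties, same-specialty pairs included, so
``k = l(l+1)/2`` types for ``l`` specialties.  Each type's normalized sum
``s_j / m`` is categorized against training-period tertiles into
missing / weak / moderate / strong link indicators, which a regression
model then weights to predict an outcome.  The weighted linear predictor is
the FCD score.

Care density is undefined for patients with fewer than two providers; that
state is the explicit :data:`UNDEFINED` sentinel, never 0 or NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .network import PatientNetwork, ProviderSharingGraph
from .quarters import Quarter

__all__ = [
    "UNDEFINED",
    "ConnectionTypeRegistry",
    "ConnectionTypeSums",
    "TertileCutpoints",
    "LINK_CATEGORIES",
    "enumerate_connection_types",
    "care_density",
    "decompose_sums",
    "reconstruct_cd",
    "fit_tertile_cutpoints",
    "categorize_links",
    "fcd_linear_predictor",
    "contribution_shares",
    "lorenz_points",
    "metric_table",
    "dummy_column",
]

#: Link strength categories; "missing" is the reference and carries no dummy.
LINK_CATEGORIES: tuple[str, ...] = ("weak", "moderate", "strong")


class _Undefined:
    """Sentinel for care density of a network with fewer than two providers."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class ConnectionTypeRegistry:
    """Ordered provider types and the derived connection types.

    Connection types are unordered specialty pairs with repetition, ordered
    deterministically: same-type pairs first (registry order), then cross
    pairs in registry-lexicographic order.
    """

    provider_types: tuple[str, ...]
    connection_types: tuple[tuple[str, str], ...]

    @property
    def l(self) -> int:
        return len(self.provider_types)

    @property
    def k(self) -> int:
        return len(self.connection_types)

    def type_of_pair(self, spec_a: str, spec_b: str) -> tuple[str, str]:
        """Canonical connection type of a specialty pair."""
        order = {s: i for i, s in enumerate(self.provider_types)}
        for s in (spec_a, spec_b):
            if s not in order:
                raise KeyError(f"specialty {s!r} not in registry")
        return (spec_a, spec_b) if order[spec_a] <= order[spec_b] else (spec_b, spec_a)

    def type_label(self, ctype: tuple[str, str]) -> str:
        return f"{ctype[0]}_{ctype[1]}"


def enumerate_connection_types(provider_types: Sequence[str]) -> ConnectionTypeRegistry:
    """All unordered specialty pairs with repetition; ``k = l(l+1)/2``."""
    types = tuple(provider_types)
    if len(types) < 1:
        raise ValueError("need at least one provider type")
    if len(set(types)) != len(types):
        raise ValueError("configuration error: duplicate provider type labels")
    same = [(t, t) for t in types]
    cross = [(types[i], types[j]) for i in range(len(types))
             for j in range(i + 1, len(types))]
    return ConnectionTypeRegistry(provider_types=types,
                                  connection_types=tuple(same + cross))


def care_density(network: PatientNetwork) -> Union[float, _Undefined]:
    """Average shared-patient count over all provider pairs (C_p).

    Returns :data:`UNDEFINED` when the patient saw fewer than two providers
    (the pair denominator vanishes).
    """
    if network.n_p < 2:
        return UNDEFINED
    return sum(network.edges.values()) / network.m


@dataclass
class ConnectionTypeSums:
    """Per-type shared-patient sums ``s_j`` for one patient-quarter."""

    patient_id: str
    quarter: Quarter
    n_p: int
    s: dict[tuple[str, str], float]

    @property
    def m(self) -> int:
        return self.n_p * (self.n_p - 1) // 2

    @property
    def s_norm(self) -> dict[tuple[str, str], float]:
        """Sums normalized by the pair count; defined only for n_p >= 2."""
        if self.n_p < 2:
            raise ValueError("s_norm undefined for networks with fewer than 2 providers")
        return {t: v / self.m for t, v in self.s.items()}

    def total(self) -> float:
        return float(sum(self.s.values()))


def decompose_sums(network: PatientNetwork,
                   registry: ConnectionTypeRegistry) -> ConnectionTypeSums:
    """Split the network's total weight into connection-type sums.

    ``s_j`` adds the weights of exactly the pairs whose specialty pair is
    type ``j``; the sums conserve the total: ``sum_j s_j = sum_i w_i``.
    """
    s = {t: 0.0 for t in registry.connection_types}
    for (a, b), w in network.edges.items():
        sa, sb = network.providers[a], network.providers[b]
        try:
            ctype = registry.type_of_pair(sa, sb)
        except KeyError as exc:
            raise KeyError(f"provider {a if sa not in registry.provider_types else b} "
                           f"has specialty outside registry") from exc
        s[ctype] += float(w)
    return ConnectionTypeSums(patient_id=network.patient_id,
                              quarter=network.quarter, n_p=network.n_p, s=s)


def reconstruct_cd(sums: ConnectionTypeSums) -> Union[float, _Undefined]:
    """Care density recomputed from the type sums (decomposition identity)."""
    if sums.n_p < 2:
        return UNDEFINED
    return sums.total() / sums.m


def _nearest_rank(sorted_vals: Sequence[float], p: float) -> float:
    """Nearest-rank quantile, lower tie: value at rank ceil(p*n)."""
    n = len(sorted_vals)
    rank = max(1, math.ceil(p * n))
    return float(sorted_vals[rank - 1])


@dataclass
class TertileCutpoints:
    """Per connection type: tertile cutpoints on the normalized-sum scale.

    Estimated among training observations with a *positive* normalized sum;
    zeros are the missing-link reference and are not part of the tertile
    pool.  A type never observed positive gets ``(inf, inf)`` so any future
    positive value codes as a weak link.
    """

    cutpoints: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __getitem__(self, ctype: tuple[str, str]) -> tuple[float, float]:
        return self.cutpoints[ctype]


def fit_tertile_cutpoints(training_sums: Iterable[ConnectionTypeSums],
                          registry: ConnectionTypeRegistry) -> TertileCutpoints:
    """Empirical 1/3 and 2/3 nearest-rank quantiles of positive s_j/m."""
    pos: dict[tuple[str, str], list[float]] = {t: [] for t in registry.connection_types}
    n_seen = 0
    for sums in training_sums:
        n_seen += 1
        if sums.n_p < 2:
            continue
        for t, v in sums.s_norm.items():
            if v > 0:
                pos[t].append(v)
    if n_seen == 0:
        raise ValueError("training collection is empty")
    cut = {}
    for t, vals in pos.items():
        if not vals:
            cut[t] = (math.inf, math.inf)
        else:
            vals.sort()
            cut[t] = (_nearest_rank(vals, 1 / 3), _nearest_rank(vals, 2 / 3))
    return TertileCutpoints(cutpoints=cut)


def categorize_links(sums: ConnectionTypeSums,
                     cutpoints: TertileCutpoints) -> dict[tuple[str, str], str]:
    """Categorize each connection type as missing/weak/moderate/strong.

    Zero (or an empty network) is the missing reference; boundary ties go to
    the lower category (value <= cutpoint).
    """
    out = {}
    norm = sums.s_norm if sums.n_p >= 2 else {t: 0.0 for t in sums.s}
    for t, v in norm.items():
        t1, t2 = cutpoints[t]
        if v <= 0:
            out[t] = "missing"
        elif v <= t1:
            out[t] = "weak"
        elif v <= t2:
            out[t] = "moderate"
        else:
            out[t] = "strong"
    return out


def dummy_column(registry: ConnectionTypeRegistry, ctype: tuple[str, str],
                 category: str) -> str:
    """Deterministic design-column name, e.g. ``link_GP_PSY_strong``."""
    return f"link_{registry.type_label(ctype)}_{category}"


def link_dummy_columns(registry: ConnectionTypeRegistry) -> list[str]:
    """All 3k dummy column names in registry order."""
    return [dummy_column(registry, t, c)
            for t in registry.connection_types for c in LINK_CATEGORIES]


def fcd_linear_predictor(categories: Mapping[tuple[str, str], str],
                         model: "FCDModel") -> float:  # noqa: F821
    """FCD score: the model's linear predictor from network information only.

    ``beta0 + sum_j beta_{j,cat(j)} + offset`` where the offset fixes every
    control variable at its training mean, so score differences between
    patients reflect network differences alone.  A patient with no links
    scores ``beta0 + offset`` — the base risk.
    """
    unmatched = [t for t in categories if t not in model.registry.connection_types]
    missing = [t for t in model.registry.connection_types if t not in categories]
    if unmatched or missing:
        raise ValueError(
            f"connection-type layout mismatch; unmatched={unmatched}, absent={missing}")
    score = model.beta0 + model.control_offset()
    for t, cat in categories.items():
        if cat != "missing":
            score += model.link_weights[(t, cat)]
    return float(score)


def contribution_shares(graph: ProviderSharingGraph,
                        registry: ConnectionTypeRegistry
                        ) -> dict[tuple[str, str], float]:
    """Fraction of total shared patients carried by each connection type."""
    if not graph.edges:
        return {}
    totals = {t: 0.0 for t in registry.connection_types}
    for (a, b), w in graph.edges.items():
        ctype = registry.type_of_pair(graph.provider_index[a], graph.provider_index[b])
        totals[ctype] += w
    grand = sum(totals.values())
    return {t: v / grand for t, v in totals.items()}


def lorenz_points(weights: Sequence[float]) -> list[tuple[float, float]]:
    """Standard Lorenz construction over non-negative weights.

    Returns (cumulative population fraction, cumulative weight fraction)
    points starting at (0, 0) and ending at (1, 1); weights are sorted
    ascending first.  Used to display how unequally shared patients are
    distributed across the connections of one type.
    """
    w = np.asarray(sorted(weights), dtype=float)
    if w.size == 0:
        raise ValueError("need at least one weight")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("Lorenz curve undefined for all-zero weights")
    cum = np.cumsum(w) / total
    pop = np.arange(1, w.size + 1) / w.size
    return [(0.0, 0.0)] + list(zip(pop.tolist(), cum.tolist()))


def metric_table(networks: Iterable[PatientNetwork],
                 registry: ConnectionTypeRegistry,
                 cutpoints: Optional[TertileCutpoints] = None,
                 model: Optional["FCDModel"] = None,  # noqa: F821
                 ) -> pd.DataFrame:
    """Per patient-quarter metric table.

    Always contains ``patient_id, year, quarter, n_p, m, cd, cd_defined``
    (cd is 0.0 with cd_defined=False when undefined).  With ``cutpoints``
    the 3k link dummy columns are added; with a ``model`` additionally the
    ``fcd_score`` column.
    """
    dummy_cols = link_dummy_columns(registry)
    rows = []
    for net in networks:
        sums = decompose_sums(net, registry)
        cd = care_density(net)
        row: dict[str, object] = {
            "patient_id": net.patient_id,
            "year": net.quarter.year,
            "quarter": net.quarter.q,
            "n_p": net.n_p,
            "m": net.m,
            "cd": 0.0 if cd is UNDEFINED else float(cd),
            "cd_defined": cd is not UNDEFINED,
        }
        if cutpoints is not None:
            cats = categorize_links(sums, cutpoints)
            for col in dummy_cols:
                row[col] = 0
            for t, cat in cats.items():
                if cat != "missing":
                    row[dummy_column(registry, t, cat)] = 1
            if model is not None:
                row["fcd_score"] = fcd_linear_predictor(cats, model)
        rows.append(row)
    return pd.DataFrame(rows)
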