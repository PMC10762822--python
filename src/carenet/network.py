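"""Patient-sharing provider graphs and patient-centered networks.

A yearly :class:`ProviderSharingGraph` is the one-mode projection of the
bipartite patient-provider visit relation restricted to a reference cohort:
the weight ``w`` of an undirected provider pair is the number of cohort
patients with at least one visit to both providers within the calendar
year.  Patient-level counting (not visit-level) makes ``w`` robust to
repeat billing.

A :class:`PatientNetwork` is the subgraph induced by the providers one
patient visited during a lookback window.  Visited provider pairs absent
from the thresholded graph still count in the pair denominator ``m`` with
weight 0 — care density averages over all pairs of visited providers, not
only the connected ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .quarters import Quarter, lookback_quarters

logger = logging.getLogger(__name__)

__all__ = [
    "ProviderSharingGraph",
    "PatientNetwork",
    "filter_providers",
    "build_sharing_graph",
    "apply_threshold",
    "extract_patient_network",
    "build_yearly_graphs",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class ProviderSharingGraph:
    """Undirected weighted patient-sharing graph for one calendar year."""

    year: int
    #: lexicographically ordered provider pair -> shared-patient count
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    #: provider_id -> specialty, for every provider that appears in visits
    provider_index: dict[str, str] = field(default_factory=dict)

    def weight(self, a: str, b: str) -> int:
        """Shared-patient count for an unordered pair (0 if no edge)."""
        if a == b:
            raise ValueError("self-pairs have no sharing weight")
        return self.edges.get(_pair(a, b), 0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for pid, spec in self.provider_index.items():
            g.add_node(pid, specialty=spec)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=int(w))
        return g

    def to_edgelist(self) -> pd.DataFrame:
        rows = sorted(self.edges.items())
        return pd.DataFrame(
            [(a, b, w) for (a, b), w in rows],
            columns=["provider_a", "provider_b", "w"],
        )

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_edgelist(cls, year: int, df: pd.DataFrame,
                      provider_index: Optional[Mapping[str, str]] = None
                      ) -> "ProviderSharingGraph":
        edges = {_pair(str(r.provider_a), str(r.provider_b)): int(r.w)
                 for r in df.itertuples()}
        return cls(year=year, edges=edges,
                   provider_index=dict(provider_index or {}))


@dataclass
class PatientNetwork:
    """One patient-quarter's visited providers and induced weighted pairs."""

    patient_id: str
    quarter: Quarter
    #: provider_id -> specialty for every provider visited in the lookback
    providers: dict[str, str]
    #: ordered pair -> effective sharing weight (0-weight pairs included)
    edges: dict[tuple[str, str], int]

    @property
    def n_p(self) -> int:
        return len(self.providers)

    @property
    def m(self) -> int:
        n = self.n_p
        return n * (n - 1) // 2

    def weights(self) -> list[int]:
        """Edge weights for all m unordered pairs, in pair order."""
        return [w for _, w in sorted(self.edges.items())]


def filter_providers(visits: pd.DataFrame, region_flags: Mapping[str, bool],
                     percentile: float = 0.95) -> set[str]:
    """Retain in-region providers plus sufficiently busy out-of-region ones.

    Patients near a regional border routinely see providers just outside it;
    out-of-region providers with trivially low service volume, however, are
    unlikely to be regular providers for the sample.  An out-of-region
    provider is retained iff its total service count reaches the
    ``(1 - percentile)`` nearest-rank quantile of the in-region totals of
    the same specialty (boundary inclusive) — i.e. it outperforms the bottom
    ``1 - percentile`` share of in-region peers.

    ``region_flags`` maps provider_id -> True when in-region.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie strictly between 0 and 1")
    totals = visits.groupby(["provider_id", "specialty"])["n_services"].sum()
    retained: set[str] = set()
    by_spec: dict[str, list[tuple[str, int]]] = {}
    for (pid, spec), tot in totals.items():
        by_spec.setdefault(spec, []).append((pid, int(tot)))

    for spec, members in by_spec.items():
        in_tot = sorted(t for pid, t in members if region_flags.get(pid, True))
        out_members = [(pid, t) for pid, t in members if not region_flags.get(pid, True)]
        retained.update(pid for pid, _ in members if region_flags.get(pid, True))
        if not out_members:
            continue
        if not in_tot:
            logger.warning(
                "specialty %s has no in-region providers; dropping %d "
                "out-of-region provider(s)", spec, len(out_members))
            continue
        # nearest-rank, lower-tie quantile of in-region totals
        rank = max(1, math.ceil((1.0 - percentile) * len(in_tot)))
        cutoff = in_tot[rank - 1]
        retained.update(pid for pid, t in out_members if t >= cutoff)
    return retained


def build_sharing_graph(visits: pd.DataFrame, cohort_patients: Iterable[str],
                        year: int) -> ProviderSharingGraph:
    """Project cohort visits of one calendar year onto provider pairs.

    ``w`` counts distinct cohort patients seen by both providers of a pair
    during ``year``; pairs with no shared patient are omitted.
    """
    cohort = set(cohort_patients)
    sub = visits[(visits["year"] == year) & visits["patient_id"].isin(cohort)]
    provider_index = dict(zip(visits["provider_id"], visits["specialty"]))

    pairs = (sub[["patient_id", "provider_id"]].drop_duplicates()
             .sort_values(["patient_id", "provider_id"]))
    edges: dict[tuple[str, str], int] = {}
    for _, grp in pairs.groupby("patient_id", sort=False):
        provs = grp["provider_id"].to_numpy()
        for i in range(len(provs)):
            for j in range(i + 1, len(provs)):
                key = _pair(provs[i], provs[j])
                edges[key] = edges.get(key, 0) + 1
    return ProviderSharingGraph(year=year, edges=edges, provider_index=provider_index)


def apply_threshold(graph: ProviderSharingGraph, min_w: int = 3) -> ProviderSharingGraph:
    """Drop edges below the shared-patient threshold (inclusive bound).

    A small absolute threshold (default ``w >= 3``) removes incidental
    sharing while keeping connections to low-volume provider types such as
    psychotherapists.  Nodes are retained even if isolated.
    """
    if min_w < 1:
        raise ValueError("min_w must be >= 1")
    kept = {pair: w for pair, w in graph.edges.items() if w >= min_w}
    return ProviderSharingGraph(year=graph.year, edges=kept,
                                provider_index=dict(graph.provider_index))


def extract_patient_network(patient_id: str, quarter: Quarter,
                            visits: pd.DataFrame,
                            graphs: Mapping[int, ProviderSharingGraph],
                            lookback_length: int = 2,
                            retained_providers: Optional[set[str]] = None,
                            ) -> PatientNetwork:
    """Build the patient-centered network for one outcome quarter.

    Providers are those visited during the lookback window (default the two
    preceding quarters).  Pair weights are looked up in the thresholded
    sharing graph of the calendar year of the *later* lookback quarter —
    the most recent sharing information available when the window straddles
    two years.  Visited pairs without a graph edge get weight 0.
    """
    window = lookback_quarters(quarter, lookback_length)
    ref_year = window[-1].year
    if ref_year not in graphs:
        raise KeyError(f"no sharing graph available for required year {ref_year}")
    graph = graphs[ref_year]

    widx = visits["year"] * 4 + (visits["quarter"] - 1)
    in_window = visits[(visits["patient_id"] == patient_id)
                       & widx.isin([q.index for q in window])]
    providers = {str(r.provider_id): str(r.specialty) for r in in_window.itertuples()}
    if retained_providers is not None:
        providers = {p: s for p, s in providers.items() if p in retained_providers}

    ids = sorted(providers)
    edges = {(a, b): graph.weight(a, b)
             for i, a in enumerate(ids) for b in ids[i + 1:]}
    return PatientNetwork(patient_id=patient_id, quarter=quarter,
                          providers=providers, edges=edges)


def build_yearly_graphs(visits: pd.DataFrame, cohort_patients: Iterable[str],
                        years: Sequence[int], min_w: int = 3,
                        ) -> dict[int, ProviderSharingGraph]:
    """Thresholded sharing graphs for a range of calendar years."""
    cohort = list(cohort_patients)
    return {y: apply_threshold(build_sharing_graph(visits, cohort, y), min_w)
            for y in years}


def patient_networks_for_quarters(visits: pd.DataFrame,
                                  patient_quarters: Iterable[tuple[str, Quarter]],
                                  graphs: Mapping[int, ProviderSharingGraph],
                                  lookback_length: int = 2,
                                  retained_providers: Optional[set[str]] = None,
                                  ) -> list[PatientNetwork]:
    """Vectorized-ish batch extraction of patient networks.

    Groups the visit table once by (patient, window quarter) membership
    instead of filtering per patient, which matters for simulation studies.
    """
    if retained_providers is not None:
        visits = visits[visits["provider_id"].isin(retained_providers)]
    qidx = (visits["year"] * 4 + (visits["quarter"] - 1)).to_numpy()
    pids = visits["patient_id"].to_numpy()
    provs = visits["provider_id"].to_numpy()
    specs = visits["specialty"].to_numpy()
    seen: dict[tuple[str, int], dict[str, str]] = {}
    for i in range(len(pids)):
        seen.setdefault((pids[i], qidx[i]), {})[provs[i]] = specs[i]

    out = []
    for pid, quarter in patient_quarters:
        window = lookback_quarters(quarter, lookback_length)
        ref_year = window[-1].year
        if ref_year not in graphs:
            raise KeyError(f"no sharing graph available for required year {ref_year}")
        edge_map = graphs[ref_year].edges
        providers: dict[str, str] = {}
        for q in window:
            providers.update(seen.get((pid, q.index), ()))
        ids = sorted(providers)
        edges = {(a, b): edge_map.get((a, b), 0)
                 for i, a in enumerate(ids) for b in ids[i + 1:]}
        out.append(PatientNetwork(patient_id=pid, quarter=quarter,
                                  providers=providers, edges=edges))
    return out
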