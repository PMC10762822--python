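import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carenet.metrics import (UNDEFINED, ConnectionTypeSums, TertileCutpoints,
                             care_density, categorize_links,
                             contribution_shares, decompose_sums,
                             enumerate_connection_types, fit_tertile_cutpoints,
                             lorenz_points, reconstruct_cd)
from carenet.network import PatientNetwork, ProviderSharingGraph
from carenet.quarters import Quarter

SPECS = ("GP", "PSY", "NEU", "NP", "PT")
REG = enumerate_connection_types(SPECS)
Q = Quarter(2016, 1)


def _net(providers, edges):
    return PatientNetwork("p", Q, providers, edges)


class TestEnumerateConnectionTypes:
    @pytest.mark.parametrize("l,k", [(5, 15), (1, 1), (3, 6)])
    def test_k_formula(self, l, k):
        reg = enumerate_connection_types([f"T{i}" for i in range(l)])
        assert reg.k == k == reg.l * (reg.l + 1) // 2

    def test_same_type_pairs_first_then_cross(self):
        reg = enumerate_connection_types(("A", "B", "C"))
        assert reg.connection_types[:3] == (("A", "A"), ("B", "B"), ("C", "C"))
        assert reg.connection_types[3:] == (("A", "B"), ("A", "C"), ("B", "C"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            enumerate_connection_types(("GP", "GP"))

    def test_pair_canonicalization(self):
        assert REG.type_of_pair("PSY", "GP") == ("GP", "PSY")
        assert REG.type_of_pair("GP", "PSY") == ("GP", "PSY")


class TestCareDensity:
    def test_worked_three_provider_network(self):
        net = _net({"a": "GP", "b": "PSY", "c": "NEU"},
                   {("a", "b"): 9, ("a", "c"): 4, ("b", "c"): 3})
        assert care_density(net) == pytest.approx(16 / 3)

    def test_two_providers_single_edge(self):
        net = _net({"a": "GP", "b": "PSY"}, {("a", "b"): 3})
        assert care_density(net) == 3.0

    def test_single_provider_undefined(self):
        assert care_density(_net({"a": "GP"}, {})) is UNDEFINED

    def test_empty_network_undefined(self):
        assert care_density(_net({}, {})) is UNDEFINED


class TestDecomposition:
    def test_sums_select_by_type(self):
        net = _net({"g1": "GP", "g2": "GP", "p1": "PSY"},
                   {("g1", "g2"): 4, ("g1", "p1"): 9, ("g2", "p1"): 0})
        sums = decompose_sums(net, REG)
        assert sums.s[("GP", "GP")] == 4
        assert sums.s[("GP", "PSY")] == 9
        assert sum(v for t, v in sums.s.items()
                   if t not in (("GP", "GP"), ("GP", "PSY"))) == 0

    def test_empty_network_all_zero(self):
        sums = decompose_sums(_net({}, {}), REG)
        assert all(v == 0 for v in sums.s.values())

    def test_reconstruction_of_worked_example(self):
        net = _net({"a": "GP", "b": "PSY", "c": "NEU"},
                   {("a", "b"): 9, ("a", "c"): 4, ("b", "c"): 3})
        assert reconstruct_cd(decompose_sums(net, REG)) == pytest.approx(16 / 3)

    def test_reconstruct_undefined_below_two_providers(self):
        assert reconstruct_cd(decompose_sums(_net({"a": "GP"}, {}), REG)) is UNDEFINED

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_identity_on_random_networks(self, data):
        """Summing per-type sums reproduces care density exactly."""
        n = data.draw(st.integers(2, 8))
        providers = {f"x{i}": data.draw(st.sampled_from(SPECS))
                     for i in range(n)}
        ids = sorted(providers)
        edges = {(a, b): data.draw(st.integers(0, 100))
                 for i, a in enumerate(ids) for b in ids[i + 1:]}
        net = _net(providers, edges)
        sums = decompose_sums(net, REG)
        assert sums.total() == sum(edges.values())
        assert abs(reconstruct_cd(sums) - care_density(net)) <= 1e-12


class TestTertiles:
    def _sums(self, value_by_type):
        s = {t: 0.0 for t in REG.connection_types}
        s.update(value_by_type)
        n_p = 3
        return ConnectionTypeSums("p", Q, n_p, {t: v * 3 for t, v in s.items()})

    def test_nearest_rank_cutpoints(self):
        t = ("GP", "PSY")
        training = [self._sums({t: v}) for v in (1, 2, 3, 4, 5, 6)]
        cuts = fit_tertile_cutpoints(training, REG)
        assert cuts[t] == (2, 4)

    def test_all_identical_values_code_weak(self):
        t = ("GP", "PSY")
        cuts = fit_tertile_cutpoints([self._sums({t: 2.0})] * 5, REG)
        assert cuts[t] == (2.0, 2.0)
        cats = categorize_links(self._sums({t: 2.0}), cuts)
        assert cats[t] == "weak"

    def test_type_never_positive_gets_infinite_cutpoints(self):
        cuts = fit_tertile_cutpoints([self._sums({})], REG)
        assert cuts[("NP", "PT")] == (math.inf, math.inf)
        cats = categorize_links(self._sums({("NP", "PT"): 7.0}), cuts)
        assert cats[("NP", "PT")] == "weak"

    def test_category_boundaries(self):
        t = ("GP", "PSY")
        cuts = TertileCutpoints({ct: (2.0, 4.0) for ct in REG.connection_types})
        assert categorize_links(self._sums({}), cuts)[t] == "missing"
        assert categorize_links(self._sums({t: 2.0}), cuts)[t] == "weak"
        assert categorize_links(self._sums({t: 3.0}), cuts)[t] == "moderate"
        assert categorize_links(self._sums({t: 4.0}), cuts)[t] == "moderate"
        assert categorize_links(self._sums({t: 4.01}), cuts)[t] == "strong"

    def test_training_assignment_near_thirds(self, small_analysis):
        """Positive training observations split ~evenly across tertiles."""
        mt = small_analysis.training_table
        for lab in ("GP_PSY", "GP_GP"):
            cols = [f"link_{lab}_{c}" for c in ("weak", "moderate", "strong")]
            counts = mt[cols].sum()
            if counts.sum() < 30:
                continue
            frac = counts / counts.sum()
            # ties at cutpoints can shift mass toward the lower category
            assert frac.max() - frac.min() < 0.34


class TestReports:
    def _graph(self):
        return ProviderSharingGraph(
            2015, {("g1", "g2"): 6, ("g1", "p1"): 2},
            {"g1": "GP", "g2": "GP", "p1": "PSY"})

    def test_single_edge_share_is_one(self):
        g = ProviderSharingGraph(2015, {("a", "b"): 5}, {"a": "GP", "b": "GP"})
        shares = contribution_shares(g, REG)
        assert shares[("GP", "GP")] == 1.0

    def test_equal_weights_split_evenly(self):
        g = ProviderSharingGraph(2015, {("a", "b"): 5, ("a", "c"): 5},
                                 {"a": "GP", "b": "GP", "c": "PSY"})
        shares = contribution_shares(g, REG)
        assert shares[("GP", "GP")] == shares[("GP", "PSY")] == 0.5

    def test_shares_sum_to_one(self, small_analysis):
        g = small_analysis.graphs[max(small_analysis.graphs)]
        shares = contribution_shares(g, small_analysis.registry)
        assert abs(sum(shares.values()) - 1.0) <= 1e-12

    def test_gp_gp_share_is_maximum_in_generated_graph(self, small_analysis):
        g = small_analysis.graphs[max(small_analysis.graphs)]
        shares = contribution_shares(g, small_analysis.registry)
        assert max(shares, key=shares.get) == ("GP", "GP")

    def test_empty_graph_empty_mapping(self):
        g = ProviderSharingGraph(2015, {}, {})
        assert contribution_shares(g, REG) == {}


class TestLorenz:
    def test_equal_weights_on_diagonal(self):
        pts = lorenz_points([2, 2, 2, 2])
        for pop, cum in pts:
            assert cum == pytest.approx(pop)

    def test_single_weight(self):
        assert lorenz_points([5]) == [(0.0, 0.0), (1.0, 1.0)]

    def test_concentrated_weights(self):
        pts = lorenz_points([1, 1, 1, 97])
        assert pts[3] == (0.75, pytest.approx(0.03))
        assert pts[-1] == (1.0, pytest.approx(1.0))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lorenz_points([0, 0])

    def test_curve_below_diagonal(self, rng):
        w = rng.gamma(0.5, size=30)
        for pop, cum in lorenz_points(w):
            assert cum <= pop + 1e-12
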