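import numpy as np
import pandas as pd
import pytest

from carenet.estimation import (FCDModel, assemble_design, compare_models,
                                estimate_fcd_weights, relative_risk_by_decile,
                                score_validation_year)
from carenet.glmm import MixedLogitResult
from carenet.metrics import (LINK_CATEGORIES, enumerate_connection_types,
                             fcd_linear_predictor, link_dummy_columns)


def _tables(small_analysis, small_signal_bundle, which="validation"):
    b = small_signal_bundle
    mt = (small_analysis.validation_table if which == "validation"
          else small_analysis.training_table)
    controls = mt[["patient_id", "year", "quarter"]].merge(
        b.patients[["patient_id", "age_z", "female", "comorb_depression",
                    "comorb_substance"]], on="patient_id").merge(
        b.timevarying, on=["patient_id", "year", "quarter"])
    return mt, controls, b.outcomes


class TestAssembleDesign:
    def test_baseline_has_no_coordination_columns(self, small_analysis,
                                                  small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        d = assemble_design(mt, controls, outcomes, "baseline")
        assert not any(c.startswith(("cd", "fcd", "link_")) for c in d.X.columns)

    def test_cd_spec_zero_fills_undefined(self, small_analysis,
                                          small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        d = assemble_design(mt, controls, outcomes, "cd")
        undef = d.X["cd_undefined"] == 1.0
        assert undef.sum() > 0
        assert (d.X.loc[undef, "cd"] == 0.0).all()
        # the dummy flags exactly the rows with fewer than two providers
        merged = d.keys.merge(mt, on=["patient_id", "year", "quarter"])
        assert ((merged["n_p"] < 2).to_numpy() == undef.to_numpy()).all()

    def test_fcd_spec_has_single_coordination_column(self, small_analysis,
                                                     small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        d = assemble_design(mt, controls, outcomes, "fcd")
        coord = [c for c in d.X.columns if c in ("fcd_score", "cd",
                                                 "cd_undefined")]
        assert coord == ["fcd_score"]

    def test_misaligned_keys_error_names_first_offender(self, small_analysis,
                                                        small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        with pytest.raises(ValueError, match="misaligned"):
            assemble_design(mt, controls.iloc[5:], outcomes, "baseline")


class TestFCDModel:
    def test_json_roundtrip_lossless(self, small_analysis, tmp_path):
        model = small_analysis.model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FCDModel.from_json(path)
        assert back.beta0 == model.beta0
        assert back.link_weights == model.link_weights
        assert back.control_means == model.control_means
        assert back.cutpoints.cutpoints == model.cutpoints.cutpoints
        assert back.sigma2 == model.sigma2

    def test_weights_cover_all_type_categories(self, small_analysis):
        model = small_analysis.model
        assert len(model.link_weights) == 3 * model.registry.k

    def test_offset_uses_training_means(self, small_analysis):
        model = small_analysis.model
        expected = sum(model.control_coefs[c]["coef"] * model.control_means[c]
                       for c in model.control_coefs)
        assert model.control_offset() == pytest.approx(expected)


class TestFcdLinearPredictor:
    def test_empty_network_scores_base_risk(self, small_analysis):
        model = small_analysis.model
        cats = {t: "missing" for t in model.registry.connection_types}
        assert fcd_linear_predictor(cats, model) == pytest.approx(
            model.beta0 + model.control_offset())

    def test_single_link_adds_its_weight(self, small_analysis):
        model = small_analysis.model
        cats = {t: "missing" for t in model.registry.connection_types}
        cats[("GP", "PSY")] = "strong"
        base = model.beta0 + model.control_offset()
        w = model.link_weights[(("GP", "PSY"), "strong")]
        assert fcd_linear_predictor(cats, model) == pytest.approx(base + w)

    def test_layout_mismatch_rejected(self, small_analysis):
        model = small_analysis.model
        cats = {("GP", "DENTIST"): "weak"}
        with pytest.raises(ValueError, match="layout mismatch"):
            fcd_linear_predictor(cats, model)


class TestScoring:
    def test_score_is_deterministic_linear_function(self, small_analysis):
        mt = small_analysis.validation_table
        model = small_analysis.model
        again = score_validation_year(mt.drop(columns=["fcd_score"]), model)
        assert np.allclose(again["fcd_score"], mt["fcd_score"])

    def test_score_differences_depend_only_on_dummies(self, small_analysis):
        """Two rows with identical dummy patterns score identically."""
        mt = small_analysis.validation_table
        cols = link_dummy_columns(small_analysis.model.registry)
        key = mt[cols].astype(int).astype(str).agg("".join, axis=1)
        for _, grp in mt.groupby(key):
            assert grp["fcd_score"].nunique() == 1

    def test_missing_dummy_columns_rejected(self, small_analysis):
        mt = small_analysis.validation_table.drop(
            columns=["link_GP_PSY_strong"])
        with pytest.raises(ValueError, match="dummy column"):
            score_validation_year(mt, small_analysis.model)


class TestCompareModels:
    def test_identical_designs_give_zero_statistic(self, small_analysis,
                                                   small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        base = assemble_design(mt, controls, outcomes, "baseline")
        comp = compare_models({"baseline": base, "again": base},
                              compute_se=False)
        assert comp.lrt["again"]["statistic"] == pytest.approx(0.0, abs=1e-6)
        assert comp.lrt["again"]["p"] == 1.0

    def test_degrees_of_freedom_by_spec(self, small_analysis):
        comp = small_analysis.comparison
        assert comp.lrt["cd"]["df"] == 2
        assert comp.lrt["fcd"]["df"] == 1

    def test_chi_square_tail_probability(self, small_analysis):
        from scipy import stats
        for name, t in small_analysis.comparison.lrt.items():
            assert t["p"] == pytest.approx(
                stats.chi2.sf(t["statistic"], t["df"]))

    def test_row_mismatch_rejected(self, small_analysis, small_signal_bundle):
        mt, controls, outcomes = _tables(small_analysis, small_signal_bundle)
        base = assemble_design(mt, controls, outcomes, "baseline")
        short = assemble_design(mt.iloc[:-4], controls, outcomes, "baseline")
        with pytest.raises(ValueError, match="rows differ"):
            compare_models({"baseline": base, "cd": short})


class TestRelativeRisk:
    def _fake_fit(self, gamma):
        return MixedLogitResult(
            param_names=["const", "age_z", "fcd_score"],
            beta=np.array([-2.5, 0.1, gamma]), sigma2=0.3,
            se=np.full(3, 0.1), se_log_sigma=0.1, loglik=-100.0,
            n_obs=100, n_subjects=25, quadrature_nodes=15,
            converged=True, separation_flag=False)

    def _scores(self, rng):
        return pd.DataFrame({"fcd_score": rng.normal(-2.5, 0.5, 400)})

    def test_median_reference_is_exactly_one(self, rng):
        rr = relative_risk_by_decile(self._scores(rng), self._fake_fit(0.8),
                                     {"age_z": 0.0})
        assert rr.loc[rr.decile == 5, "relative_risk"].iloc[0] == 1.0

    def test_positive_weight_gives_monotone_risk(self, rng):
        rr = relative_risk_by_decile(self._scores(rng), self._fake_fit(0.8),
                                     {"age_z": 0.0})
        assert rr["relative_risk"].is_monotonic_increasing

    def test_zero_weight_gives_unit_risk_everywhere(self, rng):
        rr = relative_risk_by_decile(self._scores(rng), self._fake_fit(0.0),
                                     {"age_z": 0.0})
        assert np.allclose(rr["relative_risk"], 1.0)

    def test_too_few_distinct_scores_rejected(self):
        scored = pd.DataFrame({"fcd_score": [1.0] * 50})
        with pytest.raises(ValueError, match="distinct"):
            relative_risk_by_decile(scored, self._fake_fit(0.5), {"age_z": 0.0})
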