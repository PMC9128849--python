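import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mrp import analysis, sdt, simulate
from mrp.exceptions import InsufficientDataError


class TestDeltaTdxc:
    def test_identical_lists(self):
        assert analysis.delta_tdxc([1.5, -0.5], [1.5, -0.5]) == 0.0

    def test_hand_worked_example(self):
        original = sdt.transform_tdxc(np.array([4, 4, 3]))      # 3.5, 3.5, 2.5
        modified = sdt.transform_tdxc(np.array([1, -2]))        # 0.5, -1.5
        assert analysis.delta_tdxc(original, modified) == pytest.approx(
            (3.5 + 3.5 + 2.5) / 3 - (0.5 - 1.5) / 2)
        assert analysis.delta_tdxc(original, modified) == pytest.approx(3.66667, abs=1e-4)

    def test_extreme_bound(self):
        o = sdt.transform_tdxc(np.array([4, 4]))
        m = sdt.transform_tdxc(np.array([-4, -4]))
        assert analysis.delta_tdxc(o, m) == 7.0

    def test_antisymmetry(self, rng):
        a = rng.choice(sdt.TDXC_LEVELS, size=9)
        b = rng.choice(sdt.TDXC_LEVELS, size=4)
        assert analysis.delta_tdxc(a, b) == pytest.approx(-analysis.delta_tdxc(b, a))
        assert abs(analysis.delta_tdxc(a, b)) <= 7.0

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            analysis.delta_tdxc([], [1.5])


def _pair_frame(cong_orig, cong_mod, incong_orig, incong_mod, pair_id="pX"):
    rows = []
    for cong, ptype, vals in [("congruent", "original", cong_orig),
                              ("congruent", "modified", cong_mod),
                              ("incongruent", "original", incong_orig),
                              ("incongruent", "modified", incong_mod)]:
        for v in vals:
            rows.append({"image_pair_id": pair_id, "initial_congruence": cong,
                         "patch_type": ptype, "dxc": int(v)})
    return pd.DataFrame(rows)


class TestClassifyImagePair:
    def test_large_effect_only_congruent_is_blue(self):
        df = _pair_frame([4] * 10, [-4] * 10, [1, -1] * 5, [-1, 1] * 5)
        res = analysis.classify_image_pair(df)
        assert res.category == "blue"
        assert res.delta_tdxc_congruent == pytest.approx(7.0)
        assert res.p_congruent < 0.05 <= res.p_incongruent

    def test_large_effect_only_incongruent_is_red(self):
        df = _pair_frame([1, -1] * 5, [-1, 1] * 5, [4] * 10, [-4] * 10)
        assert analysis.classify_image_pair(df).category == "red"

    def test_opposite_effects_black_with_interaction(self):
        df = _pair_frame([4] * 10, [-4] * 10, [-4] * 10, [4] * 10)
        res = analysis.classify_image_pair(df)
        assert res.category == "black"
        assert res.interaction_flag is True
        assert res.delta_tdxc_congruent == pytest.approx(7.0)
        assert res.delta_tdxc_incongruent == pytest.approx(-7.0)

    def test_parallel_effects_no_interaction(self):
        df = _pair_frame([4] * 12, [-4] * 12, [4] * 12, [-4] * 12)
        res = analysis.classify_image_pair(df)
        assert res.category == "black"
        assert res.interaction_flag is False

    def test_untestable_cell_reported_missing(self):
        df = _pair_frame([4], [-4] * 5, [1] * 5, [-1] * 5)  # 1 obs in a cell
        res = analysis.classify_image_pair(df)
        assert res.category is None

    def test_null_effect_mostly_grey(self):
        rng = np.random.default_rng(0)
        n_grey = 0
        reps = 300
        for _ in range(reps):
            vals = rng.choice(sdt.DXC_LEVELS, size=(4, 15))
            df = _pair_frame(*vals)
            res = analysis.classify_image_pair(df, interaction=False)
            n_grey += res.category == "grey"
        # two independent tests at alpha=0.05 -> P(grey) ~ 0.90
        assert 0.84 <= n_grey / reps <= 0.96

    def test_classify_all_pairs(self, exp2_responses):
        table = analysis.classify_all_pairs(exp2_responses, interaction=False)
        probes = exp2_responses[~exp2_responses.is_catch]
        assert len(table) == probes["image_pair_id"].nunique()
        assert table["category"].isin(["grey", "blue", "red", "black"]).all()
        # directional preset: mean congruent delta exceeds incongruent
        assert (table["delta_tdxc_congruent"].mean()
                > table["delta_tdxc_incongruent"].mean())


class TestNullCalibration:
    def test_fpr_close_to_alpha(self):
        fpr = analysis.null_classifier_fpr(n_reps=4000, seed=1)
        assert fpr == pytest.approx(0.05, abs=0.015)


class TestProportionCurves:
    def test_per_participant_proportions_sum_to_one(self, exp2_responses):
        probes = exp2_responses[~exp2_responses.is_catch]
        props = analysis._participant_proportions(
            probes[probes.patch_type.isin({"present", "original"})])
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_curve_table_shape_and_direction(self, exp2_responses):
        out = analysis.proportion_curves(
            exp2_responses, {"present", "original"}, {"null"},
            labels=("present", "null"))
        assert list(out["dxc"]) == list(sdt.DXC_LEVELS)
        top = out.set_index("dxc")
        # confident yes dominates the present curve; confident no the null curve
        assert top.loc[4, "mean_present"] > top.loc[4, "mean_null"]
        assert top.loc[-4, "mean_null"] > top.loc[-4, "mean_present"]

    def test_identical_populations_not_flagged(self, null_responses):
        out = analysis.proportion_curves(
            null_responses, {"present"}, {"null"}, labels=("a", "b"))
        assert (out["flag"] == "").all()

    def test_eccentricity_filter(self, exp2_responses):
        out = analysis.proportion_curves(
            exp2_responses, {"present", "original"}, {"null"},
            labels=("present", "null"), eccentricity="fovea")
        assert len(out) == 8


class TestAucSummary:
    def test_chance_preset(self, null_responses):
        per = analysis.auc_summary(null_responses, "present_vs_null", strata=False)
        assert per["type1_auc"].mean() == pytest.approx(0.5, abs=0.02)

    def test_perfect_preset(self):
        from mrp import design
        plan = design.build_design("exp2", n_participants=4, seed=2, n_pairs=34)
        df = simulate.simulate_responses(plan, simulate.get_preset("perfect"), seed=2)
        per = analysis.auc_summary(df, "present_vs_null", strata=False)
        assert (per["type1_auc"] == 1.0).all()

    def test_eccentricity_attenuation_monotone(self, exp2_responses):
        per = analysis.auc_summary(exp2_responses, "present_vs_null")
        means = per.groupby("stratum")["type1_auc"].mean()
        assert means["fovea"] > means["parafovea"] > means["periphery"]

    def test_type2_missing_when_no_errors(self):
        df = pd.DataFrame({
            "participant_id": ["p"] * 4,
            "patch_type": ["present", "present", "null", "null"],
            "decision": ["yes", "yes", "no", "no"],
            "confidence": [4, 3, 4, 2],
            "dxc": [4, 3, -4, -2],
            "eccentricity_class": ["fovea"] * 4,
        })
        per = analysis.auc_summary(df, "present_vs_null", strata=False)
        assert per["type1_auc"].iloc[0] == 1.0
        assert np.isnan(per["type2_auc"].iloc[0])

    def test_summarize_matches_recovered_truth(self, exp2_responses):
        """Mean per-stratum AUC matches the closed-form value for the task's
        signal mixture (4/5 present + 1/5 original, congruence split 50/50)."""
        params = simulate.get_preset("exp2-default")
        per = analysis.auc_summary(exp2_responses, "present_vs_null")
        summ = analysis.summarize_auc(per)
        for ecc in ("fovea", "parafovea", "periphery"):
            p_sig = (0.8 * simulate.rating_bin_probs(params, "present", ecc)
                     + 0.1 * simulate.rating_bin_probs(params, "original", ecc,
                                                       "congruent")
                     + 0.1 * simulate.rating_bin_probs(params, "original", ecc,
                                                       "incongruent"))
            p_noi = simulate.rating_bin_probs(params, "null", ecc)
            truth = simulate.discrete_auc(p_sig, p_noi)
            got = summ.loc[(summ.stratum == ecc) & (summ.measure == "type1_auc"),
                           "mean"].iloc[0]
            assert got == pytest.approx(truth, abs=0.02)


class TestLrtChi2:
    def test_zero_difference(self):
        chi2_stat, p = analysis.lrt_chi2(-100.0, -100.0, 1)
        assert chi2_stat == 0.0 and p == 1.0

    def test_df1(self):
        chi2_stat, p = analysis.lrt_chi2(-100.0, -102.0, 1)
        assert chi2_stat == 4.0
        assert p == pytest.approx(chi2.sf(4, 1))
        assert p == pytest.approx(0.0455, abs=1e-4)

    def test_df2(self):
        _, p = analysis.lrt_chi2(-100.0, -102.0, 2)
        assert p == pytest.approx(0.1353, abs=1e-4)

    def test_misordered_models(self):
        with pytest.raises(ValueError):
            analysis.lrt_chi2(-102.0, -100.0, 1)
        with pytest.raises(ValueError):
            analysis.lrt_chi2(-100.0, -102.0, 0)


class TestModellingExport:
    def test_tidy_table(self, exp2_responses):
        out = analysis.modelling_export(exp2_responses)
        assert {"image_pair_id", "congruence", "delta_tdxc",
                "n_original", "n_modified"} <= set(out.columns)
        assert out["delta_tdxc"].abs().max() <= 7.0

    def test_merges_image_stats(self, exp2_responses):
        stats_df = pd.DataFrame({
            "pair_id": exp2_responses["image_pair_id"].unique(),
            "object_size": 0.05,
        })
        out = analysis.modelling_export(exp2_responses, stats_df)
        assert "object_size" in out.columns
        assert out["object_size"].notna().all()
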