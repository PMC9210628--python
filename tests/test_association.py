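import numpy as np
import pandas as pd
import pytest

from pathburden import association as am
from pathburden.design import build_matched_dataset
from pathburden.simulate import CohortSpec, EffectSpec, generate_study
from pathburden.studies import crude_or_2x2


class TestCochranQ:
    def test_identical_estimates_give_zero_q(self):
        h = am.cochran_q([(0.3, 0.1), (0.3, 0.2)])
        assert h.q_stat == pytest.approx(0.0, abs=1e-12)
        assert h.p_value == pytest.approx(1.0)
        assert h.df == 1

    def test_two_cohort_concordant_example(self):
        # cohort ORs 1.81 (0.95, 3.44) and 1.57 (0.84, 2.95): no heterogeneity
        h = am.cochran_q_from_or_ci([(1.81, 0.95, 3.44), (1.57, 0.84, 2.95)])
        assert h.q_stat == pytest.approx(0.096, abs=0.005)
        assert h.p_value == pytest.approx(0.757, abs=0.01)

    def test_two_cohort_discordant_example(self):
        # cohort ORs 2.01 (1.06, 3.8) and 0.66 (0.34, 1.29): heterogeneous
        h = am.cochran_q_from_or_ci([(2.01, 1.06, 3.8), (0.66, 0.34, 1.29)])
        assert h.q_stat == pytest.approx(5.59, abs=0.05)
        assert h.p_value == pytest.approx(0.018, abs=0.005)

    def test_invariant_to_cohort_order_and_global_sign(self):
        est = [(0.5, 0.2), (-0.1, 0.3), (0.2, 0.25)]
        h1 = am.cochran_q(est)
        h2 = am.cochran_q(est[::-1])
        h3 = am.cochran_q([(-t, s) for t, s in est])
        assert h1.q_stat == pytest.approx(h2.q_stat)
        assert h1.q_stat == pytest.approx(h3.q_stat)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            am.cochran_q([(0.1, 0.2)])
        with pytest.raises(ValueError):
            am.cochran_q([(0.1, 0.0), (0.2, 0.1)])
        with pytest.raises(ValueError):
            am.cochran_q_from_or_ci([(1.2, -0.5, 2.0), (1.0, 0.5, 2.0)])


def test_crude_2x2_or_from_counts():
    """Exposed/unexposed cases 86/122 vs controls 71/137 give the
    cross-product crude OR ~1.36 (the adjusted estimate differs)."""
    assert crude_or_2x2(86, 122, 71, 137) == pytest.approx(
        (86 * 137) / (71 * 122), abs=1e-9
    )
    assert crude_or_2x2(86, 122, 71, 137) == pytest.approx(1.360, abs=0.001)


class TestBuildDesign:
    def test_reference_levels_and_dummies(self):
        data = pd.DataFrame(
            {
                "status": [1, 0, 1, 0],
                "cohort": ["cohortA", "cohortA", "cohortB", "cohortB"],
                "subtype": ["LuminalA", "LuminalB", "TNBC", "LuminalA"],
                "x": [0.0, 1.0, 0.5, 0.2],
            }
        )
        y, X, names = am.build_design(data, "basic", "x")
        assert names[:2] == ["intercept", "x"]
        assert "cohort[cohortB]" in names
        # reference levels produce no column of their own
        assert "subtype[LuminalA]" not in names

    def test_unexpected_level_rejected(self):
        data = pd.DataFrame(
            {
                "status": [1, 0],
                "cohort": ["a", "a"],
                "subtype": ["LuminalA", "Basal"],
                "x": [0.0, 1.0],
            }
        )
        with pytest.raises(ValueError, match="Basal"):
            am.build_design(data, "basic", "x")

    def test_constant_columns_dropped(self):
        data = pd.DataFrame(
            {
                "status": [1, 0, 1, 0],
                "cohort": ["a"] * 4,
                "subtype": ["LuminalA", "LuminalB", "LuminalA", "LuminalB"],
                "x": [0.0, 1.0, 0.5, 0.2],
            }
        )
        _, _, names = am.build_design(data, "basic", "x")
        assert not any(n.startswith("cohort") for n in names)


@pytest.fixture(scope="module")
def matched_data(small_study):
    matched, _, _ = build_matched_dataset(small_study.patients, seed=3)
    return am.attach_exposures(matched, small_study.tmb)


class TestAssociationModel:
    def test_fit_reports_all_cohorts_and_heterogeneity(self, matched_data):
        res = am.PathwayAssociationModel(
            matched_data, "glucocorticoid", "log2_tmb", "main"
        ).fit()
        assert set(res.by_cohort) == {"pooled", "cohortA", "cohortB"}
        assert res.heterogeneity is not None and res.heterogeneity.df == 1
        for r in res.by_cohort.values():
            assert r.ci_low <= r.odds_ratio <= r.ci_high
            assert r.ci_low > 0
        # Wald CI reproducible from the coefficient and SE
        r = res.pooled
        assert r.ci_low == pytest.approx(np.exp(r.log_or - am.Z975 * r.se))
        assert r.ci_high == pytest.approx(np.exp(r.log_or + am.Z975 * r.se))

    def test_summary_mentions_key_numbers(self, matched_data):
        res = am.PathwayAssociationModel(
            matched_data, "glucocorticoid", "any_mutation", "main"
        ).fit()
        text = res.summary()
        assert "glucocorticoid" in text and "heterogeneity" in text

    def test_schedules_agree_when_extra_covariates_are_null(self, rng):
        """Basic vs main adjusted ORs agree within Monte-Carlo tolerance when
        stage/age/menopause carry no effect (small-effect collapsibility)."""
        eff = EffectSpec(
            or_per_doubling_tmb={"glucocorticoid": 1.3},
            covariate_effects={},
            batch_shift={},
        )
        from pathburden.simulate import demo_pathway_collection

        coll = demo_pathway_collection(0)
        study = generate_study(
            coll,
            [CohortSpec(700, "cohortA", seed=4), CohortSpec(700, "cohortB", seed=5)],
            eff,
            seed=12,
            tissues=(),
        )
        matched, _, _ = build_matched_dataset(study.patients, seed=6)
        data = am.attach_exposures(matched, study.tmb)
        basic = am.run_model_schedule(data, "glucocorticoid", "log2_tmb", "basic")
        main = am.run_model_schedule(data, "glucocorticoid", "log2_tmb", "main")
        assert main.odds_ratio == pytest.approx(basic.odds_ratio, abs=0.08)

    def test_exposure_recovery_quick(self, matched_data):
        res = am.run_model_schedule(matched_data, "glucocorticoid", "log2_tmb", "main")
        assert res.ci_low < 1.5 < res.ci_high * 1.5  # loose sanity at small n

    def test_missing_exposure_column_raises(self, matched_data):
        with pytest.raises(KeyError):
            am.PathwayAssociationModel(matched_data, "nonexistent", "log2_tmb")


class TestStratifyEr:
    def test_strata_fit_or_skip(self, matched_data):
        out = am.stratify_er(matched_data, "glucocorticoid", "log2_tmb")
        assert set(out) == {"pos", "neg"}
        for v in out.values():
            assert isinstance(v, (am.PathwayAssociationResults, str))

    def test_absent_stratum_reported_skipped(self, matched_data):
        allpos = matched_data[matched_data["er"] == "pos"]
        out = am.stratify_er(allpos, "glucocorticoid", "log2_tmb")
        assert isinstance(out["neg"], str) and "skipped" in out["neg"]


class TestSensitivityExclusions:
    def _data(self, n_pairs, flagged_pairs):
        rows = []
        for k in range(n_pairs):
            flag = k in flagged_pairs
            rows.append({"id": f"c{k}", "pair_id": k, "status": 1,
                         "nonbc_death": flag, "neoadjuvant": False})
            rows.append({"id": f"k{k}", "pair_id": k, "status": 0,
                         "nonbc_death": False, "neoadjuvant": False})
        return pd.DataFrame(rows)

    def test_flagged_pairs_fully_removed(self):
        data = self._data(10, {2, 7})
        out = am.sensitivity_exclusions(data, "drop_nonbc_death_pairs")
        assert out["pair_id"].nunique() == 8
        assert len(out) == 16

    def test_no_flags_identity(self):
        data = self._data(5, set())
        out = am.sensitivity_exclusions(data, "drop_nonbc_death_pairs")
        pd.testing.assert_frame_equal(out.reset_index(drop=True), data)

    def test_random_flags_match_bruteforce(self, rng):
        data = self._data(30, set())
        data["neoadjuvant"] = rng.random(len(data)) < 0.2
        out = am.sensitivity_exclusions(data, "drop_neoadjuvant_pairs")
        bad = set(data.loc[data["neoadjuvant"], "pair_id"])
        expected_ids = set(data.loc[~data["pair_id"].isin(bad), "id"])
        assert set(out["id"]) == expected_ids

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            am.sensitivity_exclusions(self._data(2, set()), "drop_everything")
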