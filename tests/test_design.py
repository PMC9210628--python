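import numpy as np
import pandas as pd
import pytest

from pathburden.design import (
    build_matched_dataset,
    classify_case_control,
    classify_subtype,
    match_pairs,
)


class TestSubtypeClassifier:
    @pytest.mark.parametrize(
        "er,pr,her2,ki67,expected",
        [
            ("pos", "pos", "neg", 10.0, "LuminalA"),
            ("pos", "pos", "neg", 30.0, "LuminalB"),
            ("pos", "pos", "pos", 10.0, "LuminalB"),
            ("pos", "neg", "neg", 10.0, "LuminalB"),
            ("pos", "neg", "unknown", 10.0, "LuminalB"),  # PR- decides alone
            ("neg", "neg", "pos", 50.0, "HER2"),
            ("neg", "neg", "neg", 50.0, "TNBC"),
            ("pos", "pos", "unknown", 10.0, "Unclassified"),
            ("pos", "pos", "neg", None, "Unclassified"),  # Ki-67 needed for A/B
            ("neg", "pos", "neg", 50.0, "Unclassified"),  # combination not covered
            ("unknown", "neg", "neg", 50.0, "Unclassified"),
        ],
    )
    def test_st_gallen_rule(self, er, pr, her2, ki67, expected):
        assert classify_subtype(er, pr, her2, ki67, ki67_cutoff=20.0) == expected

    def test_cutoff_is_configurable(self):
        assert classify_subtype("pos", "pos", "neg", 25.0, ki67_cutoff=30.0) == "LuminalA"


class TestCaseControlClassifier:
    @pytest.mark.parametrize(
        "event,t,fu,status",
        [
            (True, 3.2, 3.2, "case"),
            (True, 4.999, 4.999, "case"),
            (True, 5.0, 5.0, "ineligible"),  # 5-year window is half-open [0, 5)
            (True, 6.0, 6.0, "ineligible"),
            (False, 6.1, 6.1, "control"),
            (False, 5.0, 5.0, "control"),  # >= 5 years event-free qualifies
            (False, 4.0, 4.0, "ineligible"),
        ],
    )
    def test_five_year_boundary(self, event, t, fu, status):
        assert classify_case_control("p", event, t, fu).status == status

    def test_ineligibility_reasons(self):
        assert "censored" in classify_case_control("p", False, 4.0, 4.0).reason
        assert "after 5" in classify_case_control("p", True, 7.0, 7.0).reason

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            classify_case_control("p", True, -1.0, 1.0)


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["id", "subtype", "er", "pr", "her2"]
    )


class TestMatching:
    def test_simple_subtype_match(self):
        cases = _frame([(f"c{i}", "LuminalA", "pos", "pos", "neg") for i in range(3)])
        controls = _frame([(f"k{i}", "LuminalA", "pos", "pos", "neg") for i in range(5)])
        pairs, unmatched = match_pairs(cases, controls, seed=0)
        assert len(pairs) == 3 and not unmatched
        assert all(p.matching_key == "LuminalA" for p in pairs)

    def test_no_control_reused(self):
        cases = _frame([(f"c{i}", "TNBC", "neg", "neg", "neg") for i in range(4)])
        controls = _frame([(f"k{i}", "TNBC", "neg", "neg", "neg") for i in range(4)])
        pairs, unmatched = match_pairs(cases, controls, seed=1)
        used = [p.control_id for p in pairs]
        assert len(used) == len(set(used)) == 4 and not unmatched

    def test_unmatched_case_reported_not_fatal(self):
        cases = _frame([("c0", "TNBC", "neg", "neg", "neg"),
                        ("c1", "HER2", "neg", "neg", "pos")])
        controls = _frame([("k0", "TNBC", "neg", "neg", "neg")])
        pairs, unmatched = match_pairs(cases, controls, seed=0)
        assert len(pairs) == 1 and unmatched == ["c1"]

    def test_her2_unknown_case_matches_on_er_pr(self):
        cases = _frame([("c0", "Unclassified", "pos", "pos", "unknown")])
        controls = _frame([("k0", "LuminalA", "pos", "pos", "neg"),
                           ("k1", "TNBC", "neg", "neg", "neg")])
        pairs, _ = match_pairs(cases, controls, seed=0)
        assert pairs[0].control_id == "k0"
        assert pairs[0].matching_key == "ER:pos|PR:pos"

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        subs = ["LuminalA", "LuminalB", "TNBC"]
        cases = _frame(
            [(f"c{i}", subs[rng.integers(3)], "pos", "pos", "neg") for i in range(20)]
        )
        controls = _frame(
            [(f"k{i}", subs[rng.integers(3)], "pos", "pos", "neg") for i in range(30)]
        )
        p1, u1 = match_pairs(cases, controls, seed=42)
        p2, u2 = match_pairs(cases, controls, seed=42)
        assert p1 == p2 and u1 == u2

    def test_finds_perfect_matching_when_one_exists(self, rng):
        """Whenever Hall's condition holds on a small instance, some seed
        ordering yields a complete matching (checked against a brute-force
        bipartite feasibility oracle)."""
        subs = ["LuminalA", "LuminalB", "TNBC"]
        for trial in range(30):
            n_c, n_k = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            cases = _frame(
                [(f"c{i}", subs[rng.integers(3)], "pos", "pos", "neg") for i in range(n_c)]
            )
            controls = _frame(
                [(f"k{i}", subs[rng.integers(3)], "pos", "pos", "neg") for i in range(n_k)]
            )
            # oracle: per-subtype supply must cover demand (disjoint keys)
            demand = cases["subtype"].value_counts()
            supply = controls["subtype"].value_counts()
            feasible = all(supply.get(s, 0) >= k for s, k in demand.items())
            found = any(
                not match_pairs(cases, controls, seed=s)[1] for s in range(20)
            )
            if feasible:
                assert found
            else:
                assert not found

    def test_no_cases_is_informative_error(self):
        with pytest.raises(ValueError, match="no cases"):
            match_pairs(_frame([]), _frame([("k0", "TNBC", "neg", "neg", "neg")]), 0)


def test_matched_dataset_balances_subtypes(small_study):
    matched, pairs, _ = build_matched_dataset(small_study.patients, seed=5)
    cases = matched[matched["status"] == 1]
    controls = matched[matched["status"] == 0]
    assert len(cases) == len(controls) == len(pairs)
    # matching keys balance the subtype distribution by construction
    her2_known = matched.merge(pairs, left_on="id", right_on="case_id")
    for _, p in pairs.iterrows():
        c_sub = matched.set_index("id").loc[p["case_id"], "subtype"]
        k_sub = matched.set_index("id").loc[p["control_id"], "subtype"]
        if not p["matching_key"].startswith("ER:"):
            assert c_sub == k_sub
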