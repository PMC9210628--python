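import numpy as np
import pandas as pd
import pytest

from pathburden.design import classify_subtype, match_pairs, build_matched_dataset
from pathburden.registry import PathwayCollection, PathwaySet
from pathburden.simulate import (
    CohortSpec,
    EffectSpec,
    generate_expression,
    generate_mutations,
    generate_outcome,
    generate_patients,
    generate_study,
)
from pathburden.tmb import compute_tmb


@pytest.fixture(scope="module")
def one_mb_pathway():
    lengths = {"A": 600_000, "B": 400_000}
    return PathwayCollection([PathwaySet("pw", frozenset({"A", "B"}), lengths)])


class TestPatients:
    def test_deterministic_under_seed(self):
        spec = CohortSpec(50, "cohortA", seed=11)
        pd.testing.assert_frame_equal(generate_patients(spec), generate_patients(spec))

    def test_subtype_marginal_converges(self):
        spec = CohortSpec(1000, "cohortA", seed=1)
        df = generate_patients(spec)
        frac = (df["subtype"] == "LuminalB").mean()
        assert frac == pytest.approx(0.40, abs=0.05)

    def test_receptors_consistent_with_subtype_rule(self):
        df = generate_patients(CohortSpec(300, "cohortA", seed=2))
        for r in df.itertuples():
            assert classify_subtype(r.er, r.pr, r.her2, r.ki67, 20.0) == r.subtype

    def test_minimal_cohort(self):
        df = generate_patients(CohortSpec(4, "cohortA", seed=0))
        assert len(df) == 4
        assert (df["followup_years"] >= 0).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_patients", 3),
            ("subtype_probs", {"LuminalA": 0.5, "LuminalB": 0.6}),
            ("er_positive_prob", 1.4),
            ("followup_years_range", (5.0, 2.0)),
        ],
    )
    def test_invalid_spec_rejected(self, field, value):
        spec = CohortSpec(10, "cohortA")
        setattr(spec, field, value)
        with pytest.raises(ValueError):
            spec.validate()


class TestMutations:
    def test_zero_rate_means_no_records(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(20, "cohortA", seed=1))
        eff = EffectSpec(default_mutation_rate=0.0)
        assert generate_mutations(pts, one_mb_pathway, eff, seed=0).empty

    def test_poisson_mean_matches_rate_times_length(self, one_mb_pathway):
        n = 400
        pts = generate_patients(CohortSpec(n, "cohortA", seed=1))
        rate = 3.0
        eff = EffectSpec(mutation_rate_per_mb={"pw": rate})
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=5)
        lam = rate * 1.0  # 1 Mb total
        mean = len(muts) / n
        se = np.sqrt(lam / n)
        assert abs(mean - lam) < 3 * se

    def test_gene_hits_proportional_to_coding_length(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(500, "cohortA", seed=1))
        eff = EffectSpec(mutation_rate_per_mb={"pw": 5.0})
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=6)
        frac_a = (muts["Hugo_Symbol"] == "A").mean()
        n = len(muts)
        assert abs(frac_a - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)

    def test_deterministic_under_seed(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(30, "cohortA", seed=1))
        eff = EffectSpec()
        m1 = generate_mutations(pts, one_mb_pathway, eff, seed=9)
        m2 = generate_mutations(pts, one_mb_pathway, eff, seed=9)
        pd.testing.assert_frame_equal(m1, m2)


class TestExpression:
    def test_mutation_effect_shifts_tumor_log2_mean(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(800, "cohortA", seed=3))
        eff = EffectSpec(
            mutation_rate_per_mb={"pw": 0.7},
            tmb_expr_effect={"A": 1.0},
            batch_shift={},
            dispersion=0.05,
        )
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=1)
        # filler genes keep gene A a small share of the library, so CPM
        # composition effects do not attenuate the measured shift
        panel = ["A", "B"] + [f"F{i:02d}" for i in range(40)]
        counts = generate_expression(
            pts, muts, panel, eff, tissue="tumor", seed=2, coll=one_mb_pathway
        )
        mutated = set(muts["Tumor_Sample_Barcode"])
        is_mut = pts["id"].isin(mutated).to_numpy()
        lib = counts.sum(axis=0).to_numpy(float)
        l2 = np.log2((counts.loc["A"].to_numpy(float) + 0.5) / lib * 1e6)
        diff = l2[is_mut].mean() - l2[~is_mut].mean()
        assert diff == pytest.approx(1.0, abs=0.2)

    def test_normal_tissue_free_of_mutation_effect(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(800, "cohortA", seed=3))
        eff = EffectSpec(
            mutation_rate_per_mb={"pw": 0.7},
            tmb_expr_effect={"A": 1.0},
            batch_shift={},
            dispersion=0.05,
        )
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=1)
        panel = ["A", "B"] + [f"F{i:02d}" for i in range(40)]
        counts = generate_expression(
            pts, muts, panel, eff, tissue="normal", seed=2, coll=one_mb_pathway
        )
        mutated = set(muts["Tumor_Sample_Barcode"])
        is_mut = pts["id"].isin(mutated).to_numpy()
        lib = counts.sum(axis=0).to_numpy(float)
        l2 = np.log2((counts.loc["A"].to_numpy(float) + 0.5) / lib * 1e6)
        diff = l2[is_mut].mean() - l2[~is_mut].mean()
        assert diff == pytest.approx(0.0, abs=0.2)

    def test_small_dispersion_approaches_poisson(self):
        pts = generate_patients(CohortSpec(2000, "cohortA", seed=4))
        eff = EffectSpec(dispersion=1e-12, batch_shift={})
        counts = generate_expression(pts, pd.DataFrame(
            columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
        ), ["G1"], eff, seed=5)
        # remove depth variation: rescale by per-sample depth is unavailable,
        # so compare against the NB overdispersion expected at phi=0.3 instead
        x = counts.loc["G1"].to_numpy(float)
        # depth lognormal(0, 0.3) dominates; variance/mean must stay far below
        # the phi=0.3 NB level for the same mean
        phi_hat = max((x.var() - x.mean()) / x.mean() ** 2, 0.0)
        assert phi_hat < 0.15

    def test_empty_gene_list_rejected(self):
        pts = generate_patients(CohortSpec(10, "cohortA"))
        with pytest.raises(ValueError, match="empty"):
            generate_expression(pts, pd.DataFrame(), [], EffectSpec(), seed=0)


class TestOutcome:
    def test_zero_effects_and_zero_logit_give_half_event_rate(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(2000, "cohortA", seed=6))
        eff = EffectSpec(
            baseline_event_logit=0.0, batch_shift={}, covariate_effects={}
        )
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=0)
        tmb = compute_tmb(muts, one_mb_pathway, pts["id"].tolist())
        out = generate_outcome(pts, tmb, None, eff, seed=1)
        assert out["idfs_event"].mean() == pytest.approx(0.5, abs=0.03)

    def test_event_times_within_five_years(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(300, "cohortA", seed=6))
        eff = EffectSpec()
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=0)
        tmb = compute_tmb(muts, one_mb_pathway, pts["id"].tolist())
        out = generate_outcome(pts, tmb, None, eff, seed=1)
        ev = out[out["idfs_event"]]
        assert (ev["idfs_time_years"] < 5.0).all()
        assert (out["idfs_time_years"] <= out["followup_years"]).all()

    def test_hopeless_baseline_yields_no_cases_and_matching_error(self, one_mb_pathway):
        pts = generate_patients(CohortSpec(100, "cohortA", seed=6))
        eff = EffectSpec(baseline_event_logit=-30.0, covariate_effects={})
        muts = generate_mutations(pts, one_mb_pathway, eff, seed=0)
        tmb = compute_tmb(muts, one_mb_pathway, pts["id"].tolist())
        out = generate_outcome(pts, tmb, None, eff, seed=1)
        assert out["idfs_event"].sum() == 0
        with pytest.raises(ValueError, match="no cases"):
            build_matched_dataset(out, seed=0)


class TestStudy:
    def test_full_determinism(self, demo_coll):
        kw = dict(
            coll=demo_coll,
            cohort_specs=[CohortSpec(60, "cohortA"), CohortSpec(60, "cohortB")],
            eff=EffectSpec(),
            seed=77,
            tissues=("tumor",),
        )
        s1, s2 = generate_study(**kw), generate_study(**kw)
        pd.testing.assert_frame_equal(s1.patients, s2.patients)
        pd.testing.assert_frame_equal(s1.mutations, s2.mutations)
        pd.testing.assert_frame_equal(s1.expression["tumor"], s2.expression["tumor"])

    def test_cohort_labels_and_sizes(self, small_study):
        counts = small_study.patients["cohort"].value_counts()
        assert counts["cohortA"] == 250 and counts["cohortB"] == 250
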