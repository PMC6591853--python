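import numpy as np
import pandas as pd
import pytest

import dermengraft as dg
from dermengraft.engraftment import (
    DonorSolution,
    SolutionSet,
    diversity_vs_engraftment,
    engraftment_score,
    engraftment_significance,
    engraftment_timecourse,
    group_contrasts,
)
from dermengraft.profiles import normalize_counts
from dermengraft.simulate import EngraftmentKinetics, StudyDesign


class TestScore:
    def test_self_correlation_is_one(self):
        p = pd.Series([60.0, 30.0, 10.0], index=list("ABC"))
        assert engraftment_score(p, p) == pytest.approx(1.0)

    def test_disjoint_two_taxon_universe(self):
        s = pd.Series([100.0, 0.0], index=["A", "B"])
        sol = pd.Series([0.0, 100.0], index=["A", "B"])
        assert engraftment_score(s, sol) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        s = pd.Series([60.0, 30.0, 10.0], index=list("ABC"))
        sol = pd.Series([70.0, 20.0, 10.0], index=list("ABC"))
        assert engraftment_score(s, sol) == pytest.approx(0.9683006310, abs=1e-9)

    def test_symmetric_and_scale_invariant(self, rng):
        s = pd.Series(rng.random(5) * 100, index=list("ABCDE"))
        sol = pd.Series(rng.random(5) * 100, index=list("ABCDE"))
        r = engraftment_score(s, sol)
        assert engraftment_score(sol, s) == pytest.approx(r)
        assert engraftment_score(s * 4.2, sol) == pytest.approx(r)

    def test_union_support_with_absent_taxa(self):
        s = pd.Series([80.0, 20.0], index=["A", "B"])
        sol = pd.Series([100.0], index=["A"])
        assert engraftment_score(s, sol) == pytest.approx(1.0)
        # a taxon declared with zero abundance is zero-filled identically
        # whichever side declares it
        s2 = pd.Series([80.0, 20.0, 0.0], index=["A", "B", "Z"])
        sol2 = pd.Series([100.0, 0.0], index=["A", "Z"])
        assert engraftment_score(s2, sol) == pytest.approx(engraftment_score(s2, sol2))
        assert engraftment_score(s2, sol) == pytest.approx(engraftment_score(s, sol2))

    def test_constant_vector_undefined(self):
        s = pd.Series([50.0, 50.0], index=["A", "B"])
        sol = pd.Series([50.0, 50.0], index=["A", "B"])
        assert np.isnan(engraftment_score(s, sol))


def _mini_solutions():
    return SolutionSet.from_solutions([
        DonorSolution("SOL", {"slst": pd.Series({"H1": 80.0, "A1": 20.0})}, "slst"),
    ])


class TestTimecourse:
    def test_treated_rises_then_decays(self, default_series):
        study, _, series = default_series
        tr = series[~series.is_control]
        by_day = tr.groupby("day")["score"].mean()
        assert by_day[3] > by_day[1]
        assert by_day[4] > by_day[1]
        assert by_day[52] < by_day[4]

    def test_control_trajectory_flat(self, default_series):
        _, _, series = default_series
        ctrl = series[series.is_control].groupby("day")["score"].mean()
        assert ctrl.max() - ctrl.min() < 0.05

    def test_single_sample_single_day(self):
        abund = {"slst": pd.DataFrame([[70.0, 30.0]], index=["s1"],
                                      columns=["H1", "A1"])}
        meta = pd.DataFrame([{"sample_id": "s1", "subject_id": "P1", "area": 1,
                              "day": 0, "solution_id": "SOL",
                              "dose_cfu_per_ml": 1e6}])
        out = engraftment_timecourse(abund, meta, _mini_solutions(),
                                     control_policy="skip")
        assert len(out) == 1 and not np.isnan(out.loc[0, "score"])

    def test_missing_solution_errors_with_samples(self):
        abund = {"slst": pd.DataFrame([[70.0, 30.0]], index=["s1"],
                                      columns=["H1", "A1"])}
        meta = pd.DataFrame([{"sample_id": "s1", "subject_id": "P1", "area": 1,
                              "day": 0, "solution_id": "GHOST",
                              "dose_cfu_per_ml": 1e6}])
        with pytest.raises(ValueError, match="GHOST.*s1"):
            engraftment_timecourse(abund, meta, _mini_solutions())

    def test_controls_scored_against_each_solution(self, default_series):
        study, _, series = default_series
        ctrl = series[series.is_control]
        assert set(ctrl["solution_id"]) == set(study.solutions)


class TestSignificance:
    def test_identical_distributions_all_tied_p_one(self):
        rows = [{"group": "g", "day": d, "score": 5.0, "is_control": False,
                 "subject_id": f"P{i}", "area": 1, "solution_id": "x",
                 "dose_cfu_per_ml": 1e6}
                for d in (1, 2) for i in range(9)]
        out = engraftment_significance(pd.DataFrame(rows), baseline_day=1)
        assert out.loc[0, "p"] == 1.0

    def test_insufficient_n_recorded_as_na(self):
        rows = [{"group": "g", "day": d, "score": s, "is_control": False,
                 "subject_id": "P1", "area": 1, "solution_id": "x",
                 "dose_cfu_per_ml": 1e6}
                for d, s in [(1, 0.1), (1, 0.2), (2, 0.9)]]
        out = engraftment_significance(pd.DataFrame(rows), baseline_day=1)
        assert out.loc[0, "reason"] == "insufficient_n"
        assert np.isnan(out.loc[0, "p"])

    def test_q_never_below_p(self, default_series):
        _, _, series = default_series
        out = engraftment_significance(series, baseline_day=1)
        ok = out.dropna(subset=["p"])
        assert (ok["q"] >= ok["p"] - 1e-15).all()

    def test_high_dose_significant_days_2_to_5(self, default_series):
        _, _, series = default_series
        out = engraftment_significance(series, baseline_day=1)
        hi = out[out.group.str.endswith("@1e8") & out.day.isin([2, 3, 4, 5])]
        assert (hi["q"] < 0.05).all()

    def test_per_group_family_option(self, default_series):
        _, _, series = default_series
        joint = engraftment_significance(series, family="joint")
        per = engraftment_significance(series, family="per_group")
        assert len(joint) == len(per)
        assert not np.allclose(joint["q"].to_numpy(), per["q"].to_numpy(),
                               equal_nan=True)


class TestContrasts:
    def test_susceptible_archetype_ranks_first(self, default_series):
        study, _, series = default_series
        dts = pd.Series(study.truth["subject_slst_archetype"])
        summary, pairs = group_contrasts(series, "dermatotype", dermatotypes=dts)
        assert summary.loc[0, "group"] == "dermatotype_D1+H1"
        top_pairs = pairs[(pairs.group_a == "dermatotype_D1+H1")
                          | (pairs.group_b == "dermatotype_D1+H1")]
        assert (top_pairs["p"] < 0.05).any()

    def test_dose_ordering_in_summary(self, default_series):
        _, _, series = default_series
        summary, _ = group_contrasts(series, "dose")
        assert list(summary["group"]) == ["1e8", "1e6", "1e4"]

    def test_single_group_summaries_only(self):
        rows = [{"group": "SOL@1e6", "day": d, "score": 0.5 + 0.01 * i,
                 "is_control": False, "subject_id": f"P{i}", "area": 1,
                 "solution_id": "SOL", "dose_cfu_per_ml": 1e6}
                for d in (2, 3) for i in range(4)]
        summary, pairs = group_contrasts(pd.DataFrame(rows), "solution")
        assert len(summary) == 1 and pairs.empty

    def test_small_groups_excluded_with_warning(self):
        rows = [{"group": "A@1e6", "day": 2, "score": 0.5, "is_control": False,
                 "subject_id": "P1", "area": 1, "solution_id": "A",
                 "dose_cfu_per_ml": 1e6},
                {"group": "B@1e6", "day": 2, "score": 0.7, "is_control": False,
                 "subject_id": "P2", "area": 2, "solution_id": "B",
                 "dose_cfu_per_ml": 1e6}]
        with pytest.warns(UserWarning, match="excluded"):
            summary, _ = group_contrasts(pd.DataFrame(rows), "solution")
        assert summary.empty


class TestDiversityVsEngraftment:
    def test_no_association_under_default_simulation(self, default_series):
        study, abund, series = default_series
        out = diversity_vs_engraftment(series, abund["slst"], study.metadata)
        assert out["defined"] and out["n"] == 18

    def test_engineered_dependence_detected(self, default_series):
        study, abund, series = default_series
        # add a subject-level effect proportional to baseline diversity rank
        s = series.copy()
        bump = {f"S{i + 1:02d}": 0.3 * i / 17 for i in range(18)}
        div = {}
        base = study.metadata[study.metadata.day <= 1]
        for subj, g in base.groupby("subject_id"):
            vals = [dg.shannon_diversity(abund["slst"].loc[x]) for x in g.sample_id]
            div[subj] = np.mean(vals)
        order = sorted(div, key=div.get)
        bump = {subj: 0.5 * i / len(order) for i, subj in enumerate(order)}
        s["score"] = s["score"] * 0.3 + s["subject_id"].map(bump)
        out = diversity_vs_engraftment(s, abund["slst"], study.metadata)
        assert out["r"] > 0 and out["p"] < 0.05

    def test_too_few_subjects_refused(self, default_series):
        study, abund, series = default_series
        few = series[series.subject_id.isin(["S01", "S02"])]
        with pytest.raises(ValueError, match="4 subjects"):
            diversity_vs_engraftment(few, abund["slst"], study.metadata)


class TestKinetics:
    def test_lambda_monotone_in_dose(self):
        kin = EngraftmentKinetics()
        for day in (2, 3, 4, 5, 8, 12):
            lams = [kin.lambda_at(day, d) for d in (1e4, 1e6, 1e8)]
            assert lams == sorted(lams)

    def test_lambda_zero_before_application(self):
        kin = EngraftmentKinetics()
        assert kin.lambda_at(0, 1e8) == 0.0
        assert kin.lambda_at(1, 1e8) == 0.0

    def test_washout_decays(self):
        kin = EngraftmentKinetics()
        lam = [kin.lambda_at(d, 1e8) for d in (4, 8, 12, 24, 52)]
        assert all(a > b for a, b in zip(lam, lam[1:]))
        # half-life: 4 days
        assert lam[1] == pytest.approx(lam[0] / 2)

    def test_invalid_lambda_max_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            EngraftmentKinetics(dose_lambda_max={1e4: 0.2, 1e6: 0.5, 1e8: 1.4})

    def test_susceptibility_capped_at_one(self):
        kin = EngraftmentKinetics(dose_lambda_max={1e8: 0.9},
                                  susceptibility={"X": 5.0})
        assert kin.lambda_at(4, 1e8, archetype="X") == 1.0
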