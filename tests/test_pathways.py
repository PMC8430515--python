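"""Milestone counting, PCA refinement, pathway assignment and chronology."""

import numpy as np
import pandas as pd
import pytest

import crcdelay as cd
from crcdelay.registry import CATEGORIES

from conftest import make_events, make_patients


class TestCountMilestones:
    def test_empty_history_all_zero(self):
        patients = make_patients([("p1", "2019-06-01")])
        linked = pd.DataFrame(columns=["patient_id", "category", "event_date"])
        counts = cd.count_milestones(linked, patients["patient_id"])
        assert counts.shape == (1, len(CATEGORIES))
        assert (counts.to_numpy() == 0).all()

    def test_simple_tally(self, study):
        events = make_events([("p1", "2019-05-01", "colonoscopy"),
                              ("p1", "2019-05-10", "colonoscopy"),
                              ("p1", "2019-04-01", "fit")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        counts = cd.count_milestones(linked)
        assert counts.loc["p1", "colonoscopy"] == 2
        assert counts.loc["p1", "fit"] == 1
        assert counts.loc["p1"].sum() == 3

    def test_matches_brute_force_tally(self, study):
        rng = np.random.default_rng(3)
        cats = rng.choice(list(CATEGORIES), 50)
        days = rng.integers(0, 300, 50)
        dx = pd.Timestamp("2019-06-01")
        events = make_events([("p1", dx - pd.Timedelta(int(d), "D"), c)
                              for c, d in zip(cats, days)])
        linked = cd.link_lookback(make_patients([("p1", dx)]), events, study)
        counts = cd.count_milestones(linked)
        for cat in CATEGORIES:
            assert counts.loc["p1", cat] == (cats == cat).sum()


class TestPCA:
    def test_block_structure_two_components(self):
        # a perfectly correlated pair plus an exactly orthogonal column:
        # correlation matrix [[1,1,0],[1,1,0],[0,0,1]], eigenvalues (2,1,0)
        a = np.tile([0.0, 1.0], 250)
        c = np.tile([0.0, 0.0, 1.0, 1.0], 125)
        X = pd.DataFrame({"fit": a, "colonoscopy": a, "ct": c})
        result = cd.pca_refine(X)
        assert result.n_retained == 2
        # the correlated pair loads together on one rotated component
        load = result.loadings.abs()
        top = load.idxmax(axis=1)
        assert top["fit"] == top["colonoscopy"] != top["ct"]

    def test_independent_columns_have_unit_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((5000, 4)),
                         columns=["a", "b", "c", "d"])
        result = cd.pca_refine(X)
        assert np.allclose(result.eigenvalues, 1.0, atol=0.12)

    def test_eigenvalues_match_characteristic_polynomial_roots(self):
        # brute-force oracle: coefficients of det(C - lambda I) for 3x3 built
        # from trace, principal-minor sum and determinant
        X = pd.DataFrame([[1.0, 2.0, 0.0], [2.0, 1.0, 1.0],
                          [3.0, 4.0, 1.0], [0.0, 1.0, 3.0]],
                         columns=["x", "y", "z"])
        C = np.corrcoef(X.to_numpy(), rowvar=False)
        tr = np.trace(C)
        minors = sum(np.linalg.det(C[np.ix_([i, j], [i, j])])
                     for i in range(3) for j in range(i + 1, 3))
        det = np.linalg.det(C)
        roots = np.sort(np.roots([1.0, -tr, minors, -det]).real)[::-1]
        result = cd.pca_refine(X)
        assert np.allclose(result.eigenvalues, roots, atol=1e-8)

    def test_trace_conservation_and_row_order_invariance(self, default_cohort):
        counts = cd.count_milestones(default_cohort["linked"]).head(3000)
        used = counts.loc[:, counts.std() > 0]
        result = cd.pca_refine(counts)
        assert result.eigenvalues.sum() == pytest.approx(used.shape[1], abs=1e-8)
        shuffled = counts.sample(frac=1.0, random_state=0)
        result2 = cd.pca_refine(shuffled)
        pd.testing.assert_frame_equal(result.loadings, result2.loadings)

    def test_constant_columns_rejected_when_too_few_remain(self):
        X = pd.DataFrame({"a": [1.0] * 10, "b": [2.0] * 10,
                          "c": np.arange(10, dtype=float)})
        with pytest.raises(ValueError):
            cd.pca_refine(X)


class TestAssignPathway:
    def test_fit_initiator_is_screening(self, study):
        events = make_events([("p1", "2019-01-01", "fit"),
                              ("p1", "2019-03-21", "colonoscopy")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        a = cd.assign_pathway(linked)
        assert a.loc[0, "group"] == "screening"
        assert a.loc[0, "initiating_category"] == "fit"
        assert a.loc[0, "detail"] == "fit>colonoscopy"

    def test_procedure_only_history_unclassified(self, study):
        events = make_events([("p1", "2019-05-01", "colonoscopy")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        a = cd.assign_pathway(linked)
        assert a.loc[0, "group"] == "unclassified"
        assert pd.isna(a.loc[0, "initiating_category"])

    def test_same_day_tie_prefers_blood_over_symptom(self, study):
        events = make_events([("p1", "2019-05-01", "rectal_bleeding"),
                              ("p1", "2019-05-01", "blood_test")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        assert cd.assign_pathway(linked).loc[0, "group"] == "blood_test"

    def test_same_day_tie_prefers_fit_over_all(self, study):
        events = make_events([("p1", "2019-05-01", "abdominal_pain"),
                              ("p1", "2019-05-01", "fit"),
                              ("p1", "2019-05-01", "blood_test")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        assert cd.assign_pathway(linked).loc[0, "group"] == "screening"

    def test_earliest_initiator_wins_regardless_of_category_rank(self, study):
        events = make_events([("p1", "2019-02-01", "bowel_obstruction"),
                              ("p1", "2019-05-01", "fit")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        assert cd.assign_pathway(linked).loc[0, "group"] == "symptom"

    def test_round_trip_fidelity_on_generator_output(self, default_cohort):
        a = cd.assign_pathway(default_cohort["linked"],
                              default_cohort["patients"]["patient_id"])
        merged = a.merge(default_cohort["truth"], on="patient_id")
        cls = merged[merged["group"] != "unclassified"]
        assert (cls["group"] == cls["pathway"]).mean() >= 0.99


class TestPathwayProportions:
    def test_arithmetic(self):
        a = pd.DataFrame({"patient_id": list("abcde"),
                          "group": ["screening"] * 3 + ["blood_test", "unclassified"]})
        props, classified = cd.pathway_proportions(a)
        assert props["screening"] == pytest.approx(0.75)
        assert props["blood_test"] == pytest.approx(0.25)
        assert props["symptom"] == 0.0
        assert classified == pytest.approx(0.8)

    def test_order_invariance(self, default_cohort):
        a = cd.assign_pathway(default_cohort["linked"])
        p1, c1 = cd.pathway_proportions(a)
        p2, c2 = cd.pathway_proportions(a.sample(frac=1.0, random_state=1))
        pd.testing.assert_series_equal(p1, p2)
        assert c1 == c2

    def test_all_unclassified_raises(self):
        a = pd.DataFrame({"patient_id": ["a"], "group": ["unclassified"]})
        with pytest.raises(ValueError):
            cd.pathway_proportions(a)

    def test_default_cohort_recovers_pre_pandemic_mix(self, default_cohort):
        assignments = default_cohort["patients"][["patient_id", "period"]].merge(
            cd.assign_pathway(default_cohort["linked"],
                              default_cohort["patients"]["patient_id"]),
            on="patient_id")
        props, classified = cd.pathway_proportions(
            assignments[assignments["period"] == "pre"])
        assert props["screening"] == pytest.approx(0.312, abs=0.015)
        assert classified == pytest.approx(0.752, abs=0.02)


class TestChronology:
    def test_ordered_history_scores_one(self, study):
        events = make_events([("p1", "2019-01-01", "fit"),
                              ("p1", "2019-03-01", "colonoscopy")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        a = cd.assign_pathway(linked)
        assert cd.validate_chronology(linked, a) == 1.0

    def test_reversed_history_scores_zero(self, study):
        # colonoscopy before the FIT in a screening-template history
        events = make_events([("p1", "2019-01-01", "colonoscopy"),
                              ("p1", "2019-03-01", "fit")])
        linked = cd.link_lookback(make_patients([("p1", "2019-06-01")]), events, study)
        a = cd.assign_pathway(linked)
        a["group"] = "screening"  # force the screening template
        assert cd.validate_chronology(linked, a) == 0.0
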