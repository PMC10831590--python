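"""Share tables, agreement metrics, linear probability models, prediction."""

import numpy as np
import pandas as pd
import pytest

from spherodict import (
    consistency,
    correlation,
    fit_lpm,
    nesting_check,
    percent_increase,
    predict_evaluate,
    topic_share_table,
)
from spherodict.tagger import tag_visits
from spherodict import TopicDictionary, oracle_dictionaries


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "initial,enhanced,expected",
        [(315, 1217, 286.35), (100, 100, 0.00), (14141, 10569, -25.26), (375, 405, 8.0)],
    )
    def test_values(self, initial, enhanced, expected):
        assert percent_increase(initial, enhanced) == pytest.approx(expected, abs=0.005)

    def test_zero_initial_flagged(self):
        assert percent_increase(0, 5) is None

    def test_count_difference_exact(self):
        initial, enhanced = 2683, 5219
        assert enhanced - initial == 2536  # the "n" column is exact arithmetic


class TestTopicShareTable:
    def _matrices(self):
        idx = pd.Index([f"v{i}" for i in range(10)], name="visit_id")
        initial = pd.DataFrame(
            {"a": [1, 0, 0, 0, 1, 0, 0, 0, 0, 0], "b": [0, 1, 0, 0, 0, 0, 0, 0, 0, 0]},
            index=idx,
        )
        enhanced = initial.copy()
        enhanced.loc["v2", "a"] = 1  # enhancement adds one visit to topic a
        return initial, enhanced

    def test_hand_tally(self):
        initial, enhanced = self._matrices()
        table = topic_share_table(initial, enhanced, n=10)
        assert table.loc["a", "initial_count"] == 2
        assert table.loc["a", "enhanced_count"] == 3
        assert table.loc["a", "increase_pct"] == 50.0
        assert table.loc["a", "enhanced_share_pct"] == 30.0
        assert table.loc["No tag", "initial_count"] == 7
        assert table.loc["No tag", "enhanced_count"] == 6

    def test_identical_matrices_zero_increase(self):
        initial, _ = self._matrices()
        table = topic_share_table(initial, initial.copy())
        assert (table["increase_pct"].dropna() == 0).all()

    def test_no_tag_share_never_rises(self):
        initial, enhanced = self._matrices()
        table = topic_share_table(initial, enhanced)
        assert table.loc["No tag", "enhanced_count"] <= table.loc["No tag", "initial_count"]

    def test_id_mismatch_rejected(self):
        initial, enhanced = self._matrices()
        with pytest.raises(ValueError, match="visit ids"):
            topic_share_table(initial.iloc[:5], enhanced)


def _phi_from_table(ls, nlp):
    """Textbook phi from the 2x2 contingency table."""
    ls, nlp = np.asarray(ls), np.asarray(nlp)
    n11 = ((ls == 1) & (nlp == 1)).sum()
    n10 = ((ls == 1) & (nlp == 0)).sum()
    n01 = ((ls == 0) & (nlp == 1)).sum()
    n00 = ((ls == 0) & (nlp == 0)).sum()
    denom = np.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return (n11 * n00 - n10 * n01) / denom


class TestCorrelation:
    def test_identical_vectors(self):
        assert correlation([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_balanced_independent_is_zero(self):
        # contingency table (1,1,1,1): phi = 0 by hand
        assert correlation([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_phi(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ls = (rng.random(200) < 0.3).astype(int)
            nlp = (rng.random(200) < 0.4).astype(int)
            if ls.std() == 0 or nlp.std() == 0:
                continue
            assert correlation(ls, nlp) == pytest.approx(_phi_from_table(ls, nlp), abs=1e-10)

    def test_symmetric(self):
        ls, nlp = [1, 1, 0, 0, 1], [1, 0, 1, 0, 0]
        assert correlation(ls, nlp) == pytest.approx(correlation(nlp, ls))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation([1, 1, 1], [1, 0, 1])


class TestConsistency:
    @pytest.mark.parametrize(
        "ls,nlp,expected",
        [
            ([1, 1, 0, 0], [1, 1, 1, 0], 1.0),  # nlp covers all ls tags
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),  # disjoint supports
            ([1, 1, 0, 0], [1, 0, 1, 0], 0.5),  # overlap 1 of 2
        ],
    )
    def test_values(self, ls, nlp, expected):
        assert consistency(ls, nlp) == pytest.approx(expected)

    def test_asymmetric_by_design(self):
        ls, nlp = [1, 0, 0, 0], [1, 1, 1, 0]
        assert consistency(ls, nlp) != consistency(nlp, ls)

    def test_empty_ls_flagged(self):
        assert consistency([0, 0], [1, 0]) is None


def _lpm_visits(y, **covs):
    df = pd.DataFrame({"visit_id": [str(i) for i in range(len(y))]})
    for k, v in covs.items():
        df[k] = v
    df["y_inpatient"] = y
    return df


class TestFitLpm:
    def test_constant_outcome_degenerate_fit(self):
        v = _lpm_visits([1, 1, 1, 1], age=[10, 20, 30, 40])
        res = fit_lpm(v, None, None, "inpatient", model_id=1)
        assert res.alpha == pytest.approx(1.0, abs=1e-10)
        assert res.beta()["age"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == 0.0

    def test_exactly_linear_toy_data(self):
        # y = 0 + 1 * age exactly -> residuals vanish, hand solution recovered
        v = _lpm_visits([0, 0, 1, 1], age=[0, 0, 1, 1])
        res = fit_lpm(v, None, None, "inpatient", model_id=1)
        assert res.alpha == pytest.approx(0.0, abs=1e-10)
        assert res.beta()["age"] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.resid, 0, atol=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_rank_deficiency_names_columns(self):
        # night + late = 1 everywhere, i.e. collinear with the intercept
        v = _lpm_visits(
            [0, 1, 0, 1], night=[1, 0, 1, 0], late=[0, 1, 0, 1]
        )
        with pytest.raises(ValueError, match="night|late|const"):
            fit_lpm(v, None, None, "inpatient", model_id=1)

    def test_non_binary_outcome_rejected(self):
        v = _lpm_visits([0, 2, 1, 1], age=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="binary"):
            fit_lpm(v, None, None, "inpatient", model_id=1)

    def test_model_blocks(self, small_corpus):
        cfg, visits, truth = small_corpus
        names = cfg.topic_names()
        z = truth[[f"true_{t}" for t in names]].copy()
        z.columns = names
        z.index = pd.Index(visits["visit_id"], name="visit_id")
        w = pd.get_dummies(truth["true_ls_cluster"]).reindex(columns=names, fill_value=0)
        w = w.astype(int).set_index(z.index)
        m1 = fit_lpm(visits, z, None, "inpatient", model_id=1)
        m2 = fit_lpm(visits, None, w, "inpatient", model_id=2)
        m3 = fit_lpm(visits, z, w, "inpatient", model_id=3)
        assert len(m1.gamma()) == len(names) and len(m1.delta()) == 0
        assert len(m2.delta()) == len(names) and len(m2.gamma()) == 0
        assert len(m3.gamma()) == len(names) and len(m3.delta()) == len(names)
        assert nesting_check((m1, m2, m3))

    def test_robust_se_differ_from_classical(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(0, 1, 400)
        y = (rng.random(400) < 0.2 + 0.5 * age).astype(int)
        v = _lpm_visits(y, age=age)
        classical = fit_lpm(v, None, None, "inpatient", se_type="classical")
        robust = fit_lpm(v, None, None, "inpatient", se_type="robust")
        assert not np.allclose(classical.bse, robust.bse)
        assert np.allclose(classical.params, robust.params)


class TestNestingCheck:
    def test_mismatched_samples_error(self, small_corpus):
        cfg, visits, truth = small_corpus
        names = cfg.topic_names()
        z = truth[[f"true_{t}" for t in names]].copy()
        z.columns = names
        z.index = pd.Index(visits["visit_id"], name="visit_id")
        m1 = fit_lpm(visits, z, None, "inpatient", model_id=1)
        from dataclasses import replace

        m_other = replace(m1, n=m1.n - 1)
        with pytest.raises(ValueError, match="sample"):
            nesting_check((m1, m1, m_other))


class TestPredictEvaluate:
    def test_separable_outcome_perfect_auc(self):
        n = 400
        age = np.repeat([0.0, 1.0], n // 2)
        v = _lpm_visits((age > 0.5).astype(int), age=age)
        rep = predict_evaluate(v, None, None, "inpatient", model_id=1, seed=0)
        assert rep.auc == 1.0

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(5)
        n = 10_000
        v = _lpm_visits(
            (rng.random(n) < 0.5).astype(int), age=rng.uniform(0, 1, n)
        )
        rep = predict_evaluate(v, None, None, "inpatient", model_id=1, seed=5)
        assert rep.auc == pytest.approx(0.5, abs=0.02)

    def test_f1_all_positive_hand_value(self):
        # all-positive predictor, 30% prevalence: F1 = 2*0.3/1.3 = 0.4615
        from sklearn.metrics import f1_score

        y = np.zeros(1000, dtype=int)
        y[:300] = 1
        assert f1_score(y, np.ones_like(y)) == pytest.approx(0.4615, abs=1e-4)

    def test_single_class_split_suggests_reseed(self):
        v = _lpm_visits([0] * 50 + [1], age=np.linspace(0, 1, 51))
        with pytest.raises(ValueError, match="seed"):
            predict_evaluate(v, None, None, "inpatient", model_id=1, seed=0)

    def test_auc_invariant_to_monotone_score_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.random(500)
        y = (rng.random(500) < scores).astype(int)
        a1 = roc_auc_score(y, scores)
        a2 = roc_auc_score(y, np.exp(3 * scores))
        assert a1 == pytest.approx(a2, abs=1e-12)


def test_share_table_from_tagging_pipeline(small_corpus):
    """End-to-end: truncated vs full dictionaries through the share table."""
    cfg, visits, _ = small_corpus
    initial = tag_visits(visits, oracle_dictionaries(cfg, words_per_topic=4))
    enhanced = tag_visits(visits, oracle_dictionaries(cfg))
    table = topic_share_table(initial, enhanced)
    assert (table["increase_n"].drop("No tag") >= 0).all()
    assert table.loc["No tag", "increase_n"] <= 0
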