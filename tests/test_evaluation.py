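import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpmnext import (
    NONE_OUTCOME,
    TransitionTable,
    evaluate,
    genotype_covariates,
    js_distance,
    method_agreement,
    stratified_summary,
    true_transition_table,
)
from cpmnext.sampling import CrossSectionalSample

from conftest import make_run


def js_oracle(p, q):
    """Direct evaluation of sqrt(0.5 KL(p||m) + 0.5 KL(q||m)), log base 2."""
    def kl(a, b):
        return sum(x * math.log2(x / y) for x, y in zip(a, b) if x > 0)

    m = [(x + y) / 2 for x, y in zip(p, q)]
    return math.sqrt(0.5 * kl(p, m) + 0.5 * kl(q, m))


class TestJSDistance:
    def test_identical_is_exactly_zero(self):
        assert js_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_is_exactly_one(self):
        assert js_distance([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_reference_value(self):
        # frozen from the hand formula: js((1,0), (.5,.5)) = 0.5579230...
        assert js_distance([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.557923, abs=1e-6)
        assert js_oracle([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.557923, abs=1e-6)

    def test_matches_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            assert js_distance(p, q) == pytest.approx(js_oracle(p, q), abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            js_distance([0.5, 0.5], [1.0])
        with pytest.raises(ValueError):
            js_distance([0.7, 0.7], [0.5, 0.5])

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_is_a_bounded_metric(self, a, b, c):
        p, q, r = (np.array(v) / np.sum(v) for v in (a, b, c))
        dpq = js_distance(p, q)
        assert 0.0 <= dpq <= 1.0
        assert dpq == pytest.approx(js_distance(q, p))
        assert dpq <= js_distance(p, r) + js_distance(r, q) + 1e-9


def table(G, rows):
    return TransitionTable(G=G, rows=rows)


class TestEvaluate:
    def setup_method(self):
        self.truth = true_transition_table(
            [
                make_run(2, lod=[0b00, 0b01, 0b11], observable=[0b00]),
                make_run(2, lod=[0b00, 0b10, 0b11], observable=[0b00]),
            ]
        )

    def test_perfect_prediction_scores_zero(self):
        pred = table(2, {0b00: dict(self.truth.rows[0b00])})
        df = evaluate(self.truth, {"M": pred})
        assert df["js"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["min_js"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_none_vs_ce_disjoint_scores_one(self):
        truth = table(2, {0b01: {NONE_OUTCOME: 1.0}})
        truth.denominators[0b01] = 4
        pred = table(2, {0b01: {0b11: 1.0, NONE_OUTCOME: 0.0}})
        df = evaluate(truth, {"CE": pred})
        assert df["js"].iloc[0] == 1.0

    def test_min_js_over_methods(self):
        good = table(2, {0b00: {0b01: 0.5, 0b10: 0.5, NONE_OUTCOME: 0.0}})
        perfect = table(2, {0b00: dict(self.truth.rows[0b00])})
        df = evaluate(self.truth, {"A": good, "B": perfect})
        by_m = df.set_index("method")
        assert by_m.loc["B", "js"] <= by_m.loc["A", "js"]
        assert (df["min_js"] <= df["js"] + 1e-12).all()

    def test_missing_prediction_uses_fallback_and_flags(self):
        df = evaluate(self.truth, {"E": table(2, {})})
        assert (df["flag"] == "missing_prediction").all()


class TestCovariates:
    def test_rank_propmax_and_frequencies(self, rep_landscape):
        runs = [
            make_run(4, lod=[0b0000, 0b0001, 0b0011], observable=[0b0000, 0b0011])
        ]
        truth = true_transition_table(runs)
        rows = np.zeros((20, 4), dtype=int)
        rows[:1, 0] = 0  # 1 of 20 rows is WT... all-zero rows already
        sample = CrossSectionalSample(
            matrix=pd.DataFrame(rows, columns=list("abcd"))
        )
        cov = genotype_covariates(truth, rep_landscape, sample=sample, full_sample=sample)
        cov = cov.set_index("genotype")
        # global maximum of the representable landscape is 1111 -> rank 1
        assert cov.loc["0000", "fitnessRank"] > 1
        assert cov.loc["0000", "propLocalMax"] == 0.0
        assert cov.loc["0000", "nMut"] == 0
        assert cov.loc["0000", "observedProp"] == pytest.approx(1.0)
        assert cov.loc["0000", "diff_obs_prop"] == pytest.approx(0.0)

    def test_observed_proportion_arithmetic(self, rep_landscape):
        truth = true_transition_table(
            [make_run(4, lod=[0b0000, 0b0001], observable=[0b0001])]
        )
        m_small = np.zeros((200, 4), dtype=int)
        m_small[:10, 0] = 1  # genotype 1000 in 10/200 rows
        m_full = np.zeros((20000, 4), dtype=int)
        m_full[:800, 0] = 1  # and in 800/20000 of the full sample
        cols = list("abcd")
        cov = genotype_covariates(
            truth,
            rep_landscape,
            sample=CrossSectionalSample(matrix=pd.DataFrame(m_small, columns=cols)),
            full_sample=CrossSectionalSample(matrix=pd.DataFrame(m_full, columns=cols)),
        ).set_index("genotype")
        assert cov.loc["1000", "observedProp"] == pytest.approx(0.05)
        assert cov.loc["1000", "diff_obs_prop"] == pytest.approx(0.01)


class TestAgreement:
    def _tables(self, ce_same=True, td_same=True, ce_td_far=True):
        sup = {0b01: 1.0, 0b10: 0.0, NONE_OUTCOME: 0.0}
        alt = {0b01: 0.0, 0b10: 1.0, NONE_OUTCOME: 0.0}
        stay = {0b01: 0.0, 0b10: 0.0, NONE_OUTCOME: 1.0}
        preds = {
            "CBN": table(2, {0: dict(sup)}),
            "MHN": table(2, {0: dict(sup if ce_same else alt)}),
            "CBN_td": table(2, {0: dict(stay if ce_td_far else sup)}),
            "MHN_td": table(2, {0: dict(stay if td_same else alt)}),
        }
        return preds

    def test_similar_ce_and_different_ce_td(self):
        df, summary = method_agreement(self._tables())
        rec = df.iloc[0]
        assert rec["similar_ce"] and rec["similar_td"] and rec["different_ce_td"]
        assert summary["pct_similar_ce_and_different"] == 100.0
        assert summary["pct_both_similar_and_different"] == 100.0

    def test_different_ce_pair_not_flagged(self):
        df, summary = method_agreement(self._tables(ce_same=False))
        assert not df.iloc[0]["similar_ce"]
        assert summary["pct_similar_ce_and_different"] == 0.0

    def test_counting_percentage(self):
        sup = {0b01: 1.0, 0b10: 0.0, NONE_OUTCOME: 0.0}
        stay = {0b01: 0.0, 0b10: 0.0, NONE_OUTCOME: 1.0}
        # 5 genotypes, flag pattern True for 0b00 only
        rows_ce = {g: dict(sup) for g in [0b00]}
        preds = {
            "CBN": table(2, {0b00: dict(sup), 0b01: {0b11: 1.0, NONE_OUTCOME: 0.0}}),
            "MHN": table(2, {0b00: dict(sup), 0b01: {NONE_OUTCOME: 1.0}}),
            "CBN_td": table(2, {0b00: dict(stay), 0b01: {0b11: 1.0, NONE_OUTCOME: 0.0}}),
            "MHN_td": table(2, {0b00: dict(stay), 0b01: {NONE_OUTCOME: 1.0}}),
        }
        df, summary = method_agreement(preds)
        assert summary["n_genotypes"] == 2
        assert summary["pct_similar_ce_and_different"] == 50.0

    def test_missing_method_raises(self):
        preds = self._tables()
        del preds["MHN_td"]
        with pytest.raises(ValueError):
            method_agreement(preds)


class TestStratifiedSummary:
    def _records(self):
        return pd.DataFrame(
            {
                "genotype": ["00", "01", "00", "01"],
                "method": ["A", "A", "B", "B"],
                "js": [0.2, 0.4, 0.3, 0.1],
                "min_js": [0.2, 0.1, 0.2, 0.1],
                "weight": [1.0, 1.0, 1.0, 1.0],
                "kind": ["x", "x", "x", "x"],
            }
        )

    def test_single_stratum_equals_plain_average(self):
        out = stratified_summary(self._records(), ["kind"])
        assert out["mean_min_js"].iloc[0] == pytest.approx(0.15)
        assert out["mean_js_A"].iloc[0] == pytest.approx(0.3)

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            stratified_summary(pd.DataFrame(), ["kind"])
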