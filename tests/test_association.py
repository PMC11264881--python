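"""Logistic association, BH adjustment, AUC and cohort-table statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neometab import association as A
from neometab.io_model import records_to_frame
from neometab import synthetic_data as sd
from neometab import feature_processing as fp
from neometab import qc_normalization as qn


class TestFitFeatureAssoc:
    def test_two_by_two_equals_cross_product_or(self):
        y = np.r_[np.ones(100), np.zeros(100)]
        x = np.r_[np.ones(30), np.zeros(70), np.ones(15), np.zeros(85)]
        res = A.fit_feature_assoc(y, x, None, mode="binary_presence")[0]
        assert res.estimate == pytest.approx((30 * 85) / (15 * 70), abs=1e-6)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_null_feature_or_near_one(self, rng):
        y = rng.integers(0, 2, 4000).astype(float)
        x = rng.normal(size=4000)
        res = A.fit_feature_assoc(y, x, None)[0]
        assert res.estimate == pytest.approx(1.0, abs=0.15)

    def test_quartile_reference_fixed_at_one(self, rng):
        y = rng.integers(0, 2, 400).astype(float)
        x = fp.quartile_bins(rng.normal(size=400))
        results = A.fit_feature_assoc(y, x, None, mode="quartile")
        assert results[0].quartile_level == 1
        assert results[0].estimate == 1.0
        assert {r.quartile_level for r in results} == {1, 2, 3, 4}

    def test_separation_gets_penalized_fallback(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()  # complete separation
        res = A.fit_feature_assoc(y, x, None, mode="binary_presence")[0]
        assert res.flag == "penalized"
        assert np.isfinite(res.estimate)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = A.bh_adjust([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8], rtol=1e-9)

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(A.bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert A.bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            A.bh_adjust([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=40))
    def test_permutation_invariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        q = A.bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(A.bh_adjust(p[perm]), q[perm], rtol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1 + 1e-12).all()


class TestAuc:
    def test_enumeration_example(self):
        # pairs: (.9,.4)+, (.9,.8)+, (.7,.4)+, (.7,.8)- -> 3/4
        assert A.auc_single([0.9, 0.7, 0.4, 0.8], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert A.auc_single([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert A.auc_single([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            A.auc_single([1, 2], [1, 1])

    def test_equals_exhaustive_pair_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            m = np.round(rng.normal(size=n), 1)  # induce ties
            cases, ctrls = m[y == 1], m[y == 0]
            wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
            assert A.auc_single(m, y) == pytest.approx(wins / (len(cases) * len(ctrls)))


class TestTableStats:
    def test_season_counts_give_balanced_p(self):
        # printed seasonal counts of the matched cohort: p rounds to 0.99
        res = A.contingency_chisq([[168, 180, 190, 201], [168, 185, 188, 198]])
        assert res.df == 3
        assert round(res.p, 2) == 0.99

    def test_family_history_counts_highly_significant(self):
        res = A.contingency_chisq([[222, 517], [138, 601]])
        # hand: N(ad-bc)^2 / (r1 r2 c1 c2)
        n = 222 + 517 + 138 + 601
        hand = n * (222 * 601 - 517 * 138) ** 2 / (739 * 739 * 360 * 1118)
        assert res.statistic == pytest.approx(hand, rel=1e-9)
        assert res.p < 0.001

    def test_identical_rows_statistic_zero(self):
        res = A.contingency_chisq([[10, 20], [10, 20]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_marginal_error(self):
        with pytest.raises(ValueError):
            A.contingency_chisq([[0, 5], [0, 7]])

    def test_t_test_closed_form(self):
        res = A.two_sample_t([0, 1], [1, 2])
        assert res.statistic == pytest.approx(-math.sqrt(2), abs=1e-9)
        assert res.df == 2
        assert res.p == pytest.approx(0.29289, abs=1e-4)

    def test_t_identical_groups(self):
        res = A.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_t_group_size_error(self):
        with pytest.raises(ValueError):
            A.two_sample_t([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def pipeline_run():
    cfg = sd.SimConfig(
        n_pairs=739, n_features=12, n_plates=4, seed=20,
        signal_features=[sd.SignalFeature("F0001", "continuous", 2.0),
                         sd.SignalFeature("F0002", "binary", 2.0)],
    )
    records, truth = sd.generate_neonatal_cohort(cfg)
    table = sd.generate_feature_matrix(records, truth, cfg)
    table = qn.apply_drift_correction(table, qn.fit_drift_model(table))
    proc = fp.process_features(table, impute_method="half_min")
    res = A.run_mwas(proc, records_to_frame(records))
    return truth, res


class TestRunMwas:
    def test_planted_effects_have_smallest_q(self, pipeline_run):
        truth, res = pipeline_run
        by_q = sorted(res, key=lambda r: r.q)
        assert {by_q[0].feature_id, by_q[1].feature_id} == {"F0001", "F0002"}
        assert by_q[0].q < 0.05 and by_q[1].q < 0.05

    def test_modes_match_strata(self, pipeline_run):
        _, res = pipeline_run
        modes = {r.feature_id: r.mode for r in res}
        assert modes["F0001"] == "continuous_per_sd"
        assert modes["F0002"] == "binary_presence"

    def test_model2_adjusts_for_confounders(self, small_cohort):
        _, records, _, table = small_cohort
        proc = fp.process_features(table, impute_method="half_min")
        res = A.run_mwas(proc, records_to_frame(records), A.ModelSpec.model2())
        assert all(r.model_id == "model2" for r in res)

    def test_deterministic(self, small_cohort):
        _, records, _, table = small_cohort
        proc = fp.process_features(table, impute_method="half_min")
        r1 = A.run_mwas(proc, records_to_frame(records))
        r2 = A.run_mwas(proc, records_to_frame(records))
        assert [(r.feature_id, r.p, r.q) for r in r1] == [(r.feature_id, r.p, r.q) for r in r2]


class TestStratifiedInteraction:
    def _run(self, or_early, or_late, seed):
        cfg = sd.SimConfig(n_pairs=400, n_features=4, n_plates=2, seed=seed,
                           drift_amplitude=0.0, batch_sd=0.0, signal_features=[])
        records, truth = sd.generate_neonatal_cohort(cfg)
        table = sd.generate_feature_matrix(records, truth, cfg)
        df = records_to_frame(records)
        # plant a feature whose case shift depends on diagnosis-age stratum
        rng = np.random.default_rng(seed + 1000)
        x = rng.normal(size=len(df))
        is_case = (df["y"] == 1).to_numpy()
        early = is_case & (df["age_at_diagnosis"] < 6).to_numpy()
        late = is_case & ~early
        x[early] += math.log(or_early)
        x[late] += math.log(or_late)
        proc = fp.process_features(table, impute_method="half_min")
        planted = pd.Series((x - x.mean()) / x.std(ddof=1), index=df.index)
        proc.continuous["Fplanted"] = planted.reindex(proc.continuous.index)
        return A.stratified_interaction(proc, df).loc["Fplanted"]

    def test_differential_effect_detected(self):
        hits = sum(self._run(2.2, 1.0, s)["p_interaction"] < 0.05 for s in range(5))
        assert hits >= 3

    def test_equal_effect_not_flagged(self):
        ps = [self._run(1.8, 1.8, s)["p_interaction"] for s in range(5)]
        assert min(ps) > 0.001  # no systematic signal

    def test_empty_stratum_error(self, small_cohort):
        _, records, _, table = small_cohort
        proc = fp.process_features(table, impute_method="half_min")
        df = records_to_frame(records)
        with pytest.raises(ValueError):
            A.stratified_interaction(proc, df, age_threshold=0.0)
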