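import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nodalrisk.io import ReferenceCohort
from nodalrisk.predictor import (
    PredictorParams,
    RiskThresholds,
    _posterior_from_correlations,
    classify_risk,
    posterior_risk,
    predict_cohort,
    results_to_frame,
    spearman_correlation,
)
from nodalrisk.evaluation import roc_auc
from nodalrisk.synthetic import SimulationConfig, generate_cohort

from conftest import matrix_from


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # 1 - 6*4/(4*15)
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_correlation(x, y) == pytest.approx(expected)

    def test_equals_d_squared_formula_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.permutation(12).astype(float)
            y = rng.permutation(12).astype(float)
            d = stats.rankdata(x) - stats.rankdata(y)
            oracle = 1 - 6 * np.sum(d**2) / (12 * (12**2 - 1))
            assert spearman_correlation(x, y) == pytest.approx(oracle)

    def test_equals_pearson_of_ranks_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 4, 15).astype(float)
            y = rng.integers(0, 4, 15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert spearman_correlation(x, y) == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])


class TestPosteriorFormula:
    def test_hand_computed_weighted_mean(self):
        """Correlations (0.8, 0.5, 0.2), labels (1, 0, 1), gamma=1, s=0
        give p = (0.8 + 0.2) / (0.8 + 0.5 + 0.2) = 2/3."""
        params = PredictorParams(prior_strength=0.0)
        p, fallback, _ = _posterior_from_correlations(
            np.array([0.8, 0.5, 0.2]), np.array([1, 0, 1]), params
        )
        assert p == pytest.approx(2 / 3)
        assert not fallback

    def test_negative_correlations_carry_no_weight(self):
        params = PredictorParams(prior_strength=0.0)
        p, _, w = _posterior_from_correlations(
            np.array([0.5, -0.9]), np.array([0, 1]), params
        )
        assert p == 0.0 and w[1] == 0.0

    def test_prior_fallback_when_no_evidence_and_no_prior(self):
        params = PredictorParams(prior_strength=0.0, baseline_prevalence=0.23)
        p, fallback, _ = _posterior_from_correlations(
            np.array([-0.5, -0.1]), np.array([1, 1]), params
        )
        assert p == 0.23 and fallback

    def test_prior_only_when_all_anticorrelated(self):
        params = PredictorParams(prior_strength=2.0, baseline_prevalence=0.23)
        p, fallback, _ = _posterior_from_correlations(
            np.array([-0.5, -0.1]), np.array([1, 1]), params
        )
        assert p == pytest.approx(0.23) and not fallback

    def test_top_k_keeps_ties_with_kth(self):
        params = PredictorParams(k=2, prior_strength=0.0)
        rho = np.array([0.9, 0.5, 0.5, 0.1])
        y = np.array([1, 0, 0, 1])
        p, _, w = _posterior_from_correlations(rho, y, params)
        assert w[3] == 0.0 and w[1] > 0 and w[2] > 0  # both 0.5s retained
        assert p == pytest.approx(0.9 / 1.9)

    @given(st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_is_convex_combination_of_prior_and_labels(self, pi0, seed):
        pi0 = min(max(pi0, 1e-6), 1 - 1e-6)
        rng = np.random.default_rng(seed)
        rho = rng.uniform(-1, 1, 10)
        y = rng.integers(0, 2, 10)
        params = PredictorParams(prior_strength=rng.uniform(0, 5),
                                 baseline_prevalence=pi0)
        p, _, _ = _posterior_from_correlations(rho, y, params)
        assert 0.0 <= p <= 1.0
        assert min(pi0, y.min()) - 1e-12 <= p <= max(pi0, y.max()) + 1e-12

    def test_label_flip_zero_to_one_never_decreases_p(self):
        rng = np.random.default_rng(9)
        rho = rng.uniform(-1, 1, 8)
        y = np.array([0, 1, 0, 0, 1, 0, 1, 0])
        params = PredictorParams()
        p0, _, w = _posterior_from_correlations(rho, y, params)
        for i in np.where((y == 0) & (w > 0))[0]:
            y2 = y.copy()
            y2[i] = 1
            p1, _, _ = _posterior_from_correlations(rho, y2, params)
            assert p1 >= p0

    def test_prior_dominates_as_strength_grows(self):
        rho = np.array([0.9, 0.8])
        y = np.array([1, 1])
        ps = [
            _posterior_from_correlations(
                rho, y, PredictorParams(prior_strength=s, baseline_prevalence=0.23)
            )[0]
            for s in (0, 1, 10, 1e6)
        ]
        assert ps[0] == 1.0
        assert abs(ps[-1] - 0.23) < 1e-5
        assert all(a >= b for a, b in zip(ps, ps[1:]))  # monotone toward prior


class TestPosteriorRisk:
    def test_all_negative_cohort_gives_zero(self, small_cohort):
        cohort = ReferenceCohort(
            matrix=small_cohort.matrix,
            labels=pd.Series(0, index=small_cohort.matrix.sample_ids),
        )
        res = posterior_risk([1, 2, 3, 4], cohort, PredictorParams(prior_strength=0.0))
        assert res.p == 0.0

    def test_known_rank_correlations_recovered(self, small_cohort):
        # query (1,2,3,4): rho = 1 with R1, 0.6 with R2, -1 with R3, 0.8 with R4
        res = posterior_risk(
            [1, 2, 3, 4], small_cohort, PredictorParams(prior_strength=0.0),
            keep_detail=True,
        )
        rho = res.neighbor_detail["rho"]
        assert rho.loc["R1"] == pytest.approx(1.0)
        assert rho.loc["R2"] == pytest.approx(0.6)
        assert rho.loc["R3"] == pytest.approx(-1.0)
        # labels (1,0,1,0): p = 1 / (1 + 0.6 + 0.8)
        assert res.p == pytest.approx(1 / 2.4)

    def test_scale_invariance_under_monotone_transform(self, small_cohort):
        q = np.array([0.5, 2.0, 3.5, 9.0])
        base = posterior_risk(q, small_cohort).p
        assert posterior_risk(np.exp(q), small_cohort).p == pytest.approx(base)
        assert posterior_risk(3 * q + 7, small_cohort).p == pytest.approx(base)

    def test_length_mismatch_and_constant_query_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="length"):
            posterior_risk([1, 2, 3], small_cohort)
        with pytest.raises(ValueError, match="constant"):
            posterior_risk([2, 2, 2, 2], small_cohort)


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.30, "high"),
            (0.247, "intermediate"),   # closed upper boundary
            (0.2471, "high"),
            (0.227, "intermediate"),   # closed lower boundary
            (0.2269, "low"),
            (0.0, "low"),
            (1.0, "high"),
        ],
    )
    def test_boundaries(self, p, expected):
        assert classify_risk(p) == expected

    @given(st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_every_p_maps_to_exactly_one_class(self, p):
        t = RiskThresholds()
        cls = classify_risk(p, t)
        memberships = [p < t.t_low, t.t_low <= p <= t.t_high, p > t.t_high]
        assert sum(memberships) == 1
        assert ["low", "intermediate", "high"][memberships.index(True)] == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(1.2)
        with pytest.raises(ValueError, match="t_low"):
            RiskThresholds(t_low=0.3, t_high=0.2)


class TestPredictCohort:
    def test_batch_matches_single_sample_path(self, small_cohort):
        queries = matrix_from([[1.0, 3.0, 2.0, 4.0]], sample_ids=["Q1"],
                              probe_ids=small_cohort.matrix.probe_ids)
        batch = predict_cohort(queries, small_cohort)[0]
        single = posterior_risk([1.0, 3.0, 2.0, 4.0], small_cohort)
        assert batch.p == pytest.approx(single.p)
        assert batch.risk_class == classify_risk(single.p)

    def test_probe_order_mismatch_rejected(self, small_cohort):
        queries = matrix_from([[1.0, 3.0, 2.0, 4.0]], sample_ids=["Q1"],
                              probe_ids=["P1", "P0", "P2", "P3"])
        with pytest.raises(ValueError, match="order"):
            predict_cohort(queries, small_cohort)

    def test_leave_one_out_ignores_own_label(self):
        matrix, labels = generate_cohort(SimulationConfig(n_samples=30, seed=5))
        cohort = ReferenceCohort(matrix=matrix, labels=labels)
        flipped = labels.copy()
        sid = matrix.sample_ids[0]
        flipped[sid] = 1 - flipped[sid]
        cohort_flipped = ReferenceCohort(matrix=matrix, labels=flipped)
        p_orig = predict_cohort(matrix, cohort, leave_one_out=True)[0].p
        p_flip = predict_cohort(matrix, cohort_flipped, leave_one_out=True)[0].p
        assert p_orig == pytest.approx(p_flip)

    def test_signal_recovery_beats_null_margin(self):
        """Leave-one-out AUC on an informative 200-sample cohort exceeds
        0.5 by more than 3 null SEs."""
        matrix, labels = generate_cohort(
            SimulationConfig(n_samples=200, effect_size=1.0, seed=17)
        )
        cohort = ReferenceCohort(matrix=matrix, labels=labels)
        res = predict_cohort(matrix, cohort, leave_one_out=True)
        auc = roc_auc([r.p for r in res], labels.to_numpy())
        n1 = int(labels.sum())
        n0 = len(labels) - n1
        se_null = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert auc > 0.5 + 3 * se_null

    def test_results_frame_round_trip(self, small_cohort):
        queries = matrix_from([[1.0, 3.0, 2.0, 4.0], [4.0, 1.0, 3.0, 2.0]],
                              sample_ids=["Q1", "Q2"],
                              probe_ids=small_cohort.matrix.probe_ids)
        frame = results_to_frame(predict_cohort(queries, small_cohort))
        assert list(frame.index) == ["Q1", "Q2"]
        assert set(frame.columns) == {"p", "risk_class", "prior_fallback"}
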