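import logging

import numpy as np
import pandas as pd
import pytest

from xbp1flux.io_formats import SurvivalCohort, ValidationError
from xbp1flux.signatures_survival import (
    km_estimate,
    logrank_test,
    median_split,
    prognostic_stratification,
    quantile_normalize,
    score_correlation,
    signature_score,
    stratified_expression_test,
)


def expr_frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        expr = expr_frame([[1, 1], [5, 5], [2, 2]])
        pd.testing.assert_frame_equal(quantile_normalize(expr), expr)

    def test_idempotent_on_random_matrix(self, rng):
        expr = expr_frame(rng.normal(size=(50, 4)))
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_two_by_two_rank_means(self):
        # columns (1,3) and (2,4): rank means are (1+2)/2 and (3+4)/2, so
        # both columns become (1.5, 3.5) preserving within-column order
        expr = expr_frame([[1, 2], [3, 4]])
        out = quantile_normalize(expr)
        np.testing.assert_allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_columns_share_sorted_values_exactly(self, rng):
        expr = expr_frame(rng.normal(size=(30, 5)))
        out = quantile_normalize(expr).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert (np.sort(out[:, j]) == ref).all()

    def test_ties_get_mean_of_spanned_reference(self):
        # column 0 has a tie at ranks 1-2; reference is (2, 3, 7);
        # tied entries each get mean(2, 3) = 2.5
        expr = expr_frame([[1.0, 3.0], [1.0, 2.0], [9.0, 6.0]])
        out = quantile_normalize(expr)
        ref = np.sort(expr.to_numpy(), axis=0).mean(axis=1)
        np.testing.assert_allclose(out.iloc[:, 0], [ref[:2].mean()] * 2 + [ref[2]])

    def test_single_column_warns_and_returns_copy(self, caplog):
        expr = expr_frame([[1.0], [2.0]])
        with caplog.at_level(logging.WARNING, logger="xbp1flux"):
            out = quantile_normalize(expr)
        pd.testing.assert_frame_equal(out, expr)


class TestSignatureScore:
    def test_single_gene_signature_is_z_score(self, rng):
        expr = expr_frame(rng.normal(size=(3, 10)))
        score = signature_score(expr, ["g1"])
        row = expr.loc["g1"]
        z = (row - row.mean()) / row.std(ddof=1)
        np.testing.assert_allclose(score.to_numpy(), z.to_numpy())

    def test_scores_have_zero_mean(self, rng):
        expr = expr_frame(rng.normal(size=(8, 25)))
        score = signature_score(expr, [f"g{i}" for i in range(8)])
        assert abs(score.mean()) < 1e-10

    def test_gene_order_irrelevant(self, rng):
        expr = expr_frame(rng.normal(size=(5, 12)))
        genes = [f"g{i}" for i in range(5)]
        a = signature_score(expr, genes)
        b = signature_score(expr, genes[::-1])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_row_shift_invariance(self, rng):
        expr = expr_frame(rng.normal(size=(5, 12)))
        shifted = expr.copy()
        shifted.loc["g2"] += 42.0
        a = signature_score(expr, [f"g{i}" for i in range(5)])
        b = signature_score(shifted, [f"g{i}" for i in range(5)])
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_absent_and_zero_variance_genes_handled(self, rng, caplog):
        expr = expr_frame(rng.normal(size=(3, 6)))
        expr.loc["g2"] = 1.0  # zero variance
        with caplog.at_level(logging.WARNING, logger="xbp1flux"):
            score = signature_score(expr, ["g0", "g1", "g2", "missing"])
        assert len(score) == 6
        assert any("absent" in r.message for r in caplog.records)
        with pytest.raises(ValidationError):
            signature_score(expr, ["nope"])


class TestScoreCorrelation:
    def test_affine_relation_gives_unit_r(self, rng):
        a = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        r, _ = score_correlation(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        r_neg, _ = score_correlation(a, -a)
        assert r_neg == pytest.approx(-1.0)

    def test_recovers_known_rho(self):
        rng = np.random.default_rng(99)
        rs = []
        for _ in range(500):
            x = rng.normal(size=200)
            y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=200)
            idx = [f"s{i}" for i in range(200)]
            r, _ = score_correlation(
                pd.Series(x, index=idx), pd.Series(y, index=idx)
            )
            rs.append(r)
        assert np.mean(rs) == pytest.approx(0.6, abs=0.03)

    def test_constant_vector_rejected(self):
        idx = ["s1", "s2", "s3"]
        a = pd.Series([1.0, 2.0, 3.0], index=idx)
        with pytest.raises(ValidationError):
            score_correlation(a, pd.Series([5.0, 5.0, 5.0], index=idx))


class TestStratifiedTest:
    def test_gene_equal_to_score_strongly_separated(self, rng):
        n = 100
        samples = [f"s{i}" for i in range(n)]
        score = pd.Series(rng.normal(size=n), index=samples)
        expr = expr_frame(score.to_numpy()[None, :], genes=["g0"], samples=samples)
        res = stratified_expression_test(expr, score, ["g0"])
        assert res.loc[0, "mean_high"] > res.loc[0, "mean_low"]
        assert res.loc[0, "p_value"] < 1e-10

    def test_constant_gene_degenerate(self, rng):
        samples = [f"s{i}" for i in range(10)]
        score = pd.Series(rng.normal(size=10), index=samples)
        expr = expr_frame(np.ones((1, 10)), genes=["g0"], samples=samples)
        res = stratified_expression_test(expr, score, ["g0"])
        assert res.loc[0, "degenerate"]
        assert res.loc[0, "p_value"] == 1.0

    def test_median_ties_go_low(self):
        score = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        high = median_split(score)
        assert list(high) == [False, False, False, True]

    def test_small_stratum_rejected(self, rng):
        samples = ["s0", "s1", "s2"]
        score = pd.Series([1.0, 2.0, 3.0], index=samples)
        expr = expr_frame(rng.normal(size=(1, 3)), genes=["g0"], samples=samples)
        with pytest.raises(ValidationError):
            stratified_expression_test(expr, score, ["g0"])


class TestKaplanMeier:
    def test_textbook_steps(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        np.testing.assert_allclose(km.survival, [1.0, 1.0, 1.0])

    def test_tie_event_before_censoring(self):
        # times (1, 2, 2, 3, 4), events (1, 1, 0, 1, 0); at t=2 the event
        # uses n=4 at risk and the censored sample leaves afterwards:
        # S = 4/5, 4/5*3/4 = 3/5, then 3/5*1/2 = 3/10 at t=3
        km = km_estimate([1, 2, 2, 3, 4], [1, 1, 0, 1, 0])
        np.testing.assert_allclose(km.survival, [4 / 5, 3 / 5, 3 / 10, 3 / 10])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(1.0, size=40)
        km = km_estimate(times, np.ones(40, dtype=int))
        emp = [(times > t).mean() for t in km.event_times]
        np.testing.assert_allclose(km.survival, emp, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


def brute_force_logrank(times_a, events_a, times_b, events_b):
    """Hand-enumerated hypergeometric expectation/variance at event times."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    num, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariant(self, rng):
        ta, tb = rng.exponential(1, 10), rng.exponential(2, 12)
        ea, eb = np.ones(10, int), np.ones(12, int)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)

    def test_matches_hand_enumerated_statistic(self):
        ta = np.array([1.0, 3.0, 5.0])
        ea = np.array([1, 1, 0])
        tb = np.array([2.0, 4.0, 6.0])
        eb = np.array([1, 0, 1])
        res = logrank_test(ta, ea, tb, eb)
        oracle = brute_force_logrank(ta, ea, tb, eb)
        assert res.chi_square == pytest.approx(oracle, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0], [0], [2.0], [0])


class TestPrognosticStratification:
    def test_score_driven_hazards_detected(self, rng):
        n = 120
        samples = [f"p{i}" for i in range(n)]
        z = rng.normal(size=n)
        expr = expr_frame(
            np.vstack([z + 0.3 * rng.normal(size=n) for _ in range(5)]),
            genes=list("abcde"),
            samples=samples,
        )
        hazard = 0.1 * np.exp(np.log(4.0) * z)
        times = rng.exponential(1 / hazard)
        cohort = SurvivalCohort(
            sample_ids=samples, time=times, event=np.ones(n, int), expression=expr
        )
        km_hi, km_lo, lr, score = prognostic_stratification(cohort, list("abcde"))
        assert lr.p_value < 1e-4
        # high-activity group dies faster: lower survival at median time
        mid = np.median(times)
        s_hi = km_hi.survival[km_hi.event_times <= mid][-1]
        s_lo = km_lo.survival[km_lo.event_times <= mid][-1]
        assert s_hi < s_lo

    def test_five_gene_signature_accepted_verbatim(self, rng):
        from xbp1flux.signatures_survival import FIVE_GENE_SIGNATURE

        assert FIVE_GENE_SIGNATURE == ["ANLN", "CSNK1G3", "RRM2", "SLC35A2", "UBAC2"]
        n = 40
        samples = [f"p{i}" for i in range(n)]
        expr = expr_frame(
            rng.normal(size=(5, n)), genes=FIVE_GENE_SIGNATURE, samples=samples
        )
        cohort = SurvivalCohort(
            sample_ids=samples,
            time=rng.exponential(1, n),
            event=np.ones(n, int),
            expression=expr,
        )
        *_, score = prognostic_stratification(cohort, FIVE_GENE_SIGNATURE)
        assert len(score) == n

    def test_missing_expression_rejected(self):
        cohort = SurvivalCohort(sample_ids=["a", "b"], time=[1, 2], event=[1, 1])
        with pytest.raises(ValidationError):
            prognostic_stratification(cohort, ["g"])
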