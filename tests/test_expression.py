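import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import audic_claverie_p
from saltmir.expression import (CtRecord, ExpressionError, classify,
                                count_pvalue, differential_expression,
                                log2_fold_change, normalize_tpm,
                                relative_quantity)


class TestTpm:
    def test_formula(self):
        assert normalize_tpm(5, 1_000_000) == pytest.approx(5.0)

    def test_zero_count_reported_as_zero(self):
        assert normalize_tpm(0, 10_000) == 0.0

    def test_published_scale_arithmetic(self):
        # 369307 miRNA-matched reads in a 14638300-read clean library
        assert normalize_tpm(369307, 14638300) == pytest.approx(25228.82, abs=0.005)

    def test_zero_library_total_is_error(self):
        with pytest.raises(ExpressionError):
            normalize_tpm(1, 0)


class TestFoldChange:
    def test_basic(self):
        assert log2_fold_change(2.0, 1.0) == pytest.approx(1.0)
        assert log2_fold_change(1.0, 2.0) == pytest.approx(-1.0)

    def test_zero_floor(self):
        assert log2_fold_change(0.0, 10.0) == pytest.approx(math.log2(0.01 / 10.0))

    def test_antisymmetric(self):
        assert log2_fold_change(3.7, 1.2) == pytest.approx(
            -log2_fold_change(1.2, 3.7))


class TestCountPvalue:
    def test_zero_zero_is_one(self):
        assert count_pvalue(0, 0, 10_000, 10_000) == pytest.approx(1.0)

    def test_extreme_counts_tiny_p(self):
        assert count_pvalue(100, 0, 10_000, 10_000) < 1e-20

    @pytest.mark.parametrize("x,y,n1,n2", [
        (0, 0, 1000, 1000), (5, 9, 1000, 2000), (12, 3, 5000, 4000),
        (40, 55, 9999, 12345), (0, 7, 800, 800), (150, 120, 20000, 18000),
    ])
    def test_matches_bruteforce_logspace_sum(self, x, y, n1, n2):
        assert count_pvalue(x, y, n1, n2) == pytest.approx(
            audic_claverie_p(x, y, n1, n2), abs=1e-9)

    @pytest.mark.parametrize("x,f", [(0, 1.0), (3, 2.0), (25, 0.5), (7, 1.7)])
    def test_distribution_normalises(self, x, f):
        """The implementation's log-space pmf sums to 1 over k (to 1e-12)."""
        from scipy.special import logsumexp

        from saltmir.expression import _log_pmf

        n1 = 10_000
        n2 = int(round(f * n1))
        f = n2 / n1
        ks = np.arange(0, 20_000)
        total = math.exp(logsumexp(_log_pmf(ks, x, math.log(f), math.log1p(f))))
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 80), st.integers(0, 80),
           st.integers(100, 50_000), st.integers(100, 50_000))
    def test_exchange_symmetry(self, x, y, n1, n2):
        assert count_pvalue(x, y, n1, n2) == pytest.approx(
            count_pvalue(y, x, n2, n1), rel=1e-9, abs=1e-12)

    def test_nbinom_tail_oracle(self):
        # the predictive distribution is negative binomial: both conditional
        # lower tails are nbinom cdfs
        x, y, n1, n2 = 10, 4, 3000, 4500
        f, g = n2 / n1, n1 / n2
        lower = stats.nbinom(x + 1, 1 / (1 + f)).cdf(y)
        upper = stats.nbinom(y + 1, 1 / (1 + g)).cdf(x)
        expected = min(1.0, 2 * min(lower, upper))
        assert count_pvalue(x, y, n1, n2) == pytest.approx(expected, abs=1e-12)

    def test_p_decreases_away_from_expectation(self):
        n = 10_000
        ps = [count_pvalue(20, y, n, n) for y in (20, 30, 45, 70, 110)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ExpressionError):
            count_pvalue(-1, 0, 100, 100)


class TestClassify:
    @pytest.mark.parametrize("lfc,p,call", [
        (1.0, 0.05, "up"),          # boundaries inclusive
        (-1.0, 0.05, "down"),
        (0.9, 0.001, "neutral"),
        (3.0, 0.06, "neutral"),
        (-2.5, 0.01, "down"),
    ])
    def test_thresholds(self, lfc, p, call):
        assert classify(lfc, p) == call

    def test_directional_consistency(self, rng):
        counts = {}
        for i in range(40):
            c = int(rng.integers(0, 400))
            t = int(rng.integers(0, 400))
            if c + t > 0:
                counts[f"m{i}"] = (c, t)
        records = differential_expression(counts, 50_000, 50_000)
        for r in records:
            if r.call == "up":
                assert r.tpm_treated > r.tpm_control
            elif r.call == "down":
                assert r.tpm_treated < r.tpm_control


class TestComparativeCt:
    def recs(self, ct_t_c, ct_r_c, ct_t_t, ct_r_t):
        return [
            CtRecord("m", "control", 1, ct_t_c, ct_r_c),
            CtRecord("m", "treated", 1, ct_t_t, ct_r_t),
        ]

    def test_all_equal_rq_one(self):
        out = relative_quantity(self.recs(20, 20, 20, 20))
        assert out["m"]["rq"] == pytest.approx(1.0)

    def test_one_cycle_drop_doubles(self):
        out = relative_quantity(self.recs(22, 15, 21, 15))
        assert out["m"]["rq"] == pytest.approx(2.0)

    def test_worked_example(self):
        # ddCt = (20-15) - (22-15) = -2 -> RQ = 4
        out = relative_quantity(self.recs(22, 15, 20, 15))
        assert out["m"]["rq"] == pytest.approx(4.0)

    def test_replicates_averaged_on_ct_scale(self):
        recs = [
            CtRecord("m", "control", 1, 22, 15),
            CtRecord("m", "control", 2, 24, 15),
            CtRecord("m", "treated", 1, 20, 15),
        ]
        out = relative_quantity(recs)
        assert out["m"]["ddct"] == pytest.approx(5 - 8)
        assert out["m"]["sd"] == pytest.approx(1.0)

    def test_missing_sample_is_error(self):
        with pytest.raises(ExpressionError):
            relative_quantity([CtRecord("m", "control", 1, 20, 15)])
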