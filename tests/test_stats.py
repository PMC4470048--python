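"""Agreement statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cardioflow4d.stats import (
    PairedMeasurements,
    agreement_report,
    bland_altman,
    comparison_table,
    correlate,
    wilcoxon_paired,
)


def _pm(x, y):
    x = np.asarray(x, float)
    return PairedMeasurements([f"s{i}" for i in range(len(x))], x, np.asarray(y, float))


def wilcoxon_enumeration_p(d):
    """Brute-force two-tailed exact p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        res = wilcoxon_paired(_pm([2, 4, 6, 8, 10], [1, 2, 3, 4, 5]))
        assert res.p_value == pytest.approx(2 / 32)
        assert res.exact

    def test_identical_data_p_one(self):
        res = wilcoxon_paired(_pm([1, 2, 3], [1, 2, 3]))
        assert res.p_value == 1.0
        assert res.note == "all differences zero"

    def test_swap_symmetry(self, rng):
        x = rng.normal(10, 2, 8)
        y = rng.normal(10, 2, 8)
        a = wilcoxon_paired(_pm(x, y))
        b = wilcoxon_paired(_pm(y, x))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        n = a.n_used
        assert a.statistic + b.statistic == pytest.approx(n * (n + 1) / 2)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(25):
            d = np.round(rng.normal(0, 3, n), 1)
            x = rng.normal(50, 5, n)
            res = wilcoxon_paired(_pm(x + d, x))
            if res.n_used == 0:
                continue
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        ours = wilcoxon_paired(_pm(x, y))
        ref = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0.3, 1, 60)
        ours = wilcoxon_paired(_pm(x, y))
        ref = sps.wilcoxon(x, y, alternative="two-sided", method="approx",
                           correction=False)
        assert not ours.exact
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestBlandAltman:
    def test_constant_offset(self):
        ba = bland_altman(_pm([2, 3, 4], [1, 2, 3]))
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd == pytest.approx(0.0)
        assert ba.loa == (pytest.approx(1.0), pytest.approx(1.0))

    def test_identity(self):
        ba = bland_altman(_pm([1, 2, 3], [1, 2, 3]))
        assert ba.bias == 0.0 and ba.sd == 0.0

    def test_two_pass_oracle(self, rng):
        x = rng.normal(90, 15, 40)
        y = x + rng.normal(-2, 5, 40)
        ba = bland_altman(_pm(x, y))
        d = x - y
        mean = d.sum() / len(d)  # independent two-pass computation
        sd = np.sqrt(((d - mean) ** 2).sum() / (len(d) - 1))
        assert ba.bias == pytest.approx(mean, abs=1e-12)
        assert ba.sd == pytest.approx(sd, abs=1e-12)
        assert ba.loa[1] - ba.bias == pytest.approx(1.96 * ba.sd, abs=1e-12)
        pct = 100.0 * d / ((x + y) / 2.0)
        assert ba.pct_bias == pytest.approx(pct.mean(), abs=1e-12)

    def test_bias_antisymmetric_sd_invariant(self, rng):
        x, y = rng.normal(50, 8, 12), rng.normal(50, 8, 12)
        a, b = bland_altman(_pm(x, y)), bland_altman(_pm(y, x))
        assert a.bias == pytest.approx(-b.bias, abs=1e-12)
        assert a.sd == pytest.approx(b.sd, abs=1e-12)

    def test_zero_denominator_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            ba = bland_altman(_pm([1.0, 2.0, 3.0], [-1.0, 1.0, 2.0]))
        assert ba.n_pct == 2

    def test_second_denominator_option(self):
        ba = bland_altman(_pm([2.0, 4.0, 8.0], [1.0, 2.0, 4.0]),
                          pct_denominator="second")
        assert ba.pct_bias == pytest.approx(100.0)


class TestCorrelation:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c = correlate(_pm(x, 2 * x + 1))
        assert c.r == pytest.approx(1.0)
        assert c.slope == pytest.approx(2.0)
        assert c.intercept == pytest.approx(1.0)
        assert c.r2 == pytest.approx(c.r**2, abs=1e-15)

    def test_r_symmetric_in_arguments(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        assert correlate(_pm(x, y)).r == pytest.approx(correlate(_pm(y, x)).r,
                                                       abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(_pm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_null_p_uniform(self, rng):
        # independent x, y: the regression p value is U(0, 1)
        ps = []
        for _ in range(400):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            ps.append(correlate(_pm(x, y)).p_value)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01


class TestReportLayer:
    def test_agreement_report_invariants(self, rng):
        x = rng.normal(90, 15, 10)
        y = x + rng.normal(0, 5, 10)
        rep = agreement_report(_pm(x, y))
        assert rep.loa[1] - rep.bias == pytest.approx(1.96 * rep.sd, abs=1e-12)
        assert rep.r2 == pytest.approx(rep.r**2, abs=1e-15)
        assert 0.0 <= rep.wilcoxon_p <= 1.0

    def test_comparison_table_shape(self, rng):
        comps = []
        for name in ("4D SV vs 2D SV", "PT inflow vs outflow"):
            x = rng.normal(90, 10, 8)
            comps.append((name, _pm(x, x + rng.normal(1, 3, 8))))
        df = comparison_table(comps)
        assert list(df.comparison) == [c[0] for c in comps]
        assert {"absolute", "percentage", "bias", "sd"} <= set(df.columns)
        assert "±" in df.absolute.iloc[0]


class TestPairedMeasurementsValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            PairedMeasurements(["a", "b"], np.ones(2), np.ones(3))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            PairedMeasurements(["a", "b"], np.ones(2), np.ones(2))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            PairedMeasurements(list("abc"), np.array([1, np.nan, 3.0]), np.ones(3))
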