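"""Poisson-corrected frequencies, selection intensities and group tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from cancereffects.catalog import SIGNATURE_NAMES
from cancereffects.selection import (
    compare_selection_by_context,
    fisher_exact,
    logistic_hpv_on_apobec,
    net_realized,
    net_realized_table,
    observed_frequency,
    selection_intensity,
    selection_table,
    wilcoxon_rank_sum,
)


class TestObservedFrequency:
    @pytest.mark.parametrize(
        "n,N,expected",
        [(0, 100, 0.0), (50, 100, math.log(2)), (1, 10, -math.log(0.9))],
    )
    def test_closed_forms(self, n, N, expected):
        assert observed_frequency(n, N) == pytest.approx(expected)

    def test_saturated_prevalence_is_na(self):
        assert math.isnan(observed_frequency(10, 10))

    @given(st.integers(1, 999))
    def test_flux_always_exceeds_prevalence(self, n):
        lam = observed_frequency(n, 1000)
        assert lam > n / 1000

    def test_monte_carlo_inversion(self, rng):
        """Forward-simulate presence/absence at per-tumor flux 0.2 and invert:
        the recovered flux matches within +-0.01 at N=1e5."""
        N = 100_000
        carriers = int((rng.random(N) < 1 - math.exp(-0.2)).sum())
        assert observed_frequency(carriers, N) == pytest.approx(0.2, abs=0.01)


class TestSelectionIntensity:
    def test_neutral_and_scaled(self):
        assert selection_intensity(1e-3, 1e-3) == pytest.approx(1.0)
        assert selection_intensity(2e-5, 1e-7) == pytest.approx(200.0)

    def test_zero_mu_raises(self):
        with pytest.raises(ValueError):
            selection_intensity(0.1, 0.0)

    def test_ranking_invariant_to_global_rescaling(self, rng):
        lam = rng.uniform(1e-4, 1e-2, 20)
        mu = rng.uniform(1e-6, 1e-4, 20)
        g1 = lam / mu
        g2 = (lam * 7.3) / (mu * 7.3)
        assert (np.argsort(g1) == np.argsort(g2)).all()


class TestNetRealized:
    @pytest.mark.parametrize(
        "p0,p1,alpha,gamma,expected",
        [
            (0.1, 0.1, 1.0, 100.0, 10.0),  # matched strata collapse to alpha*gamma*p
            (0.1, 0.0, 0.3, 50.0, 0.1 * 0.3 * 50.0),  # single-stratum reduction
            (0.2, 0.05, 0.5, 40.0, 3.4),  # (0.2*4 + 0.05*1) / 0.25
        ],
    )
    def test_printed_formula(self, p0, p1, alpha, gamma, expected):
        assert net_realized(p0, p1, alpha, gamma) == pytest.approx(expected)

    def test_not_recurrent_anywhere_is_na(self):
        assert math.isnan(net_realized(0.0, 0.0, 0.5, 10.0))

    @given(
        st.floats(0.001, 0.5), st.floats(0.001, 0.5),
        st.floats(0.01, 1.0), st.floats(0.0, 1000.0),
    )
    def test_monotone_in_attribution_intensity_and_joint_prevalence(
        self, p0, p1, alpha, gamma
    ):
        """Monotone in alpha, gamma, and under a joint scaling of both
        prevalences. Note the weighted-mean form is NOT monotone in a single
        stratum's prevalence: raising the smaller stratum's p shifts weight
        toward the smaller alpha*gamma*p term and can lower the mean."""
        base = net_realized(p0, p1, alpha, gamma)
        assert net_realized(p0, p1, min(alpha * 1.1, 1.0), gamma) >= base - 1e-12
        assert net_realized(p0, p1, alpha, gamma * 1.1) >= base - 1e-12
        assert net_realized(min(p0 * 1.1, 1.0), min(p1 * 1.1, 1.0),
                            alpha, gamma) >= base - 1e-12

    def test_single_stratum_prevalence_not_monotone(self):
        """Counter-example to naive per-stratum monotonicity (the weighted
        mean dips when a negligible stratum gains a little prevalence)."""
        assert (net_realized(0.01, 0.5, 1.0, 10.0)
                < net_realized(0.0, 0.5, 1.0, 10.0))


class TestWelchComparison:
    def test_identical_groups_one_sided_p_half(self):
        g = [1.0, 2.0, 4.0, 8.0]
        res = compare_selection_by_context(g, list(g))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(0.5)

    def test_shifted_alternative_detected(self, rng):
        low = 10 ** rng.normal(1.0, 0.4, 100)
        high = 10 ** rng.normal(1.6, 0.4, 100)
        res = compare_selection_by_context(low, high)
        assert res.pvalue < 0.05

    def test_matches_hand_welch_formula(self):
        a = [12.0, 15.0, 9.0, 20.0, 11.0]
        b = [30.0, 45.0, 28.0, 60.0]
        res = compare_selection_by_context(a, b, log_scale=False)
        xa, xb = np.array(a), np.array(b)
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        t = (xa.mean() - xb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.pvalue == pytest.approx(scipy.stats.t.cdf(t, df))

    def test_log_scale_requires_positive_gamma(self):
        with pytest.raises(ValueError):
            compare_selection_by_context([0.0, 1.0], [1.0, 2.0])


class TestFisherExact:
    def test_diagonal_table_by_enumeration(self):
        # C(10,5)=252 tables; only k=5 and k=0 are as extreme: p = 2/252
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    @pytest.mark.parametrize(
        "table",
        [[[3, 7], [5, 2]], [[12, 4], [3, 9]], [[1, 1], [1, 1]], [[0, 9], [8, 0]]],
    )
    def test_matches_scipy_reference(self, table):
        _, p_ref = scipy.stats.fisher_exact(table, alternative="two-sided")
        assert fisher_exact(table) == pytest.approx(p_ref, rel=1e-9)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        stat, p = wilcoxon_rank_sum([3.0, 3.0, 3.0], [3.0, 3.0])
        assert p == 1.0

    def test_tie_corrected_asymptotic(self):
        x = [1, 2, 2, 3, 5]
        y = [2, 4, 4, 6, 8]
        _, p = wilcoxon_rank_sum(x, y)
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert p == pytest.approx(res.pvalue)


class TestLogistic:
    def test_null_effect_slope_near_zero(self, rng):
        x = rng.uniform(0, 1, 400)
        y = rng.random(400) < 0.5  # outcome independent of x
        slope, p, sep = logistic_hpv_on_apobec(x, y)
        assert not sep
        assert abs(slope) < 0.8
        assert p > 0.01

    def test_positive_effect_detected(self, rng):
        x = rng.uniform(0, 1, 500)
        y = rng.random(500) < 1 / (1 + np.exp(-(x * 6 - 3)))
        slope, p, sep = logistic_hpv_on_apobec(x, y)
        assert not sep and slope > 2 and p < 1e-6

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x > 0.5
        slope, p, sep = logistic_hpv_on_apobec(x, y)
        assert sep and slope is None and p is None


class TestSelectionTable:
    def _tally(self):
        return pd.DataFrame(
            {
                "chrom": ["g1", "g1"], "pos": [10, 20], "ref": ["C", "C"],
                "alt": ["T", "A"], "gene": ["g1", "g1"],
                "aa_change": ["A1V", "A2D"], "consequence": ["missense"] * 2,
                "trinuc_ref": ["ACG", "ACA"],
                "n_negative": [4, 1], "n_positive": [2, 0], "n_unknown": [0, 0],
                "n_total": [6, 1], "recurrent": [True, False],
            }
        )

    def _mu(self):
        return pd.DataFrame(
            {"chrom": ["g1", "g1"], "pos": [10, 20], "ref": ["C", "C"],
             "alt": ["T", "A"], "mu": [1e-3, 2e-3]}
        )

    def test_per_stratum_quantities(self):
        out = selection_table(self._tally(), {"negative": 100, "positive": 50},
                              self._mu())
        v = out[out["pos"] == 10].iloc[0]
        assert v["p_negative"] == pytest.approx(0.04)
        assert v["lambda_negative"] == pytest.approx(-math.log(0.96))
        assert v["gamma_negative"] == pytest.approx(-math.log(0.96) / 1e-3)
        assert v["recurrent_negative"] and v["recurrent_positive"]
        assert v["n_pooled"] == 6 and v["N_pooled"] == 150
        single = out[out["pos"] == 20].iloc[0]
        assert not single["recurrent_pooled"]

    def test_saturated_stratum_flagged_na(self):
        tally = self._tally()
        tally.loc[0, "n_negative"] = 100
        tally.loc[0, "n_total"] = 102
        out = selection_table(tally, {"negative": 100, "positive": 50}, self._mu())
        assert math.isnan(out[out["pos"] == 10]["gamma_negative"].iloc[0])

    def test_empty_tally_gives_empty_table(self):
        empty = self._tally().iloc[0:0]
        out = selection_table(empty, {"negative": 10, "positive": 5}, self._mu())
        assert len(out) == 0


class TestNetRealizedTable:
    def test_signature_groups_sum_to_total(self, rng):
        sel = pd.DataFrame(
            {
                "chrom": ["g1"], "pos": [10], "ref": ["C"], "alt": ["T"],
                "gene": ["g1"], "aa_change": ["A1V"],
                "gamma_pooled": [120.0], "p_negative": [0.04], "p_positive": [0.08],
                "recurrent_pooled": [True],
            }
        )
        alpha = rng.dirichlet(np.ones(len(SIGNATURE_NAMES)))
        out = net_realized_table(sel, {("g1", 10, "C", "T"): alpha})
        row = out.iloc[0]
        group_sum = sum(row[g] for g in
                        ["Signature.1", "Signature.2", "Signature.13",
                         "Signature.4", "Signature.16", "other"])
        assert group_sum == pytest.approx(row["total"], abs=1e-9)
        # total equals the net-realized value at alpha=1
        expected = net_realized(0.04, 0.08, 1.0, 120.0)
        assert row["total"] == pytest.approx(expected, abs=1e-9)
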