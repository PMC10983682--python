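"""Agreement and association statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spictminer import (
    ConfusionMatrix2x2,
    SeparationError,
    TwoByTwo,
    agreement,
    cohens_kappa,
    fisher_exact_p,
    interpret_kappa,
    logistic_association,
    odds_ratio,
    percent_agreement,
    prevalence_per_100,
)

counts = st.integers(min_value=0, max_value=200)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left cell = x) under the hypergeometric
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestKappa:
    def test_perfect_agreement(self):
        k, _, _ = cohens_kappa(ConfusionMatrix2x2(50, 0, 0, 50))
        assert k == pytest.approx(1.0)

    def test_chance_level(self):
        k, _, _ = cohens_kappa(ConfusionMatrix2x2(25, 25, 25, 25))
        assert k == pytest.approx(0.0)

    def test_formula_oracle(self):
        # po = 0.85, pe = 0.50 -> kappa = 0.70
        k, se, ci = cohens_kappa(ConfusionMatrix2x2(40, 10, 5, 45))
        assert k == pytest.approx(0.70)
        assert se == pytest.approx(math.sqrt(0.85 * 0.15 / (100 * 0.25)))
        assert ci[0] <= k <= ci[1]

    def test_undefined_when_expected_agreement_one(self):
        with pytest.raises(ValueError):
            cohens_kappa(ConfusionMatrix2x2(10, 0, 0, 0))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            r1 = rng.integers(0, 2, size=60)
            r2 = rng.integers(0, 2, size=60)
            cm = ConfusionMatrix2x2.from_labels(r1 == 1, r2 == 1)
            try:
                k, _, _ = cohens_kappa(cm)
            except ValueError:
                continue
            assert k == pytest.approx(cohen_kappa_score(r1, r2), abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(a=counts, b=counts, c=counts, d=counts,
           scale=st.integers(min_value=2, max_value=5))
    def test_invariances(self, a, b, c, d, scale):
        """Symmetry under transpose and label swap; scale invariance."""
        cm = ConfusionMatrix2x2(a, b, c, d)
        if cm.n == 0:
            return
        try:
            k, se, _ = cohens_kappa(cm)
        except ValueError:
            return
        kt, _, _ = cohens_kappa(ConfusionMatrix2x2(a, c, b, d))  # rater exchange
        ks, _, _ = cohens_kappa(ConfusionMatrix2x2(d, c, b, a))  # label swap
        assert k == pytest.approx(kt, abs=1e-12)
        assert k == pytest.approx(ks, abs=1e-12)
        kb, seb, _ = cohens_kappa(ConfusionMatrix2x2(a * scale, b * scale,
                                                     c * scale, d * scale))
        assert kb == pytest.approx(k, abs=1e-12)
        assert seb == pytest.approx(se / math.sqrt(scale), rel=1e-9)
        assert percent_agreement(cm) == pytest.approx(
            percent_agreement(ConfusionMatrix2x2(a * scale, b * scale,
                                                 c * scale, d * scale)))

    def test_kappa_one_iff_no_disagreement(self):
        assert cohens_kappa(ConfusionMatrix2x2(3, 0, 0, 7))[0] == pytest.approx(1.0)
        assert cohens_kappa(ConfusionMatrix2x2(3, 1, 0, 7))[0] < 1.0


class TestBandsAndPercent:
    @pytest.mark.parametrize("k,band", [
        (0.83, "good"), (0.71, "good"), (0.70, "moderate"),
        (0.55, "moderate"), (0.40, "moderate"), (0.39, "poor"),
        (0.16, "poor"), (-0.5, "poor"),
    ])
    def test_interpretation_bands(self, k, band):
        assert interpret_kappa(k) == band

    def test_percent_agreement_bounds(self):
        assert percent_agreement(ConfusionMatrix2x2(95, 3, 2, 0)) == 95.0
        assert percent_agreement(ConfusionMatrix2x2(10, 0, 0, 0)) == 100.0
        assert percent_agreement(ConfusionMatrix2x2(0, 5, 5, 0)) == 0.0

    def test_agreement_result_composition(self):
        res = agreement(ConfusionMatrix2x2(40, 10, 5, 45))
        assert res.percent_agreement == 85.0
        assert res.band == "moderate"
        d = res.to_json_dict()
        assert d["n"] == 100 and d["confusion_matrix"]["a"] == 40


class TestPrevalence:
    @pytest.mark.parametrize("met,total,expected", [
        (1593, 14363, 11.1),
        (3282, 14363, 22.9),
        (0, 100, 0.0),
        (1, 800, 0.1),   # 0.125 rounds half-up to 0.1
        (1, 400, 0.3),   # 0.25 rounds half-up (not banker's) to 0.3
    ])
    def test_per_100_half_up(self, met, total, expected):
        assert prevalence_per_100(met, total) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            prevalence_per_100(5, 0)
        with pytest.raises(ValueError):
            prevalence_per_100(11, 10)


class TestOddsRatio:
    def test_null_association(self):
        r = odds_ratio(TwoByTwo(20, 20, 20, 20))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci95[0] < 1.0 < r.ci95[1]

    def test_cross_product_on_printed_counts(self):
        r = odds_ratio(TwoByTwo(9964, 964, 1663, 629))
        assert r.odds_ratio == pytest.approx(9964 * 629 / (964 * 1663))
        assert r.odds_ratio == pytest.approx(3.91, abs=0.005)
        assert not r.corrected

    def test_zero_cell_haldane_correction(self):
        r = odds_ratio(TwoByTwo(10, 0, 5, 5))
        assert r.corrected
        assert r.odds_ratio == pytest.approx(10.5 * 5.5 / (0.5 * 5.5))


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_p(TwoByTwo(7, 3, 7, 3)) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_p(TwoByTwo(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            p = fisher_exact_p(TwoByTwo(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
            assert 0 < p <= 1
            checked += 1


class TestLogistic:
    def test_single_binary_covariate_equals_cross_product(self):
        x = np.array([1] * 50 + [0] * 50)
        y = np.array([1] * 40 + [0] * 10 + [1] * 20 + [0] * 30)
        res = logistic_association(y, pd.DataFrame({"x": x}))
        assert res.loc["x", "or_"] == pytest.approx(6.0, rel=1e-6)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=2000)
        y = rng.random(2000) < 0.3
        res = logistic_association(y.astype(int), pd.DataFrame({"x": x}))
        assert res.loc["x", "ci_lo"] < 1.0 < res.loc["x", "ci_hi"]

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.integers(0, 2, size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.0 * x)))
        y = (rng.random(n) < p).astype(int)
        res = logistic_association(y, pd.DataFrame({"x": x}))
        assert abs(math.log(res.loc["x", "or_"]) - 1.0) < 0.15

    def test_perfect_separation_raises(self):
        x = np.array([0] * 20 + [1] * 20)
        with pytest.raises(SeparationError):
            logistic_association(x, pd.DataFrame({"x": x}))

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError):
            logistic_association([0, 1, 2], pd.DataFrame({"x": [1, 2, 3]}))
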