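import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reopair import (
    ExpressionMatrix,
    SurvivalTable,
    bh_fdr,
    binomial_consistency_test,
    cox_multivariate,
    cox_univariate,
    deg_concordance,
    harrell_c,
    km_curve,
    km_logrank,
    spearman_test,
)


def _sim_surv(rng, x, hr, baseline=0.02, censor_frac=0.3):
    hazard = baseline * hr ** np.asarray(x, dtype=float)
    t_event = rng.exponential(1.0 / hazard)
    tmax = np.quantile(t_event, 1 - censor_frac) * 2
    c = rng.uniform(0, tmax, len(x))
    time = np.maximum(np.minimum(t_event, c), 1e-9)
    event = (t_event <= c).astype(int)
    return SurvivalTable([f"s{i}" for i in range(len(x))], time, event)


class TestCoxUnivariate:
    def test_hand_derived_three_subjects(self):
        surv = SurvivalTable(["a", "b", "c"], [1, 2, 3], [1, 1, 0])
        res = cox_univariate([1, 0, 1], surv)
        assert res.coef == pytest.approx(-math.log(2) / 2, abs=1e-6)
        assert res.hr == pytest.approx(1 / math.sqrt(2), abs=1e-6)

    def test_constant_covariate(self, toy_surv):
        with pytest.raises(ValueError, match="constant covariate"):
            cox_univariate([1.0] * 6, toy_surv)

    def test_zero_events(self):
        surv = SurvivalTable(["a", "b", "c"], [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_univariate([1, 0, 1], surv)

    def test_recovers_planted_hr_2(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 2, 2000)
        surv = _sim_surv(rng, x, hr=2.0)
        res = cox_univariate(x.astype(float), surv)
        assert 1.8 <= res.hr <= 2.2

    def test_sign_flip_inverts_hr(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 100).astype(float)
        surv = _sim_surv(rng, x, hr=3.0)
        r1 = cox_univariate(x, surv)
        r2 = cox_univariate(1.0 - x, surv)
        assert r1.coef == pytest.approx(-r2.coef, abs=1e-8)
        assert r1.hr == pytest.approx(1.0 / r2.hr, rel=1e-8)

    def test_agrees_with_lifelines(self):
        # independent implementation cross-check, with tied event times
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        surv = _sim_surv(rng, x, hr=1.8)
        surv.time = np.round(surv.time, 0) + 1.0  # force ties
        res = cox_univariate(x, surv)
        df = pd.DataFrame({"T": surv.time, "E": surv.event, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)


class TestCoxMultivariate:
    def test_single_column_matches_univariate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        surv = _sim_surv(rng, x, hr=2.0)
        uni = cox_univariate(x, surv)
        multi = cox_multivariate(pd.DataFrame({"x": x}), surv)[0]
        assert multi.coef == pytest.approx(uni.coef, abs=1e-8)
        assert multi.p_wald == pytest.approx(uni.p_wald, abs=1e-8)

    def test_duplicated_column_rank_deficient(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        surv = _sim_surv(rng, x, hr=2.0)
        with pytest.raises(ValueError, match="rank"):
            cox_multivariate(pd.DataFrame({"x": x, "y": x}), surv)

    def test_two_planted_effects(self):
        rng = np.random.default_rng(21)
        x1 = rng.integers(0, 2, 600).astype(float)
        x2 = rng.integers(0, 2, 600).astype(float)
        hazard = 0.02 * 3.0**x1  # x2 is null
        t_event = rng.exponential(1.0 / hazard)
        c = rng.uniform(0, np.quantile(t_event, 0.7) * 2, 600)
        surv = SurvivalTable(
            [f"s{i}" for i in range(600)],
            np.maximum(np.minimum(t_event, c), 1e-9),
            (t_event <= c).astype(int),
        )
        r1, r2 = cox_multivariate(pd.DataFrame({"x1": x1, "x2": x2}), surv)
        assert r1.ci_low > 1.0
        assert r2.ci_low < 1.0 < r2.ci_high

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        surv = _sim_surv(rng, x, hr=2.0)
        X = pd.DataFrame({"x": x})
        X.loc[:4, "x"] = np.nan
        with pytest.warns(UserWarning, match="dropping 5"):
            res = cox_multivariate(X, surv)[0]
        assert res.n == 45


class TestKmLogrank:
    def test_identical_groups(self):
        time = [1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        event = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]
        surv = SurvivalTable([f"s{i}" for i in range(10)], time, event)
        res = km_logrank(["a"] * 5 + ["b"] * 5, surv)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_planted_separation(self):
        rng = np.random.default_rng(3)
        x = np.array([0] * 150 + [1] * 150)
        surv = _sim_surv(rng, x, hr=4.0)
        res = km_logrank(x, surv)
        assert res["p"] < 0.001

    def test_single_group_errors(self, toy_surv):
        with pytest.raises(ValueError):
            km_logrank(["a"] * 6, toy_surv)

    def test_km_curve_is_product_limit(self):
        surv = SurvivalTable(["a", "b", "c", "d"], [1, 2, 2, 4], [1, 1, 0, 1])
        km = km_curve(surv.time, surv.event)
        # t=1: 3/4; t=2: one death of 3 at risk -> 3/4 * 2/3 = 1/2; t=4: 0
        assert km["survival"].tolist() == pytest.approx([0.75, 0.5, 0.0])
        assert km["at_risk"].tolist() == [4, 3, 1]


class TestHarrellC:
    def test_perfect(self):
        surv = SurvivalTable(["a", "b", "c"], [1, 2, 3], [1, 1, 1])
        assert harrell_c([3, 2, 1], surv).c == 1.0

    def test_worked_example(self):
        surv = SurvivalTable(["a", "b", "c", "d"], [2, 1, 4, 3], [1, 0, 1, 1])
        res = harrell_c([5, 5, 2, 1], surv)
        assert res.n_usable == 3
        assert res.n_concordant == 2
        assert res.c == pytest.approx(2 / 3)

    def test_all_tied_scores(self, toy_surv):
        assert harrell_c([1.0] * 6, toy_surv).c == 0.5

    def test_no_usable_pairs(self):
        surv = SurvivalTable(["a", "b"], [5, 5], [0, 0])
        with pytest.raises(ValueError):
            harrell_c([1, 2], surv)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        time = rng.integers(1, 15, n).astype(float)
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            event[0] = 1
        score = rng.integers(0, 5, n).astype(float)
        surv = SurvivalTable([f"s{i}" for i in range(n)], time, event)
        conc = tied = usable = 0
        for i in range(n):
            for j in range(n):
                if time[i] < time[j] and event[i] == 1:
                    usable += 1
                    if score[i] > score[j]:
                        conc += 1
                    elif score[i] == score[j]:
                        tied += 1
        res = harrell_c(score, surv)
        assert (res.n_usable, res.n_concordant, res.n_tied) == (usable, conc, tied)

    def test_monotone_transform_invariance(self, toy_surv, rng):
        score = rng.normal(size=6)
        c1 = harrell_c(score, toy_surv).c
        c2 = harrell_c(np.exp(3 * score) + 7, toy_surv).c
        assert c1 == c2


class TestBhFdr:
    def test_hand_derived(self):
        q = bh_fdr([0.002, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.008, 0.02, 0.04, 0.04])

    def test_single(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_permutation_equivariant(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_fdr(p[perm]), q[perm])


class TestSpearman:
    def test_linear(self):
        assert spearman_test([1, 2, 3, 4], [2, 4, 6, 8])["rho"] == pytest.approx(1.0)

    def test_antilinear(self):
        assert spearman_test([1, 2, 3, 4], [-1, -2, -3, -4])["rho"] == pytest.approx(-1.0)

    def test_derived_minus_half(self):
        res = spearman_test([1, 2, 3], [3, 1, 2])
        assert res["rho"] == pytest.approx(-0.5)
        assert 0.0 <= res["p"] <= 1.0

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman_test([1, 1, 1], [1, 2, 3])

    def test_large_n_t_approx(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.3, size=50)
        res = spearman_test(x, y)
        assert res["rho"] > 0.8 and res["p"] < 1e-6


class TestDegConcordance:
    def _matrix_with_degs(self, seed, n_genes=60, n_deg=20, shift=3.0):
        rng = np.random.default_rng(seed)
        n1, n2 = 15, 15
        vals = rng.normal(8, 1, (n_genes, n1 + n2))
        vals[:n_deg, n1:] += shift  # first genes up-regulated in group 2
        genes = [f"g{i}" for i in range(n_genes)]
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(n1 + n2)], vals)
        labels = np.array([0] * n1 + [1] * n2)
        return m, labels

    def test_identical_cohorts(self):
        m, labels = self._matrix_with_degs(1)
        res = deg_concordance(m, labels, m, labels)
        assert res["shared"] > 0
        assert res["same_direction"] == res["shared"]
        assert res["p"] == pytest.approx(
            binomial_consistency_test(res["shared"], res["shared"])
        )

    def test_independent_cohorts_share_direction(self):
        m1, l1 = self._matrix_with_degs(1)
        m2, l2 = self._matrix_with_degs(2)
        res = deg_concordance(m1, l1, m2, l2)
        assert res["shared"] >= 15
        assert res["same_direction"] == res["shared"]

    def test_no_degs(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(8, 1, (30, 20))
        m = ExpressionMatrix([f"g{i}" for i in range(30)], [f"s{j}" for j in range(20)], vals)
        labels = np.array([0] * 10 + [1] * 10)
        res = deg_concordance(m, labels, m, labels, fdr=1e-12)
        assert res["shared"] == 0 and res["p"] == 1.0

    def test_small_group_errors(self):
        m, labels = self._matrix_with_degs(1)
        bad = labels.copy()
        bad[:] = 0
        bad[0] = 1
        with pytest.raises(ValueError):
            deg_concordance(m, bad, m, labels)
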