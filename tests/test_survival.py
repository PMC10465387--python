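import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import minimize_scalar

from trimod.io import ExpressionMatrix
from trimod.survival import (CoxData, cox_univariate, km_estimate,
                             logrank_test, prognostic_filter)


def naive_cox_loglik(beta, x, times, events):
    """Independent O(n²) Efron partial log-likelihood (explicit loops)."""
    ll = 0.0
    for u in np.unique(times[events == 1]):
        deaths = np.flatnonzero((times == u) & (events == 1))
        risk = np.flatnonzero(times >= u)
        d = len(deaths)
        wd = np.exp(beta * x[deaths])
        wr = np.exp(beta * x[risk])
        ll += beta * x[deaths].sum()
        for l in range(d):
            ll -= np.log(wr.sum() - (l / d) * wd.sum())
    return ll


class TestKaplanMeier:
    def test_four_subjects_closed_form(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve.surv, [0.75, 0.50, 0.25, 0.0])

    def test_all_censored_gives_unit_survival(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert curve.time.size == 0
        assert curve.at(100.0) == 1.0

    def test_tied_example_matches_lifelines(self):
        t = np.array([2.0, 2.0, 3.0, 5.0, 5.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u, s in zip(curve.time, curve.surv):
            assert s == pytest.approx(kmf.predict(u), abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 50)
        curve = km_estimate(t, np.ones(50))
        for u, s in zip(curve.time, curve.surv):
            assert s == pytest.approx((t > u).mean(), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_matches_lifelines_multigroup(self, rng):
        t = rng.exponential(1, 90)
        e = (rng.random(90) < 0.7).astype(int)
        g = rng.choice(list("abc"), 90)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert mine.p == pytest.approx(ref.p_value, abs=1e-12)
        assert mine.df == 2

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(1, 60)
        e = np.ones(60)
        g = rng.random(60) < 0.5
        a = logrank_test(t, e, np.where(g, "x", "y"))
        b = logrank_test(t, e, np.where(g, "y", "x"))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        """Random splits of one homogeneous sample give uniform p-values."""
        from scipy.stats import kstest
        ps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            t = r.exponential(1, 60)
            e = (r.random(60) < 0.8).astype(int)
            g = r.random(60) < 0.5
            ps.append(logrank_test(t, e, g).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_separated_groups_always_significant(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            t = np.concatenate([r.exponential(1.0, 100), r.exponential(4.0, 100)])
            e = np.ones(200)
            g = np.repeat(["hi", "lo"], 100)
            assert logrank_test(t, e, g).p < 0.001

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.p == 1.0

    def test_two_group_equals_cox_score_test_without_ties(self, rng):
        t = rng.exponential(1, 80) * (1 + 1e-12 * np.arange(80))  # tie-free
        e = np.ones(80)
        x = (rng.random(80) < 0.5).astype(float)
        lr = logrank_test(t, e, x)
        data = CoxData(t, e)
        _, grad, hess = data.loglik(0.0, x[data.order])
        assert lr.chi2 == pytest.approx(grad**2 / -hess, abs=1e-6)


class TestCox:
    def test_constant_covariate_short_circuits(self, rng):
        res = cox_univariate(np.ones(20), rng.exponential(1, 20), np.ones(20))
        assert res.beta == 0.0 and res.p == 1.0 and res.flag == "constant"

    def test_matches_grid_search_maximizer(self, rng):
        """Newton solution agrees with an independent numeric maximizer of a
        naively coded partial likelihood on tie-free two-group data."""
        t = rng.exponential(1, 60) + rng.random(60) * 1e-6
        e = (rng.random(60) < 0.8).astype(int)
        x = (rng.random(60) < 0.5).astype(float)
        res = cox_univariate(x, t, e)
        opt = minimize_scalar(lambda b: -naive_cox_loglik(b, x, t, e),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-6)
        assert res.converged

    def test_matches_lifelines_with_ties(self, rng):
        x = rng.normal(size=120)
        t = np.ceil(rng.exponential(np.exp(-0.7 * x)) * 20) / 20 + 1e-3
        e = (rng.random(120) < 0.7).astype(int)
        res = cox_univariate(x, t, e)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_loglik_increases_monotonically(self, rng):
        x = rng.normal(size=100)
        t = rng.exponential(np.exp(-x))
        e = np.ones(100)
        res = cox_univariate(x, t, e)
        trace = res.loglik_trace
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_separation_flagged_and_capped(self):
        # perfect separation: all events in one covariate group, before any other
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_univariate(x, t, e)
        assert not res.converged or res.flag == "separation"
        assert abs(res.beta) <= 50.0

    def test_recovers_planted_effect(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=300)
            t = r.exponential(np.exp(-0.8 * x))
            e = np.ones(300)
            res = cox_univariate(x, t, e)
            hits += abs(res.beta - 0.8) <= 3 * res.se
        assert hits >= 9


class TestPrognosticFilter:
    def _inputs(self, rng, n=80, genes=20):
        vals = rng.normal(5, 1, (genes, n))
        names = [f"g{i:02d}" for i in range(genes)]
        x = ExpressionMatrix(pd.DataFrame(vals, index=names,
                                          columns=[f"s{j}" for j in range(n)]), "LOG2")
        clin = pd.DataFrame({"sample_id": x.sample_ids,
                             "os_time": rng.exponential(1, n),
                             "os_event": np.ones(n, dtype=int)})
        return x, clin, names

    def test_threshold_one_is_identity(self, rng):
        x, clin, names = self._inputs(rng)
        passing, table = prognostic_filter(x, clin, names, p_threshold=1.0)
        assert passing == names
        assert len(table) == len(names)

    def test_null_pass_fraction_near_alpha(self):
        rng = np.random.default_rng(3)
        x, clin, names = self._inputs(rng, n=100, genes=200)
        passing, _ = prognostic_filter(x, clin, names, p_threshold=0.05)
        frac = len(passing) / len(names)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_empty_candidates_rejected(self, rng):
        x, clin, _ = self._inputs(rng)
        with pytest.raises(ValueError):
            prognostic_filter(x, clin, ["not_there"])

    def test_planted_prognostic_genes_recovered(self, small_cohort, small_log2):
        _, clinical, _, truth = small_cohort
        passing, _ = prognostic_filter(small_log2, clinical, truth.prognostic_gene_ids,
                                       p_threshold=0.05)
        assert len(passing) >= 0.9 * len(truth.prognostic_gene_ids)
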