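import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trimod.downstream import (compare_groups, compute_tmb, ddct_fold_change,
                               mutation_summary, ora_hypergeometric,
                               score_immune_correlation, stratified_km)
from trimod.io import GeneSetCollection
from trimod.ssgsea import EnrichmentResult
from trimod.survival import logrank_test


def _mutations(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"])


class TestTmb:
    def test_counting_with_class_filter(self):
        m = _mutations([("s1", "APC", "missense_mutation"),
                        ("s1", "TP53", "nonsense_mutation"),
                        ("s1", "TTN", "splice_site"),
                        ("s2", "APC", "missense_mutation")])
        prof = compute_tmb(m, ["s1", "s2", "s3"],
                           class_filter=["missense_mutation", "nonsense_mutation"])
        assert prof.table.loc["s1", "tmb"] == 2
        assert prof.table.loc["s2", "tmb"] == 1
        assert prof.table.loc["s3", "tmb"] == 0
        assert bool(prof.table.loc["s3", "absent"])

    def test_per_mb_normalisation(self):
        m = _mutations([("s1", "APC", "missense_mutation")] * 1)
        prof = compute_tmb(m, ["s1", "s2", "s3", "s4"], per_mb=0.5)
        assert prof.table.loc["s1", "tmb"] == 2.0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(_mutations([]), [])

    def test_score_dependent_enrichment_detected(self):
        """High-score samples get enriched mutation probability in the
        generator; the TMB comparison between groups picks it up."""
        from trimod import simulate
        cfg = simulate.SimConfig(n_samples=400, n_background_genes=20,
                                 n_prognostic_genes=10, seed=9)
        _, _, _, truth = simulate.generate_cohort(cfg)
        m = simulate.generate_mutations(cfg, truth)
        samples = truth.true_score.index
        groups = pd.Series(np.where(truth.true_score <= truth.true_score.median(),
                                    "low", "high"), index=samples)
        prof = compute_tmb(m, list(samples))
        cmp = compare_groups(prof.table["tmb"], groups.loc[prof.table.index])
        assert cmp.p < 0.05
        assert prof.table.groupby(groups)["tmb"].median()["high"] > \
            prof.table.groupby(groups)["tmb"].median()["low"]


class TestMutationSummary:
    def test_toy_rate(self):
        m = _mutations([("s1", "APC", "missense_mutation"),
                        ("s2", "APC", "missense_mutation"),
                        ("s3", "TP53", "nonsense_mutation")])
        groups = pd.Series({"s1": "g", "s2": "g", "s3": "g", "s4": "g"})
        out = mutation_summary(m, groups)
        assert out["rates"]["mutation_rate"].iloc[0] == 0.75

    def test_all_mutated_rate_one(self):
        m = _mutations([(f"s{i}", "APC", "missense_mutation") for i in range(4)])
        groups = pd.Series({f"s{i}": ("a" if i < 2 else "b") for i in range(4)})
        out = mutation_summary(m, groups)
        assert (out["rates"]["mutation_rate"] == 1.0).all()

    def test_frequency_ranking_recovers_planted_order(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = []
            for gene, f in (("APC", 0.7), ("TP53", 0.5), ("TTN", 0.4)):
                for i in np.flatnonzero(rng.random(400) < f):
                    rows.append((f"s{i}", gene, "missense_mutation"))
            groups = pd.Series({f"s{i}": "all" for i in range(400)})
            out = mutation_summary(_mutations(rows), groups)
            ranked = out["gene_frequency"].sort_values("rank")["gene"].tolist()
            hits += ranked == ["APC", "TP53", "TTN"]
        assert hits >= 9


class TestStratifiedKm:
    def _clin(self, rng, n, lam):
        return pd.DataFrame({"sample_id": [f"s{j}" for j in range(n)],
                             "os_time": rng.exponential(1 / lam),
                             "os_event": np.ones(n, dtype=int)})

    def test_collapsing_identical_strata_matches_two_group_logrank(self, rng):
        n = 80
        risk = np.repeat([0.0, 1.0], n // 2)
        clin = self._clin(rng, n, 0.01 * np.exp(1.2 * risk))
        a = pd.Series(np.where(risk > 0, "high", "low"), index=clin["sample_id"])
        b = pd.Series(np.where(risk > 0, "high", "low"), index=clin["sample_id"])
        curves, res = stratified_km(clin, a, b)
        assert len(curves) == 2  # identical factors leave 2 non-empty strata
        two = logrank_test(clin["os_time"], clin["os_event"], a.to_numpy())
        assert res.chi2 == pytest.approx(two.chi2, abs=1e-9)

    def test_score_dominates_when_tmb_is_noise(self, rng):
        n = 200
        risk = rng.random(n) < 0.5
        clin = self._clin(rng, n, 0.01 * np.exp(1.5 * risk))
        score = pd.Series(np.where(risk, "high", "low"), index=clin["sample_id"])
        tmb = pd.Series(rng.choice(["high", "low"], n), index=clin["sample_id"])
        curves, res = stratified_km(clin, tmb, score)
        assert res.p < 0.001
        lo = [c for name, c in curves.items() if name.endswith("/low")]
        hi = [c for name, c in curves.items() if name.endswith("/high")]
        horizon = np.median(clin["os_time"])
        assert min(c.at(horizon) for c in lo) > max(c.at(horizon) for c in hi)

    def test_nonbinary_factor_rejected(self, rng):
        clin = self._clin(rng, 30, 0.01)
        a = pd.Series(["x"] * 30, index=clin["sample_id"])
        b = pd.Series(["p", "q", "r"] * 10, index=clin["sample_id"])
        with pytest.raises(ValueError, match="binary"):
            stratified_km(clin, a, b)


class TestCompareGroups:
    def test_extreme_shift_two_groups(self):
        cmp = compare_groups([1, 2, 3, 101, 102, 103],
                             ["a", "a", "a", "b", "b", "b"])
        assert cmp.test == "wilcoxon"
        # exact enumeration: most extreme of C(6,3)=20 orderings, two-sided
        assert cmp.p == pytest.approx(0.1, abs=1e-12)
        assert cmp.p == pytest.approx(stats.mannwhitneyu(
            [1, 2, 3], [101, 102, 103], method="exact").pvalue)

    def test_kruskal_identical_groups_zero_statistic(self):
        cmp = compare_groups([5.0] * 9, ["a", "b", "c"] * 3)
        assert cmp.test == "kruskal" and cmp.statistic == 0.0 and cmp.p == 1.0

    def test_chi2_contingency_path(self, rng):
        vals = pd.Series(rng.choice(["MSS", "MSI-L", "MSI-H"], 200))
        groups = pd.Series(rng.choice(["high", "low"], 200))
        cmp = compare_groups(vals, groups)
        assert cmp.test == "chi2"
        ref = stats.chi2_contingency(pd.crosstab(vals, groups))[0]
        assert cmp.statistic == pytest.approx(ref)

    def test_null_rank_sum_uniform(self):
        from scipy.stats import kstest
        ps = []
        for seed in range(80):
            r = np.random.default_rng(seed)
            vals = r.normal(size=40)
            groups = np.repeat(["a", "b"], 20)
            ps.append(compare_groups(vals, groups).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestScoreImmuneCorrelation:
    def _enrichment(self, rows, samples):
        return EnrichmentResult(pd.DataFrame(rows, columns=samples), alpha=0.25)

    def test_perfect_correlations(self, rng):
        samples = [f"s{j}" for j in range(12)]
        score = pd.Series(rng.normal(size=12), index=samples)
        enr = self._enrichment([score.to_numpy(), -score.to_numpy()], samples)
        enr.scores.index = ["same", "anti"]
        out = score_immune_correlation(score, enr)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)

    def test_independent_rows_rarely_flagged(self):
        rng = np.random.default_rng(5)
        samples = [f"s{j}" for j in range(50)]
        score = pd.Series(rng.normal(size=50), index=samples)
        rows = {f"set{i}": rng.normal(size=50) for i in range(20)}
        enr = EnrichmentResult(pd.DataFrame(rows, index=samples).T, alpha=0.25)
        out = score_immune_correlation(score, enr)
        assert np.abs(out["rho"]).mean() < 0.25
        assert (out["adj_p"] < 0.05).sum() <= 2

    def test_constant_score_rejected(self):
        samples = ["a", "b", "c", "d", "e"]
        enr = EnrichmentResult(pd.DataFrame([[1, 2, 3, 4, 5.0]], index=["S"],
                                            columns=samples), alpha=0.25)
        with pytest.raises(ValueError, match="constant"):
            score_immune_correlation(pd.Series(1.0, index=samples), enr)


class TestOra:
    def test_matches_closed_form_sum(self):
        # overlap 3 of a 10-gene set, 50 hits, universe 1000
        universe = [f"g{i}" for i in range(1000)]
        hits = set(universe[:50])
        members = set(universe[:3]) | set(universe[500:507])
        out = ora_hypergeometric(hits, GeneSetCollection({"S": members}), universe)
        from math import comb
        expected = sum(comb(10, k) * comb(990, 50 - k) for k in range(3, 11)) / comb(1000, 50)
        assert out.loc["S", "p"] == pytest.approx(expected, rel=1e-12)
        assert out.loc["S", "overlap"] == 3

    def test_full_set_overlap_is_minimal_tail(self):
        universe = [f"g{i}" for i in range(100)]
        hits = set(universe[:10])
        out = ora_hypergeometric(hits, GeneSetCollection({"S": set(universe[:10])}), universe)
        assert out.loc["S", "p"] == pytest.approx(
            float(stats.hypergeom.pmf(10, 100, 10, 10)), rel=1e-9)

    def test_uniform_null(self):
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(500)]
        members = set(rng.choice(universe, 40, replace=False))
        ps = [ora_hypergeometric(set(rng.choice(universe, 50, replace=False)),
                                 GeneSetCollection({"S": members}), universe).loc["S", "p"]
              for _ in range(50)]
        # discrete p-values are super-uniform under the null
        assert np.mean(np.array(ps) < 0.05) <= 0.1

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ora_hypergeometric({"x"}, GeneSetCollection({"S": {"a", "b"}}), {"a", "b"})


class TestDdct:
    @pytest.mark.parametrize("cts,expected", [
        ((20.0, 18.0, 20.0, 18.0), 1.0),    # ΔΔCt = 0
        ((19.0, 18.0, 20.0, 18.0), 2.0),    # ΔΔCt = −1
        ((20.0, 18.0, 22.0, 18.0), 4.0),    # ΔΔCt = −2
    ])
    def test_formula(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)
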