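import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trimod.diffexpr import (DiffExprResult, all_pairwise, fit_f_dist,
                             moderated_pairwise, overlap_degs)
from trimod.io import ExpressionMatrix


def _matrix(vals, genes=None):
    genes = genes or [f"g{i:04d}" for i in range(vals.shape[0])]
    samples = [f"s{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "LOG2")


class TestModeratedT:
    def test_d0_zero_reduces_to_pooled_t(self, rng):
        vals = rng.normal(5, 1, (40, 12))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        res = moderated_pairwise(_matrix(vals), labels, "a", "b", d0_override=0.0)
        for i in range(40):
            t_ref, _ = stats.ttest_ind(vals[i, :6], vals[i, 6:], equal_var=True)
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, abs=1e-10)

    def test_huge_d0_limit_uses_prior_variance_only(self, rng):
        vals = rng.normal(0, 1, (30, 10))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        s0 = 2.0
        res = moderated_pairwise(_matrix(vals), labels, "a", "b",
                                 d0_override=1e12, s0_sq_override=s0)
        diff = vals[:, :5].mean(axis=1) - vals[:, 5:].mean(axis=1)
        expected = diff / np.sqrt((s0 * 1e12 + 8 * res.table["s2"].to_numpy()) / (1e12 + 8)
                                  * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(res.table["t"].to_numpy(), expected, atol=1e-6)

    def test_bh_is_monotone_in_raw_p(self, rng):
        vals = rng.normal(0, 1, (200, 10))
        vals[:10, :5] += 2
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = moderated_pairwise(_matrix(vals), labels, "a", "b")
        tab = res.table.sort_values("p")
        assert tab["adj_p"].is_monotonic_increasing

    def test_null_raw_p_uniformity(self):
        rng = np.random.default_rng(88)
        vals = rng.normal(0, 1, (5000, 20))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = moderated_pairwise(_matrix(vals), labels, "a", "b")
        frac = (res.table["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) < 3 * se

    def test_strong_effect_always_flagged(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 1, (300, 40))
            vals[0, :20] += 5.0
            labels = np.array(["a"] * 20 + ["b"] * 20)
            res = moderated_pairwise(_matrix(vals), labels, "a", "b")
            assert res.table["adj_p"].iloc[0] < 0.001

    def test_zero_variance_degenerate_gene(self):
        vals = np.vstack([np.full(8, 3.0), np.random.default_rng(0).normal(size=(5, 8))])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = moderated_pairwise(_matrix(vals), labels, "a", "b")
        assert res.table["zero_variance"].iloc[0]
        assert res.table["p"].iloc[0] == 1.0

    def test_small_group_rejected(self, rng):
        vals = rng.normal(size=(10, 4))
        labels = np.array(["a", "a", "a", "b"])
        with pytest.raises(ValueError, match="≥ 2 samples"):
            moderated_pairwise(_matrix(vals), labels, "a", "b")


class TestLimmaOracle:
    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_matches_limma_ebayes(self, tmp_path, rng):
        """Moderated t, prior df and prior variance agree with limma's eBayes
        on a heterogeneous-variance fixture (independent reference system)."""
        G, na, nb = 80, 6, 7
        sd = np.exp(rng.normal(0, 0.6, G))
        vals = rng.normal(0, 1, (G, na + nb)) * sd[:, None] + 5
        x = _matrix(vals)
        x.values.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))
        design <- model.matrix(~0+factor(c(rep("A",{na}), rep("B",{nb}))))
        colnames(design) <- c("A","B")
        fit <- eBayes(contrasts.fit(lmFit(x, design), makeContrasts(A-B, levels=design)))
        write.table(data.frame(t=fit$t[,1], p=fit$p.value[,1],
                               d0=fit$df.prior, s02=fit$s2.prior),
                    "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        """
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
        lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        labels = np.array(["A"] * na + ["B"] * nb)
        res = moderated_pairwise(x, labels, "A", "B")
        assert res.d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-8)
        assert res.s0_sq == pytest.approx(lim["s02"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(res.table["t"].to_numpy(), lim["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(res.table["p"].to_numpy(), lim["p"].to_numpy(), atol=1e-8)


class TestPriorFit:
    def test_homogeneous_variances_give_infinite_prior_df(self, rng):
        s2 = np.full(200, 1.3) * stats.chi2.rvs(10, size=200, random_state=1) / 10
        d0, s0 = fit_f_dist(s2, 10)
        # chi-square spread alone: no extra heterogeneity expected
        assert d0 > 10 or np.isinf(d0)
        assert s0 > 0


class TestOverlap:
    def _result(self, sig_genes, all_genes, contrast=("a", "b")):
        p = pd.Series(1.0, index=all_genes)
        p.loc[sig_genes] = 1e-9
        tab = pd.DataFrame({"adj_p": p})
        return DiffExprResult(contrast, tab, 1.0, 1.0, 10.0)

    def test_intersection_semantics(self):
        genes = list("ABCDE")
        r1 = self._result(["A", "B"], genes)
        r2 = self._result(["B", "C"], genes, contrast=("a", "c"))
        assert overlap_degs([r1, r2], alpha=0.001) == ["B"]

    def test_empty_contrast_set_gives_empty_overlap(self):
        genes = list("ABC")
        assert overlap_degs([self._result([], genes), self._result(["A"], genes)]) == []

    def test_no_contrasts_rejected(self):
        with pytest.raises(ValueError):
            overlap_degs([])

    def test_planted_all_contrast_genes_recovered_exactly(self):
        """Genes shifted in all 3 clusters are recovered by the overlap;
        genes shifted in only one cluster are excluded."""
        rng = np.random.default_rng(42)
        n_per, G = 30, 400
        labels = np.repeat(["a", "b", "c"], n_per)
        vals = rng.normal(0, 0.5, (G, 3 * n_per))
        all_contrast = [f"g{i:04d}" for i in range(30)]
        one_contrast = [f"g{i:04d}" for i in range(30, 60)]
        for i in range(30):       # distinct mean per cluster
            vals[i, n_per:2 * n_per] += 3.0
            vals[i, 2 * n_per:] += 6.0
        for i in range(30, 60):   # cluster a only
            vals[i, :n_per] += 3.0
        results = all_pairwise(_matrix(vals), labels)
        overlap = overlap_degs(results, alpha=0.001)
        assert overlap == sorted(all_contrast)
        assert not set(one_contrast) & set(overlap)
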