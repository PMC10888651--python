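import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import connexsig.diffexpr as de
from connexsig.diffexpr import (
    ExpressionExperiment,
    benjamini_hochberg,
    filter_degs,
    fit_differential,
    quantile_normalize,
)
from connexsig.errors import ValidationError
from connexsig.synthetic_data import ExperimentSpec, simulate_experiment


def brute_force_bh(p):
    """Independent step-up evaluation: q(i) = min over p(j) >= p(i) of m*p(j)/rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * p[i] / (pos + 1))
        q[i] = running_min
    return q


def make_experiment(values, n_ctrl=3, n_trt=3, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_trt)]
    groups = pd.Series(["control"] * n_ctrl + ["treated"] * n_trt, index=cols)
    return ExpressionExperiment(pd.DataFrame(values, index=genes, columns=cols), groups)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_single_column_unchanged(self):
        m = np.array([[5.0], [1.0], [3.0]])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_hand_worked_two_columns(self):
        m = np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_columns_share_sorted_values(self, rng):
        m = rng.normal(size=(50, 4))
        out = quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_rank_order_preserved(self, rng):
        m = rng.normal(size=(30, 3))
        out = quantile_normalize(m)
        for j in range(3):
            np.testing.assert_array_equal(np.argsort(m[:, j]), np.argsort(out[:, j]))

    def test_ties_get_span_mean(self):
        # column 0 has a 3-way tie occupying sorted ranks 1-3
        m = np.column_stack([[5.0, 5.0, 5.0, 9.0], [1.0, 2.0, 3.0, 4.0]])
        out = quantile_normalize(m)
        ref = np.sort(m, axis=0).mean(axis=1)
        expected_tie = ref[:3].mean()
        np.testing.assert_allclose(out[:3, 0], expected_tie)
        assert out[3, 0] == pytest.approx(ref[3])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            quantile_normalize(np.empty((0, 0)))


class TestBenjaminiHochberg:
    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_hand_worked_ladder(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 200))
    def test_matches_brute_force_step_up(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)


class TestFitDifferential:
    def test_identical_group_means(self, rng):
        values = rng.normal(size=(20, 6))
        values[0] = [1.0, 2.0, 3.0, 3.0, 1.0, 2.0]  # same multiset in both groups
        table = fit_differential(make_experiment(values))
        row = table.iloc[0]
        assert row["logFC"] == 0 and row["t"] == 0 and row["p"] == 1

    def test_moderated_equals_ordinary_when_prior_vanishes(self, rng, monkeypatch):
        values = rng.normal(size=(50, 6)) * rng.uniform(0.5, 2.0, size=(50, 1))
        expr = make_experiment(values)
        ordinary = fit_differential(expr, method="ordinary_t")
        monkeypatch.setattr(de, "_fit_variance_prior", lambda s2, df: (1e-8, 1.0))
        moderated = fit_differential(expr, method="moderated_t")
        np.testing.assert_allclose(moderated["t"], ordinary["t"], rtol=1e-6)
        np.testing.assert_allclose(moderated["p"], ordinary["p"], rtol=1e-5, atol=1e-12)

    def test_constant_matrix_falls_back_with_warning(self):
        values = np.ones((5, 6))
        with pytest.warns(RuntimeWarning, match="falling back"):
            table = fit_differential(make_experiment(values), method="moderated_t")
        assert (table["logFC"] == 0).all()

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_differential(make_experiment(rng.normal(size=(5, 6))), method="bayes")

    def test_planted_recovery_small(self):
        expr, truth = simulate_experiment(
            ExperimentSpec(n_genes=1000, n_up=100, n_down=100, seed=11)
        )
        degs = filter_degs(fit_differential(expr), q_cutoff=0.05)
        hits = set(degs["gene_id"])
        planted = set(truth["gene_id"])
        sensitivity = len(hits & planted) / len(planted)
        fdr = len(hits - planted) / max(len(hits), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.07

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same fixture."""
        rng = np.random.default_rng(42)
        values = rng.normal(7, 1, (200, 6)) * rng.uniform(0.5, 2, (200, 1))
        expr = make_experiment(values)
        ours = fit_differential(expr, method="moderated_t")
        tsv = tmp_path / "m.tsv"
        expr.matrix.to_csv(tsv, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{tsv}", row.names=1))
            fit <- eBayes(lmFit(m, cbind(1, c(0,0,0,1,1,1))))
            out <- data.frame(logFC=fit$coefficients[,2], t=fit$t[,2], p=fit$p.value[,2])
            write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        np.testing.assert_allclose(ours["logFC"], theirs["logFC"], rtol=1e-8)
        np.testing.assert_allclose(ours["t"], theirs["t"], rtol=1e-6)
        np.testing.assert_allclose(ours["p"], theirs["p"], rtol=1e-6, atol=1e-12)


class TestFilterDegs:
    def test_empty_table(self):
        table = pd.DataFrame(columns=["gene_id", "logFC", "t", "p", "q"])
        assert len(filter_degs(table)) == 0

    def test_strict_inequality_at_cutoff(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "logFC": [1.0, 2.0, 3.0], "q": [0.01, 0.05, 0.049]}
        )
        kept = filter_degs(table, q_cutoff=0.05)
        assert set(kept["gene_id"]) == {"a", "c"}

    def test_sorted_by_logfc_descending(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "logFC": [1.0, 3.0, -2.0], "q": [0.01] * 3}
        )
        assert list(filter_degs(table)["gene_id"]) == ["b", "a", "c"]

    def test_logfc_tie_broken_by_q_then_gene(self):
        table = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "logFC": [1.0, 1.0, 1.0], "q": [0.02, 0.02, 0.01]}
        )
        assert list(filter_degs(table)["gene_id"]) == ["c", "a", "b"]


class TestExperimentValidation:
    def test_fewer_than_three_per_group_rejected(self, rng):
        values = rng.normal(size=(4, 5))
        cols = [f"s{i}" for i in range(5)]
        groups = pd.Series(["control"] * 2 + ["treated"] * 3, index=cols)
        with pytest.raises(ValidationError, match="fewer than 3"):
            ExpressionExperiment(pd.DataFrame(values, columns=cols), groups)

    def test_unknown_label_rejected(self, rng):
        values = rng.normal(size=(4, 6))
        cols = [f"s{i}" for i in range(6)]
        groups = pd.Series(["control"] * 3 + ["dosed"] * 3, index=cols)
        with pytest.raises(ValidationError, match="unknown group"):
            ExpressionExperiment(pd.DataFrame(values, columns=cols), groups)
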