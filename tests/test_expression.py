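"""Differential expression, LASSO-Cox signature and qPCR quantification."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immuscore import (
    cox_fit,
    ddct,
    filter_de,
    lasso_cox,
    log_transform,
    moderated_t_test,
    risk_score_and_split,
)


def _random_expr(rng, n_genes=50, n_samples=20):
    expr = pd.DataFrame(
        rng.exponential(10, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return log_transform(expr)


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_values(self, raw, expected):
        df = pd.DataFrame({"s": [raw]}, index=["g"])
        assert log_transform(df).iloc[0, 0] == pytest.approx(expected)

    def test_double_transform_rejected(self):
        df = pd.DataFrame({"s": [1.0]}, index=["g"])
        once = log_transform(df)
        with pytest.raises(ValueError, match="already"):
            log_transform(once)

    def test_negative_input_rejected(self):
        df = pd.DataFrame({"s": [-0.5]}, index=["g"])
        with pytest.raises(ValueError, match="non-negative"):
            log_transform(df)


class TestModeratedT:
    def _labels(self, n1, n2, columns):
        return pd.Series(["CR"] * n1 + ["RR"] * n2, index=columns)

    def test_prior_df_zero_equals_classic_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(10)
        expr = _random_expr(rng)
        labels = self._labels(10, 10, expr.columns)
        res = moderated_t_test(expr, labels, prior_df=0)
        ref = ttest_ind(
            expr.iloc[:, 10:], expr.iloc[:, :10], axis=1, equal_var=True
        )
        assert np.allclose(res["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_prior_df_infinite_uses_s0_exactly(self):
        rng = np.random.default_rng(11)
        expr = _random_expr(rng)
        labels = self._labels(10, 10, expr.columns)
        res = moderated_t_test(expr, labels, prior_df=np.inf)
        s0 = np.sqrt(res.attrs["s0_squared"] * (1 / 10 + 1 / 10))
        assert np.allclose(res["t"], res["log2fc"] / s0, atol=1e-12)

    def test_null_simulation_bh_fraction_controlled(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            rng.normal(5, 1, (400, 30)),
            index=[f"g{i}" for i in range(400)],
            columns=[f"s{i}" for i in range(30)],
        )
        expr.attrs["log2_transformed"] = True
        labels = self._labels(15, 15, expr.columns)
        res = moderated_t_test(expr, labels)
        assert (res["p_adj"] < 0.05).mean() <= 0.05
        # moderated |t| should be t-like under the null
        assert 0.4 < res["t"].abs().median() < 0.95

    def test_matches_r_limma_on_fixture(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same matrix."""
        rng = np.random.default_rng(13)
        expr = _random_expr(rng, n_genes=40, n_samples=12)
        labels = self._labels(6, 6, expr.columns)
        res = moderated_t_test(expr, labels)
        mat = tmp_path / "expr.tsv"
        expr.to_csv(mat, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(limma))
                x <- as.matrix(read.delim("%s", row.names = 1))
                group <- factor(rep(c("CR", "RR"), each = 6), levels = c("CR", "RR"))
                design <- model.matrix(~group)
                fit <- eBayes(lmFit(x, design))
                out <- topTable(fit, coef = 2, number = Inf, sort.by = "none")
                write.table(data.frame(gene = rownames(out), t = out$t,
                                       lfc = out$logFC, p = out$P.Value),
                            "%s", sep = "\\t", row.names = FALSE, quote = FALSE)
                """
                % (mat, tmp_path / "limma_out.tsv")
            )
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
            timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t", index_col=0)
        ref = ref.reindex(res.index)
        assert np.allclose(res["log2fc"], ref["lfc"], atol=1e-8)
        assert np.allclose(res["t"], ref["t"], atol=1e-4)
        assert np.allclose(res["p"], ref["p"], atol=1e-6)

    def test_group_with_one_sample_rejected(self):
        rng = np.random.default_rng(14)
        expr = _random_expr(rng, n_samples=5)
        labels = self._labels(1, 4, expr.columns)
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(expr, labels)

    def test_invariant_under_gene_and_sample_reordering(self):
        rng = np.random.default_rng(15)
        expr = _random_expr(rng)
        labels = self._labels(10, 10, expr.columns)
        base = set(filter_de(moderated_t_test(expr, labels)))
        shuffled = expr.sample(frac=1, axis=0, random_state=1)
        # permute samples within each group
        cols = list(expr.columns[:10][::-1]) + list(expr.columns[10:][::-1])
        shuffled = shuffled[cols]
        again = set(filter_de(moderated_t_test(shuffled, labels)))
        assert base == again


class TestFilterDe:
    def _frame(self, log2fc, p_adj):
        return pd.DataFrame(
            {"log2fc": log2fc, "p_adj": p_adj},
            index=[f"g{i}" for i in range(len(log2fc))],
        )

    def test_strict_thresholds(self):
        res = self._frame([1.0, 2.0, -1.5, 0.5], [0.001, 0.05, 0.01, 0.001])
        # log2fc exactly 1 -> excluded; adj p exactly 0.05 -> excluded
        assert filter_de(res) == ["g2"]

    def test_order_stable(self):
        res = self._frame([2.0, -2.0, 3.0], [0.01, 0.01, 0.01])
        assert filter_de(res) == ["g0", "g1", "g2"]


class TestLassoCox:
    def _sim(self, rng, n=100, p=2, beta=None):
        beta = np.zeros(p) if beta is None else np.asarray(beta)
        X = rng.standard_normal((p, n))
        t = rng.exponential(np.exp(-(beta @ X)))
        expr = pd.DataFrame(
            X,
            index=[f"g{i}" for i in range(p)],
            columns=[f"s{i}" for i in range(n)],
        )
        expr.attrs["log2_transformed"] = True
        surv = pd.DataFrame(
            {"time_months": t, "event": np.ones(n, int)}, index=expr.columns
        )
        return expr, surv

    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(16)
        expr, surv = self._sim(rng, n=80, p=10, beta=[1] + [0] * 9)
        path, _ = lasso_cox(expr, surv, n_folds=5, seed=0)
        assert np.all(path.coefs.iloc[:, 0].to_numpy() == 0)
        assert path.alphas[0] == path.alphas.max()

    def test_near_zero_lambda_matches_unpenalized_cox(self):
        rng = np.random.default_rng(17)
        expr, surv = self._sim(rng, n=100, p=2, beta=[0.8, -0.5])
        path, model = lasso_cox(expr, surv, n_folds=5, lambda_grid=[1e-7], seed=0)
        df = surv.copy()
        df["g0"] = expr.loc["g0"].to_numpy()
        df["g1"] = expr.loc["g1"].to_numpy()
        fit = cox_fit(df, ["g0", "g1"])
        coefs = dict(zip(model.genes, model.coefficients))
        assert coefs["g0"] == pytest.approx(fit.coef[0], abs=1e-3)
        assert coefs["g1"] == pytest.approx(fit.coef[1], abs=1e-3)

    def test_lambda_min_minimizes_cv_deviance(self):
        rng = np.random.default_rng(18)
        expr, surv = self._sim(rng, n=120, p=15, beta=[1] + [0] * 14)
        path, _ = lasso_cox(expr, surv, n_folds=5, seed=3)
        assert path.cv_mean[path.lambda_min_index] == path.cv_mean.min()
        # tie-break toward larger lambda: first index achieving the min
        first = int(np.flatnonzero(path.cv_mean == path.cv_mean.min())[0])
        assert path.lambda_min_index == first

    def test_cv_curve_reproducible_under_seed(self):
        rng = np.random.default_rng(19)
        expr, surv = self._sim(rng, n=80, p=5, beta=[0.8, 0, 0, 0, 0])
        a, _ = lasso_cox(expr, surv, n_folds=5, seed=4)
        b, _ = lasso_cox(expr, surv, n_folds=5, seed=4)
        assert np.array_equal(a.cv_mean, b.cv_mean)
        assert a.lambda_min == b.lambda_min

    def test_fewer_events_than_folds_is_error(self):
        rng = np.random.default_rng(20)
        expr, surv = self._sim(rng, n=30, p=2)
        surv["event"] = 0
        surv.iloc[:3, surv.columns.get_loc("event")] = 1
        with pytest.raises(ValueError, match="n_folds"):
            lasso_cox(expr, surv, n_folds=10, seed=0)


class TestRiskScore:
    def test_single_gene_unit_coefficient_returns_expression(self):
        from immuscore.expression import RiskModel

        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g0"], columns=["a", "b", "c"]
        )
        model = RiskModel(genes=["g0"], coefficients=np.array([1.0]), lambda_=0.1)
        out = risk_score_and_split(model, expr)
        assert np.allclose(out["risk_score"], [1.0, 2.0, 3.0])
        assert list(out["risk_group"]) == ["low", "high", "high"]

    def test_empty_model_degenerate_split_flagged(self):
        from immuscore.expression import RiskModel

        expr = pd.DataFrame(
            [[1.0, 2.0]], index=["g0"], columns=["a", "b"]
        )
        model = RiskModel(genes=[], coefficients=np.array([]), lambda_=0.1)
        out = risk_score_and_split(model, expr)
        assert (out["risk_score"] == 0.0).all()
        assert out.attrs["degenerate"]

    def test_missing_model_gene_is_error(self):
        from immuscore.expression import RiskModel

        expr = pd.DataFrame([[1.0]], index=["g0"], columns=["a"])
        model = RiskModel(genes=["gX"], coefficients=np.array([1.0]), lambda_=0.1)
        with pytest.raises(ValueError, match="absent"):
            risk_score_and_split(model, expr)


class TestDdct:
    def test_zero_ddct_gives_unit_expression(self):
        assert ddct(20, 15, 22, 17).relative_expression == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        assert ddct(24, 18, 25, 18).relative_expression == pytest.approx(2.0)

    def test_direct_formula_evaluation(self):
        res = ddct(25, 18, 27, 18)
        assert res.ddct == pytest.approx(-2.0)
        assert res.relative_expression == pytest.approx(4.0)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ddct(np.nan, 18, 27, 18)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(5, 40), st.floats(5, 40))
    def test_self_comparison_identity(self, a, b):
        assert ddct(a, b, a, b).relative_expression == pytest.approx(1.0)
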