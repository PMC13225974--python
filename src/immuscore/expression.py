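"""Transcriptomic stage: log2(TPM+1) transform, moderated-t
differential expression, LASSO-Cox gene-signature selection, linear
risk scores, and the comparative 2^(-ddCt) qPCR quantity.

Differential expression follows the empirical-Bayes moderated-t
approach: per-gene residual variances s_g^2 are shrunk toward a common
prior value s0^2 with prior degrees of freedom d0, both estimated by
moment matching on the log sample variances; the moderated t uses
d0 + residual df. Genes are called significant at |log2FC| > 1 and
BH-adjusted p < 0.05 (both strict).

The gene signature is selected by an L1-penalized Cox fit along a
descending log-spaced lambda grid with 10-fold cross-validated partial
likelihood deviance; lambda_min (the deviance minimizer, ties broken
toward the larger penalty) defines the retained genes. The per-sample
risk score is the linear functional of transformed expression with the
retained coefficients, dichotomized at the cohort median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust

__all__ = [
    "log_transform",
    "moderated_t_test",
    "filter_de",
    "lasso_cox",
    "LassoPath",
    "RiskModel",
    "risk_score_and_split",
    "ddct",
    "DdctResult",
]


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------


def log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1) transform of a gene x sample matrix.

    The result carries ``attrs["log2_transformed"] = True``; applying
    the transform twice or to negative values is an error.
    """
    if expr.attrs.get("log2_transformed"):
        raise ValueError("expression matrix is already log2-transformed")
    values = expr.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("TPM values must be non-negative")
    out = pd.DataFrame(
        np.log2(values + 1.0), index=expr.index, columns=expr.columns
    )
    out.attrs["log2_transformed"] = True
    return out


# ---------------------------------------------------------------------------
# Moderated t (empirical Bayes variance shrinkage)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the log scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F prior on sample variances.

    Returns (d0, s0_squared); d0 may be inf when the observed
    log-variance spread is no larger than expected under a common
    variance.
    """
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all genes have zero residual variance")
    x = s2[ok]
    x = np.maximum(x, 1e-5 * np.median(x))  # guard near-zero variances
    z = np.log(x)
    e = z - float(special.digamma(df / 2)) + math.log(df / 2)
    ebar = float(e.mean())
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(ebar))
    evar = float(((e - ebar) ** 2).sum() / (n - 1))
    evar -= float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(x.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(
        np.exp(ebar + special.digamma(d0 / 2) - math.log(d0 / 2))
    )
    return d0, s0_sq


def moderated_t_test(
    expr: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] = ("CR", "RR"),
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression per gene.

    Parameters
    ----------
    expr : log2-transformed gene x sample matrix.
    labels : per-sample group label aligned on the columns.
    groups : (reference, alternative); log2FC is alternative minus
        reference mean.
    prior_df : override the estimated prior degrees of freedom d0
        (0 recovers the classic two-sample equal-variance t; inf makes
        every denominator use s0 exactly).

    Returns
    -------
    DataFrame indexed by gene with columns log2fc, t, p, p_adj,
    significant; hyperparameters d0 and s0_squared in ``attrs``.
    """
    labels = labels.reindex(expr.columns)
    a = expr.loc[:, (labels == groups[0]).to_numpy()]
    b = expr.loc[:, (labels == groups[1]).to_numpy()]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {groups[0]}:{n1}, "
            f"{groups[1]}:{n2})"
        )
    x1 = a.to_numpy(dtype=float)
    x2 = b.to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + (
        (x2 - m2[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = _fit_variance_prior(s2, df)[1] if d0 > 0 else float("nan")

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    # cap the total df at the pooled residual df across genes
    if prior_df is None or np.isinf(d0):
        df_total = min(df_total, df * len(expr))

    log2fc = m2 - m1
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / denom
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": (np.abs(log2fc) > 1.0) & (p_adj < 0.05),
        },
        index=expr.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_squared"] = float(s0_sq)
    out.attrs["residual_df"] = float(df)
    return out


def filter_de(result: pd.DataFrame) -> list:
    """Genes with |log2FC| > 1 and adjusted p < 0.05 (strict), in the
    input's gene order."""
    mask = (result["log2fc"].abs() > 1.0) & (result["p_adj"] < 0.05)
    return list(result.index[mask])


# ---------------------------------------------------------------------------
# LASSO-Cox signature
# ---------------------------------------------------------------------------


@dataclass
class LassoPath:
    """L1-penalized Cox coefficient path with cross-validated deviance."""

    alphas: np.ndarray  # descending lambda grid
    coefs: pd.DataFrame  # genes x lambdas, original scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_min_index: int


@dataclass
class RiskModel:
    """Genes with non-zero coefficients at lambda_min and their weights."""

    genes: list
    coefficients: np.ndarray
    lambda_: float

    def score(self, expr: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise ValueError(f"model genes absent from matrix: {missing}")
        X = expr.loc[self.genes].to_numpy(dtype=float)
        return pd.Series(self.coefficients @ X, index=expr.columns, name="risk_score")


def _breslow_loglik(beta, X, time, event):
    """Breslow log partial likelihood, vectorized (no gradients)."""
    eta = X @ beta
    eta = eta - eta.max()
    order = np.argsort(-time, kind="stable")
    t, e, h = time[order], event[order], np.exp(eta[order])
    cum = np.cumsum(h)
    # risk-set sum for each position: cumulative sum up to the end of
    # its tied-time block
    block_end = np.searchsorted(-t, -t, side="right") - 1
    s0 = cum[block_end]
    mask = e == 1
    return float(np.sum(eta[order][mask] - np.log(s0[mask])))


def _stratified_folds(event, n_folds, rng):
    """Fold labels balanced on the event indicator."""
    fold = np.empty(event.size, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def lasso_cox(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    n_folds: int = 10,
    lambda_grid=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> tuple[LassoPath, RiskModel]:
    """L1-penalized Cox regression with cross-validated lambda selection.

    Predictors are standardized internally; reported coefficients are on
    the original (transformed-expression) scale. The lambda grid is
    log-spaced downward from lambda_max (the smallest penalty shrinking
    every coefficient to zero) unless supplied. Fold assignment is
    seeded and stratified by event status; lambda_min minimizes the mean
    cross-validated partial-likelihood deviance, ties broken toward the
    larger penalty.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    samples = [s for s in expr.columns if s in survival.index]
    if len(samples) < expr.shape[1] or len(samples) < len(survival):
        survival = survival.loc[survival.index.intersection(expr.columns)]
        samples = list(survival.index)
    time = survival.loc[samples, duration_col].to_numpy(dtype=float)
    event = survival.loc[samples, event_col].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < n_folds:
        raise ValueError(
            f"only {n_events} events for {n_folds}-fold cross-validation; "
            "reduce n_folds"
        )
    X_raw = expr.loc[:, samples].to_numpy(dtype=float).T  # samples x genes
    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)
    if np.any(sd == 0):
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant expression for genes: {bad}")
    X = (X_raw - mu) / sd
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def fit_path(Xs, ys, alphas):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=alphas,
            fit_baseline_model=False,
            max_iter=100000,
            tol=1e-7,
        )
        model.fit(Xs, ys)
        return model

    def coefs_on_grid(model, grid):
        """Model coefficients aligned to the requested descending grid.

        The elastic-net path solver may stop early once the deviance
        plateaus; missing tail points reuse the last computed solution.
        """
        fitted = np.asarray(model.alphas_, dtype=float)
        coefs = np.asarray(model.coef_)
        order = np.argsort(-fitted)
        fitted, coefs = fitted[order], coefs[:, order]
        cols = [int(np.argmin(np.abs(fitted - a))) for a in grid]
        return coefs[:, cols]

    if lambda_grid is None:
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            n_alphas=n_lambdas,
            alpha_min_ratio=lambda_min_ratio,
            max_iter=100000,
            tol=1e-7,
        )
        probe.fit(X, y)
        alphas = np.asarray(probe.alphas_, dtype=float)
        full = probe
    else:
        alphas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        full = fit_path(X, y, alphas)
    alphas = np.sort(np.asarray(full.alphas_, dtype=float))[::-1]
    coef_std = coefs_on_grid(full, alphas)  # genes x lambdas

    # V&VH cross-validated partial-likelihood deviance
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(event, n_folds, rng)
    dev = np.zeros((n_folds, alphas.size))
    for k in range(n_folds):
        train = folds != k
        mdl = fit_path(X[train], Surv.from_arrays(event[train].astype(bool), time[train]), list(alphas))
        ck = coefs_on_grid(mdl, alphas)
        for i in range(alphas.size):
            beta = ck[:, i]
            l_all = _breslow_loglik(beta, X, time, event)
            l_train = _breslow_loglik(beta, X[train], time[train], event[train])
            dev[k, i] = -2.0 * (l_all - l_train)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))  # grid descends, so first minimum
    lambda_min = float(alphas[i_min])

    coef_orig = coef_std / sd[:, None]
    path = LassoPath(
        alphas=alphas,
        coefs=pd.DataFrame(coef_orig, index=expr.index, columns=alphas),
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_min_index=i_min,
    )
    nz = np.flatnonzero(coef_orig[:, i_min] != 0)
    model = RiskModel(
        genes=list(expr.index[nz]),
        coefficients=coef_orig[nz, i_min],
        lambda_=lambda_min,
    )
    return path, model


def risk_score_and_split(
    model: RiskModel, expr: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample linear risk score and inclusive-median High/Low split.

    Returns a frame with ``risk_score`` and ``risk_group``
    ("high"/"low"; score >= median is high risk). A degenerate split
    (all scores identical, e.g. an empty model) is flagged in
    ``attrs["degenerate"]``.
    """
    if not model.genes:
        scores = pd.Series(0.0, index=expr.columns, name="risk_score")
    else:
        scores = model.score(expr)
    med = float(np.median(scores))
    out = pd.DataFrame(
        {
            "risk_score": scores,
            "risk_group": np.where(scores >= med, "high", "low"),
        }
    )
    out.attrs["median"] = med
    out.attrs["degenerate"] = bool(scores.nunique() <= 1)
    return out


# ---------------------------------------------------------------------------
# Comparative 2^(-ddCt)
# ---------------------------------------------------------------------------


@dataclass
class DdctResult:
    dct_case: float
    dct_control: float
    ddct: float
    relative_expression: float


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> DdctResult:
    """Comparative 2^(-ddCt) relative quantification.

    dCt = Ct_target - Ct_reference within each condition;
    ddCt = dCt_case - dCt_control; relative expression = 2^(-ddCt)
    (case vs control, normalized to the housekeeping reference).
    """
    values = [ct_target_case, ct_ref_case, ct_target_control, ct_ref_control]
    if not all(np.isfinite(v) for v in values):
        raise ValueError("all Ct values must be finite")
    dct_case = ct_target_case - ct_ref_case
    dct_control = ct_target_control - ct_ref_control
    d = dct_case - dct_control
    return DdctResult(dct_case, dct_control, d, float(2.0 ** (-d)))
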