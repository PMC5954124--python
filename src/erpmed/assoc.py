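"""Association statistics: logistic PRS models with Nagelkerke delta-R^2 and
FDR q-values, plus the descriptive group comparisons (two-sample t-tests,
Pearson chi-square, multivariable linear regression).

The logistic fitter is iteratively reweighted least squares with explicit
rank and separation diagnostics; the incremental Nagelkerke R^2 of a score is
the full-model value minus the covariates-only value, floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AncestryPCs, ConfigurationError


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class OLSFit:
    coef: np.ndarray
    cov: np.ndarray
    pvalues: np.ndarray
    resid: np.ndarray
    df_resid: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class GroupComparison:
    variable: str
    statistic_kind: str  # "t" | "chi2" | "ols_beta"
    statistic: float
    df: float
    p: float
    adjusted_for: tuple[str, ...] = ()


@dataclass
class AssociationResult:
    trait: str
    p_threshold: float
    beta: float
    se: float
    wald_p: float
    nagelkerke_r2: float
    q_value: float
    n: int
    subset: str


def _check_rank(X: np.ndarray, names=None) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify a dependent column via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = int(np.argmin(diag))
        label = names[bad] if names is not None else f"column {bad}"
        raise RankDeficiencyError(f"design matrix rank deficient (collinear: {label})")


def logistic_fit(y: np.ndarray, X: np.ndarray, names=None,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the largest coefficient change falls below ``tol`` (or
    after ``max_iter`` iterations). Raises :class:`SeparationError` naming
    the most suspicious column under perfect separation and
    :class:`RankDeficiencyError` for collinear designs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigurationError("y must be binary 0/1")
    if y.min() == y.max():
        raise ConfigurationError("outcome is constant")
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        # Newton step via weighted least squares
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        it = max_iter

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    classified = (mu > 0.5) == (y > 0.5)
    if np.max(np.abs(eta)) > 30 and classified.all():
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        bad = int(np.argmax(np.abs(beta * scale)))
        label = names[bad] if names is not None else f"column {bad}"
        raise SeparationError(f"perfect separation detected (column: {label})")

    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return LogisticFit(coef=beta, cov=cov, loglik=ll, n_iter=it)


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's normalized Cox-Snell pseudo-R^2."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if ll_full < ll_null - 1e-9:
        raise ConfigurationError("ll_full must be >= ll_null")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(min(1.0, cox_snell / max_cs))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def prs_association(
    prs: pd.DataFrame,
    gi_flag: pd.Series,
    pcs: AncestryPCs | pd.DataFrame,
    subset: str = "all",
    subset_mask: pd.Series | None = None,
) -> list[AssociationResult]:
    """Logistic association of every trait x threshold score with GI status.

    Fits ``GI ~ score + PC1..PCk`` per score (scores standardized to unit
    variance, so ``beta`` is log-odds per score SD), reporting the Wald P of
    the score coefficient and the incremental Nagelkerke R^2 over the
    covariates-only model (floored at 0). FDR q-values are computed across
    all trait x threshold tests of the subset.
    """
    pc_frame = pcs.to_frame() if isinstance(pcs, AncestryPCs) else pcs
    results: list[AssociationResult] = []
    pvals: list[float] = []
    for (trait, pt), grp in prs.groupby(["trait", "p_threshold"], sort=True):
        s = grp.set_index("sample_id")["score"]
        idx = pc_frame.index.intersection(s.index).intersection(gi_flag.index)
        if subset_mask is not None:
            idx = idx[subset_mask.reindex(idx).fillna(False).to_numpy(dtype=bool)]
        y = gi_flag.loc[idx].to_numpy(dtype=float)
        if y.min() == y.max():
            raise ConfigurationError(f"subset {subset!r} has a single outcome class")
        score = s.loc[idx].to_numpy(dtype=float)
        C = pc_frame.loc[idx].to_numpy(dtype=float)
        ones = np.ones((len(idx), 1))

        X_cov = np.hstack([ones, C])
        fit_cov = logistic_fit(y, X_cov)
        ll0 = logistic_fit(y, ones).loglik
        r2_cov = nagelkerke_r2(ll0, fit_cov.loglik, len(y))

        if score.std() == 0:
            beta, se_, p_, r2 = 0.0, np.nan, 1.0, 0.0
        else:
            zscore = (score - score.mean()) / score.std()
            X_full = np.hstack([ones, zscore[:, None], C])
            fit = logistic_fit(y, X_full)
            beta, se_ = float(fit.coef[1]), float(fit.se[1])
            p_ = float(fit.wald_p()[1])
            r2 = max(0.0, nagelkerke_r2(ll0, fit.loglik, len(y)) - r2_cov)

        results.append(AssociationResult(
            trait=trait, p_threshold=float(pt), beta=beta, se=se_, wald_p=p_,
            nagelkerke_r2=r2, q_value=np.nan, n=len(y), subset=subset))
        pvals.append(p_)

    q = fdr_adjust(pvals)
    for res, qv in zip(results, q):
        res.q_value = float(qv)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def two_sample_t(mean1, sd1, n1, mean2, sd2, n2,
                 variable: str = "") -> GroupComparison:
    """Pooled-variance two-sample t-test from summary statistics."""
    if min(n1, n2) < 2 or min(sd1, sd2) < 0:
        raise ConfigurationError("need n >= 2 per group and non-negative SDs")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return GroupComparison(variable, "t", 0.0, n1 + n2 - 2, 1.0)
        raise ConfigurationError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return GroupComparison(variable, "t", float(t), n1 + n2 - 2, float(p))


def pearson_chi2(table, variable: str = "") -> GroupComparison:
    """Pearson chi-square (no continuity correction), upper-tail P."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ConfigurationError("contingency table must be at least 2x2")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ConfigurationError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ConfigurationError("zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return GroupComparison(variable, "chi2", float(res.statistic),
                           float(res.dof), float(res.pvalue))


def ols_fit(y: np.ndarray, X: np.ndarray, names=None) -> OLSFit:
    """Least squares with classical covariance and two-sided t p-values."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ConfigurationError("need more observations than parameters")
    _check_rank(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tvals = coef / np.sqrt(np.diag(cov))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return OLSFit(coef=coef, cov=cov, pvalues=pvals, resid=resid, df_resid=df)


def plot_delta_r2(results: list[AssociationResult], path=None):
    """Bar chart of incremental Nagelkerke R^2 by trait and threshold, with
    significance stars (* unadjusted P < 0.05, ** FDR q < 0.05)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = association_frame(results)
    traits = sorted(df["trait"].unique())
    thresholds = sorted(df["p_threshold"].unique())
    width = 0.8 / len(thresholds)
    fig, ax = plt.subplots(figsize=(1.8 * len(traits) + 2, 4))
    for j, pt in enumerate(thresholds):
        sub = df[df["p_threshold"] == pt].set_index("trait").reindex(traits)
        xs = np.arange(len(traits)) + (j - len(thresholds) / 2 + 0.5) * width
        bars = ax.bar(xs, 100 * sub["nagelkerke_r2"], width=width,
                      label=f"P_T={pt:g}")
        for x, (_, row) in zip(xs, sub.iterrows()):
            star = "**" if row["q_value"] < 0.05 else (
                "*" if row["wald_p"] < 0.05 else "")
            if star:
                ax.text(x, 100 * row["nagelkerke_r2"], star, ha="center")
    ax.set_xticks(np.arange(len(traits)))
    ax.set_xticklabels(traits)
    ax.set_ylabel("incremental Nagelkerke $R^2$ (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
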