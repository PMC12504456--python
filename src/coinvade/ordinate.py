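"""Redundancy analysis of predicted occurrence probabilities.

RDA is the constrained ordination used to link the two genera's predicted
probabilities of occurrence (the response matrix Y, n x 2) to the fused
field + remote-sensing explanatory matrix X: a multivariate least-squares
fit of centred Y on X followed by an eigen-decomposition of the fitted
values. Columns of X are standardised to unit variance internally because
field and remote-sensing variables live on wildly different scales.

Scores are returned in type-2 scaling ("effects of the explanatory
variables"): response scores are the fitted-value principal axes scaled by
the square root of their eigenvalue, and explanatory arrows are the
correlations of each (standardised) X column with the constrained site
scores, scaled the same way. "Type 2" alone underdetermines the constants,
so the convention is fixed here rather than inherited.

Variance inflation factors (VIF_j = 1/(1 - R^2_j) from regressing column j
on the others) flag redundant explanatory variables; the screening rule is
VIF > 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RdaResult", "rda", "vif", "plot_biplot", "VIF_THRESHOLD"]

VIF_THRESHOLD = 10.0


@dataclass
class RdaResult:
    eigenvalues: np.ndarray          # constrained, nonnegative, non-increasing
    total_variance: float            # sum of variances of centred Y (ddof=1)
    proportion_constrained: float
    site_scores: pd.DataFrame        # constrained (fitted) site coordinates
    response_scores: pd.DataFrame    # one row per Y column, type-2 scaling
    biplot_scores: pd.DataFrame      # one row per X column, type-2 scaling
    residual_variance: float         # unconstrained remainder of Y's variance
    vif: pd.Series
    rank_deficient: bool


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - M.mean(axis=0)) / sd


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column of X.

    A perfectly collinear column is reported as ``inf`` rather than raising.
    Needs at least two columns; exact values need n > p.
    """
    M = np.asarray(X, dtype=float)
    n, p = M.shape
    if p < 2:
        raise ValueError("VIF needs at least two variables")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(p))
    out = []
    for j in range(p):
        yj = M[:, j]
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out.append(np.inf)
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.Series(out, index=names, name="vif")


def rda(Y: pd.DataFrame, X: pd.DataFrame) -> RdaResult:
    """Redundancy analysis of Y (responses) constrained by X.

    Raises on constant Y columns; a rank-deficient X is fitted through the
    pseudoinverse and flagged (with a warning) instead of failing.
    """
    Ym = np.asarray(Y, dtype=float)
    Xm = np.asarray(X, dtype=float)
    if Ym.ndim == 1:
        Ym = Ym[:, None]
    n = Ym.shape[0]
    if n < 3:
        raise ValueError("RDA needs at least 3 observations")
    if Xm.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if np.any(Ym.std(axis=0) == 0):
        raise ValueError("constant response column")

    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else \
        [f"y{i}" for i in range(Ym.shape[1])]
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(Xm.shape[1])]

    Yc = Ym - Ym.mean(axis=0)
    Xs = _standardize(Xm)

    rank = np.linalg.matrix_rank(Xs)
    rank_deficient = rank < Xs.shape[1]
    if rank_deficient:
        warnings.warn("explanatory matrix is rank deficient; using pseudoinverse",
                      stacklevel=2)
    B = np.linalg.pinv(Xs) @ Yc
    Yhat = Xs @ B

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    order = np.argsort(eig)[::-1]
    eig, U, s, Vt = eig[order], U[:, order], s[order], Vt[order]
    naxes = int(np.sum(eig > 1e-12 * max(eig[0], 1e-300))) if eig.size else 0
    naxes = max(naxes, 1)
    eig = eig[:naxes]
    U, s, Vt = U[:, :naxes], s[:naxes], Vt[:naxes]

    total = float(np.sum(Yc.var(axis=0, ddof=1)))
    proportion = float(np.sum(eig) / total)
    residual = float(np.sum((Yc - Yhat).var(axis=0, ddof=1)))

    axes = [f"RDA{k + 1}" for k in range(naxes)]
    # constrained ("linear combination") site scores
    site = U * s
    # type-2 scaling
    resp = Vt.T * np.sqrt(eig)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.array([
            [_safe_corr(Xs[:, j], site[:, k]) for k in range(naxes)]
            for j in range(Xs.shape[1])
        ])
    arrows = corr * np.sqrt(eig)

    vif_series = vif(pd.DataFrame(Xm, columns=x_names)) if Xm.shape[1] >= 2 \
        else pd.Series([np.nan], index=x_names, name="vif")

    return RdaResult(
        eigenvalues=eig,
        total_variance=total,
        proportion_constrained=proportion,
        residual_variance=residual,
        site_scores=pd.DataFrame(site, columns=axes),
        response_scores=pd.DataFrame(resp, index=y_names, columns=axes),
        biplot_scores=pd.DataFrame(arrows, index=x_names, columns=axes),
        vif=vif_series,
        rank_deficient=rank_deficient,
    )


def plot_biplot(result: RdaResult, path) -> None:
    """Static ordination biplot: explanatory arrows plus response arrows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    naxes = result.biplot_scores.shape[1]
    ax1 = "RDA1"
    ax2 = "RDA2" if naxes > 1 else "RDA1"
    for name, row in result.biplot_scores.iterrows():
        x, y = row[ax1], (row[ax2] if naxes > 1 else 0.0)
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue", lw=0.8))
        ax.text(x * 1.05, y * 1.05, str(name), fontsize=7, color="tab:blue")
    for name, row in result.response_scores.iterrows():
        x, y = row[ax1], (row[ax2] if naxes > 1 else 0.0)
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="0.4", lw=1.4))
        ax.text(x * 1.08, y * 1.08, str(name), fontsize=9, color="0.2")
    ax.axhline(0, color="0.85", lw=0.6)
    ax.axvline(0, color="0.85", lw=0.6)
    ax.set_xlabel(ax1)
    ax.set_ylabel(ax2 if naxes > 1 else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
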