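"""Binary-trait comparative analyses: phylogenetic logistic regression,
correlations on (optionally log-transformed) life-history variables, and a
genome-wide expression/trait correlation screen.

The phylogenetic logistic regression is a quasi-likelihood (GEE-style) fit
with a working correlation among tips that decays exponentially in patristic
distance, ``corr_ij = exp(-decay * d_ij)``; the decay parameter is profiled
on a Gaussian pseudo-likelihood of the Pearson residuals.  As the decay grows
the working correlation approaches the identity and the estimator reduces to
ordinary logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clockshift.phylo_io import Tree

__all__ = [
    "PhyloLogisticFit",
    "CorrelationResult",
    "binarize_expression",
    "phylo_logistic_fit",
    "loglog_correlation",
    "correlation_screen",
]


def binarize_expression(
    table: pd.DataFrame,
    threshold: float = 1.0,
    expression_col: str = "expression_fpkm",
    species_col: str = "species",
) -> pd.Series:
    """Dichotomize expression: 1 iff FPKM >= threshold.

    Species with missing expression are dropped with a warning.  The
    threshold is recorded in the result's ``attrs``.
    """
    if expression_col not in table.columns:
        raise KeyError(f"column {expression_col!r} missing")
    df = table.set_index(species_col) if species_col in table.columns else table
    expr = df[expression_col]
    missing = expr.index[expr.isna()].tolist()
    if missing:
        warnings.warn(f"dropping species with missing expression: {missing}")
        expr = expr.dropna()
    states = (expr >= threshold).astype(int)
    states.name = "expression_state"
    states.attrs["threshold_fpkm"] = threshold
    return states


@dataclass
class PhyloLogisticFit:
    """Result of the phylogenetic logistic regression."""

    coef: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    signal_decay: float
    n: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "signal_decay": self.signal_decay,
            "n": self.n,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def _logistic_gee(y, X, R_inv, logdet_R, ridge=0.0, max_iter=100, tol=1e-10):
    """Fisher scoring for the quasi-score U = D' V^{-1} (y - mu)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        a = np.sqrt(np.maximum(mu * (1 - mu), 1e-10))
        # V^{-1} = A^{-1/2} R^{-1} A^{-1/2}; D = diag(a^2) X
        Xa = X * a[:, None]
        info = Xa.T @ R_inv @ Xa + ridge * np.eye(p)
        resid = (y - mu) / a
        score = Xa.T @ (R_inv @ resid) - ridge * beta
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    a = np.sqrt(np.maximum(mu * (1 - mu), 1e-10))
    Xa = X * a[:, None]
    info = Xa.T @ R_inv @ Xa + ridge * np.eye(p)
    cov = np.linalg.pinv(info)
    e = (y - mu) / a
    pseudo_ll = -0.5 * (logdet_R + e @ R_inv @ e)
    return beta, cov, converged, pseudo_ll, mu


def phylo_logistic_fit(
    tree: Tree,
    y: pd.Series,
    X: pd.DataFrame,
    add_intercept: bool = True,
    decay_grid: np.ndarray | None = None,
) -> PhyloLogisticFit:
    """Phylogenetic logistic regression of a binary trait on covariates.

    ``y`` and the rows of ``X`` are indexed by species names matching the
    tree tips.  P-values use a t reference with n - p degrees of freedom.
    Complete separation triggers a ridge-penalized fallback with a flag.
    """
    tips = tree.tip_names()
    missing = [t for t in tips if t not in y.index]
    if missing:
        raise KeyError(f"species missing from trait data: {missing}")
    if len(tips) < 10:
        raise ValueError("need at least 10 species")
    yv = y.loc[tips].to_numpy(dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("binary trait is constant")
    Xd = X.loc[tips].copy()
    if add_intercept:
        Xd.insert(0, "(Intercept)", 1.0)
    names = list(Xd.columns)
    Xv = Xd.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite covariates")
    n, p = Xv.shape

    names_order, D = tree.patristic_distances()
    reorder = [names_order.index(t) for t in tips]
    D = D[np.ix_(reorder, reorder)]
    d_scale = np.mean(D[np.triu_indices(n, k=1)])
    if decay_grid is None:
        # off-diagonal correlation at the mean distance spans ~0.9 .. ~1e-7
        cors = np.array([0.9, 0.7, 0.5, 0.3, 0.15, 0.05, 0.01, 1e-3, 1e-7])
        decay_grid = -np.log(cors) / max(d_scale, 1e-12)

    flags: list[str] = []
    best = None
    for decay in decay_grid:
        R = np.exp(-decay * D)
        np.fill_diagonal(R, 1.0)
        # eigen floor keeps R invertible for tiny decays
        w, U = np.linalg.eigh(R)
        w = np.maximum(w, 1e-8)
        R_inv = (U / w) @ U.T
        logdet = float(np.sum(np.log(w)))
        beta, cov, conv, pll, mu = _logistic_gee(yv, Xv, R_inv, logdet)
        sep = np.all((mu > 0.5) == (yv > 0.5)) and (
            np.min(np.abs(np.clip(Xv @ beta, -30, 30))) > 8
        )
        if sep or not np.all(np.isfinite(beta)) or not conv:
            beta, cov, conv, pll, mu = _logistic_gee(
                yv, Xv, R_inv, logdet, ridge=1e-2
            )
            local_flags = ["separation or non-convergence: ridge fallback (lambda=0.01)"]
        else:
            local_flags = []
        if best is None or pll > best[0]:
            best = (pll, decay, beta, cov, conv, local_flags)

    pll, decay, beta, cov, conv, local_flags = best
    flags.extend(local_flags)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    df = max(n - p, 1)
    pvals = 2.0 * stats.t.sf(np.abs(z), df)
    return PhyloLogisticFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(pvals, index=names),
        signal_decay=float(decay),
        n=n,
        converged=bool(conv),
        flags=flags,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation with a two-sided t-based P-value."""

    r: float
    p: float
    n: int
    transform: str = "none"
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "transform": self.transform,
            "p_adjusted": self.p_adjusted,
        }


def loglog_correlation(x, y, transform: str = "log10") -> CorrelationResult:
    """Pearson correlation of two variables, optionally log10-transformed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if transform == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 transform requires positive values")
        x, y = np.log10(x), np.log10(y)
    elif transform != "none":
        raise ValueError("transform must be 'log10' or 'none'")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x), transform=transform)


def correlation_screen(
    expr: pd.DataFrame,
    trait: pd.Series,
    transform: str = "none",
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Correlate every gene (row of ``expr``) with a trait across species
    (columns), adjust P-values across genes and rank by |R|.

    All-zero gene rows are dropped; the number dropped is recorded in the
    result's ``attrs``.
    """
    species = [s for s in expr.columns if s in trait.index]
    if len(species) < 3:
        raise ValueError("need at least 3 species shared between matrix and trait")
    sub = expr[species]
    zero_rows = sub.index[(sub == 0).all(axis=1) | (sub.std(axis=1) == 0)]
    sub = sub.drop(index=zero_rows)
    if sub.empty:
        raise ValueError("no variable genes to screen")
    tv = trait.loc[species].to_numpy(dtype=float)
    rows = []
    for gene, vals in sub.iterrows():
        res = loglog_correlation(vals.to_numpy(dtype=float), tv, transform=transform)
        rows.append({"gene": gene, "r": res.r, "p": res.p, "n": res.n})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    out["rank"] = np.arange(1, len(out) + 1)
    out = out.reset_index(drop=True)
    out.attrs["n_dropped_constant"] = int(len(zero_rows))
    out.attrs["adjust_method"] = adjust
    return out
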