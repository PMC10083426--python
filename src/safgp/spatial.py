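"""Stage-1 spatial analysis of single field trials.

Each trial is analysed per trait with fixed accession and replicate effects
and a separable first-order autoregressive residual over the plot grid,

    e ~ N(0, sigma^2 * AR1(rho_row) (x) AR1(rho_col)),

the standard spatial model for row-column field trials.  The two
autocorrelations are profiled out of the REML criterion (coarse grid search
followed by local refinement) with generalized least squares for the fixed
effects at each candidate; the reported accession BLUEs are replicate-adjusted
least-squares means.  Missing or unused plots are handled by restricting the
Kronecker covariance to the observed cells.

Grid coordinates are 1-based indices; "distance" is index difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["SpatialFit", "ar1_correlation", "fit_trial_blues", "fit_site_blues"]

_RHO_CAP = 0.98


@dataclass(frozen=True)
class SpatialFit:
    trial: str
    trait: str
    rho_row: float
    rho_col: float
    sigma2_spatial: float
    log_likelihood: float


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|i-j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("AR1 requires |rho| < 1")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _design(plots: pd.DataFrame, trait: str):
    """Fixed-effect design: accession indicators + replicate (drop-first)."""
    acc = pd.Categorical(plots["accession"])
    rep = pd.Categorical(plots["rep"])
    n = len(plots)
    A = np.zeros((n, len(acc.categories)))
    A[np.arange(n), acc.codes] = 1.0
    reps = list(rep.categories)
    Rm = np.zeros((n, max(len(reps) - 1, 0)))
    for j, r in enumerate(reps[1:]):
        Rm[rep.codes == j + 1, j] = 1.0
    X = np.hstack([A, Rm])
    return X, list(acc.categories), reps


def _reml_pieces(X, y, C):
    """(-2*REML, beta, cov_beta_unscaled, sigma2) under cov = sigma2*C."""
    n, p = X.shape
    L = np.linalg.cholesky(C)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys
    try:
        cf = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError:
        return None
    beta = np.linalg.solve(cf.T, np.linalg.solve(cf, Xty))
    r = ys - Xs @ beta
    rss = float(r @ r)
    dof = n - p
    sigma2 = max(rss / dof, 1e-300) if dof > 0 else 0.0
    logdet_C = 2.0 * np.log(np.diag(L)).sum()
    logdet_XtX = 2.0 * np.log(np.diag(cf)).sum()
    neg2 = (dof * np.log(sigma2) if dof > 0 else 0.0) + logdet_C + logdet_XtX + dof
    cov_un = np.linalg.solve(cf.T, np.linalg.solve(cf, np.eye(p)))
    return neg2, beta, cov_un, sigma2


def fit_trial_blues(
    plots: pd.DataFrame,
    trait: str,
    grid_step: float = 0.05,
    grid_limit: float = 0.9,
    fix_rho: tuple[float, float] | None = None,
    refine_tol: float = 1e-4,
) -> tuple[pd.DataFrame, SpatialFit]:
    """Accession BLUEs for one trial/trait under the AR1 x AR1 residual.

    ``plots`` needs columns site, rep, row, col, accession and the trait; a
    single site is expected.  Returns (BLUE table, SpatialFit).  ``fix_rho``
    skips estimation and evaluates GLS at the given autocorrelations.
    """
    sites = plots["site"].unique()
    if len(sites) != 1:
        raise ValueError(f"fit_trial_blues expects one site, got {list(sites)}")
    site = str(sites[0])
    df = plots.dropna(subset=[trait]).reset_index(drop=True)
    if df["accession"].nunique() < 2:
        raise ValueError("need at least 2 accessions")
    if df.duplicated(subset=["row", "col"]).any():
        raise ValueError("duplicate plot coordinates within the trial")
    y = df[trait].to_numpy(dtype=float)
    X, acc_levels, reps = _design(df, trait)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        counts = df.groupby("accession")["rep"].nunique()
        bad = counts.index[0] if counts.empty else counts.idxmin()
        raise ValueError(
            f"singular fixed-effect design (accession {bad!r} confounded with replicate)"
        )
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    nr, nc = rows.max(), cols.max()
    cell = (rows - 1) * nc + (cols - 1)

    def corr_obs(rho_r, rho_c):
        Cr = ar1_correlation(nr, rho_r)
        Cc = ar1_correlation(nc, rho_c)
        C = np.kron(Cr, Cc)
        return C[np.ix_(cell, cell)]

    def neg2(rho):
        rho_r, rho_c = np.clip(rho, -_RHO_CAP, _RHO_CAP)
        out = _reml_pieces(X, y, corr_obs(rho_r, rho_c))
        if out is None:
            return np.inf
        return out[0]

    if fix_rho is not None:
        best = (float(fix_rho[0]), float(fix_rho[1]))
    else:
        grid = np.arange(-grid_limit, grid_limit + grid_step / 2, grid_step)
        best, best_val = (0.0, 0.0), np.inf
        for rr in grid:
            for rc in grid:
                v = neg2((rr, rc))
                if v < best_val:
                    best, best_val = (rr, rc), v
        res = optimize.minimize(
            neg2, x0=np.array(best), method="Nelder-Mead",
            options={"xatol": refine_tol, "fatol": 1e-9, "maxiter": 400},
        )
        if res.fun <= best_val:
            best = tuple(np.clip(res.x, -_RHO_CAP, _RHO_CAP))
    neg2_val, beta, cov_un, sigma2 = _reml_pieces(X, y, corr_obs(*best))
    # least-squares mean: accession coefficient + average replicate effect
    n_acc = len(acc_levels)
    n_rep_cols = X.shape[1] - n_acc
    rep_adjust = np.zeros(X.shape[1])
    if n_rep_cols:
        rep_adjust[n_acc:] = 1.0 / (n_rep_cols + 1)
    estimates, ses = [], []
    for i in range(n_acc):
        c = rep_adjust.copy()
        c[i] = 1.0
        estimates.append(float(c @ beta))
        ses.append(float(np.sqrt(sigma2 * c @ cov_un @ c)))
    blues = pd.DataFrame(
        {
            "site": site,
            "accession": acc_levels,
            "trait": trait,
            "estimate": estimates,
            "se": ses,
        }
    )
    fit = SpatialFit(site, trait, float(best[0]), float(best[1]),
                     float(sigma2), -0.5 * float(neg2_val))
    return blues, fit


def fit_site_blues(plots: pd.DataFrame, traits: list[str], **kw) -> tuple[pd.DataFrame, list[SpatialFit]]:
    """fit_trial_blues for every (site, trait) combination in a trial table."""
    out, fits = [], []
    for site, sub in plots.groupby("site", sort=False):
        for tr in traits:
            b, f = fit_trial_blues(sub, tr, **kw)
            out.append(b)
            fits.append(f)
    return pd.concat(out, ignore_index=True), fits
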