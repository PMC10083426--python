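"""REML estimation of univariate, multi-trait and g x E GBLUP models.

Models fitted to accession-level BLUEs (or plot-level records):

* univariate GBLUP  y = mu + g + e,  g ~ N(0, G sA2), e ~ N(0, I se2),
  fitted by a single eigen-rotation of G and 1-D profile REML on the
  variance ratio;
* multi-trait GBLUP with genetic covariance T (g ~ N(0, G (x) T)) and
  residual covariance R across traits, fitted by average-information (AI)
  REML with step-halving safeguards; records missing for a subset of traits
  are supported (the CV1 conditional-prediction path);
* g x E GBLUP  y = site + g + gE + e with main additive effects (cov G sA2)
  and site-specific interaction deviations (cov blockdiag_site(G) sgxe2).

Balanced complete multi-trait data with a single genomic kernel use a
canonical transformation (rotation by the eigenvectors of G) that turns the
likelihood into n independent t x t blocks; unbalanced or multi-kernel data
fall back to a dense-covariance AI-REML with identical conventions, so the
two routes agree to optimizer tolerance and are cross-checked in the tests.

Convergence: relative log-likelihood change < 1e-8 and parameter change
< 1e-6, at most 500 iterations.  Variance floors are 1e-8 x the phenotypic
variance; covariance matrices are bent toward their diagonal whenever an
implied correlation magnitude would exceed 0.999.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import GRM

__all__ = [
    "VarianceComponents",
    "CovarianceComponents",
    "CorrelationEstimate",
    "heritability",
    "correlation_from_cov",
    "fit_univariate",
    "fit_multitrait",
    "fit_gxe",
    "VarTerm",
    "dense_reml",
    "DenseFit",
]

MAX_ITER = 500
LL_TOL = 1e-8
PAR_TOL = 1e-6
CORR_CAP = 0.999


# ---------------------------------------------------------------------------
# scalar helpers


def heritability(sigma2_A: float, sigma2_e: float) -> float:
    """Variance ratio sigma2_A / (sigma2_A + sigma2_e) in [0, 1].

    With a genomic relationship matrix this is the narrow-sense h2; with an
    identity relationship it is the broad-sense H2.
    """
    if sigma2_A < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    tot = sigma2_A + sigma2_e
    if tot <= 0:
        raise ValueError("heritability undefined: both variances are zero")
    return sigma2_A / tot


def correlation_from_cov(cov: float, var_x: float, var_y: float) -> float:
    """cov / sqrt(var_x * var_y), clipped to [-0.999, 0.999]."""
    if var_x <= 0 or var_y <= 0:
        raise ValueError("variances must be positive")
    r = cov / np.sqrt(var_x * var_y)
    return float(np.clip(r, -CORR_CAP, CORR_CAP))


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_A: float
    sigma2_e: float
    relationship: str  # "genomic" | "identity"
    log_likelihood: float

    @property
    def h2(self) -> float:
        return heritability(self.sigma2_A, self.sigma2_e)


@dataclass
class CovarianceComponents:
    traits: list[str]
    T: np.ndarray
    Rres: np.ndarray
    log_likelihood: float
    sigma2_row: np.ndarray | None = None
    sigma2_col: np.ndarray | None = None
    param_cov: np.ndarray | None = None  # inverse average information

    def h2(self, trait: str) -> float:
        i = self.traits.index(trait)
        return heritability(self.T[i, i], self.Rres[i, i])

    def r_A(self, x: str, y: str) -> float:
        i, j = self.traits.index(x), self.traits.index(y)
        return correlation_from_cov(self.T[i, j], self.T[i, i], self.T[j, j])

    def r_P(self, x: str, y: str) -> float:
        i, j = self.traits.index(x), self.traits.index(y)
        P = self.T + self.Rres
        return correlation_from_cov(P[i, j], P[i, i], P[j, j])


@dataclass(frozen=True)
class CorrelationEstimate:
    trait_x: str
    trait_y: str
    r_A: float
    r_P: float


# ---------------------------------------------------------------------------
# bending / parameter hygiene


def _bend_cov(M: np.ndarray, floor: np.ndarray) -> np.ndarray:
    """Clip diagonal to the floor and shrink off-diagonals until the matrix is
    PD with all implied correlations <= CORR_CAP."""
    M = 0.5 * (M + M.T)
    d = np.maximum(np.diag(M).copy(), floor)
    np.fill_diagonal(M, d)
    if M.shape[0] == 1:
        return M
    D = np.diag(np.diag(M))
    sd = np.sqrt(np.diag(M))
    corr = M / np.outer(sd, sd)
    off_max = np.abs(corr - np.diag(np.diag(corr))).max()
    if off_max > CORR_CAP:
        # scale off-diagonals exactly onto the correlation cap
        M = D + (CORR_CAP / off_max) * (M - D)
    for _ in range(200):
        if np.linalg.eigvalsh(M).min() > 1e-12 * max(np.diag(M).max(), 1e-300):
            return M
        M = D + 0.99 * (M - D)
    return M


def _vech(t: int) -> list[tuple[int, int]]:
    return [(k, l) for k in range(t) for l in range(k, t)]


def _sym_basis(t: int, k: int, l: int) -> np.ndarray:
    E = np.zeros((t, t))
    E[k, l] += 1.0
    E[l, k] += 1.0
    if k == l:
        E[k, k] = 1.0
    return E


# ---------------------------------------------------------------------------
# dense multi-kernel AI-REML engine


@dataclass
class VarTerm:
    """One random term: records map to levels of a kernel K.

    ``structure`` is "full" (t x t covariance across traits) or "diag"
    (independent traits).  ``theta`` is the current t x t coefficient matrix.
    """

    name: str
    K: np.ndarray  # (n_levels, n_levels)
    rec_level: np.ndarray  # (n_records,) int
    structure: str = "full"
    theta: np.ndarray | None = None


@dataclass
class DenseFit:
    terms: list[VarTerm]
    Rres: np.ndarray
    log_likelihood: float
    beta: np.ndarray
    w: np.ndarray  # P y, for BLUP extraction
    param_cov: np.ndarray
    n_iter: int
    converged: bool
    ll_path: list[float] = field(default_factory=list)


def _engine_ll(V, X, y):
    n, p = X.shape
    L = np.linalg.cholesky(V)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtX = Xs.T @ Xs
    cf = np.linalg.cholesky(XtX)
    beta = np.linalg.solve(cf.T, np.linalg.solve(cf, Xs.T @ ys))
    r = ys - Xs @ beta
    ll = -0.5 * (
        2 * np.log(np.diag(L)).sum() + 2 * np.log(np.diag(cf)).sum() + float(r @ r)
    )
    return ll, beta, L, cf


def _engine_P_w(V, X, y):
    """Explicit P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, and w = P y."""
    n = V.shape[0]
    L = np.linalg.cholesky(V)
    Linv = np.linalg.solve(L, np.eye(n))
    Vinv = Linv.T @ Linv
    VX = Vinv @ X
    M = X.T @ VX
    P = Vinv - VX @ np.linalg.solve(M, VX.T)
    return P, P @ y


def _param_list(terms: list[VarTerm], t: int):
    """(owner, k, l) tuples; owner = term index or -1 for the residual."""
    out = []
    for q, term in enumerate(terms):
        if term.structure == "full":
            out += [(q, k, l) for k, l in _vech(t)]
        else:
            out += [(q, k, k) for k in range(t)]
    out += [(-1, k, l) for k, l in _vech(t)]
    return out


def dense_reml(
    y: np.ndarray,
    X: np.ndarray,
    trait: np.ndarray,
    unit: np.ndarray,
    terms: list[VarTerm],
    n_traits: int,
    R0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    track_ll: bool = False,
) -> DenseFit:
    """AI-REML for y = X beta + sum_q u_q + e with arbitrary missing pattern.

    Residual covariance couples records of the same ``unit`` across traits
    via the t x t matrix R; distinct units are independent.  AI (Newton)
    steps are safeguarded: a step that would leave the parameter space is
    bent back, and the step is halved until the restricted log-likelihood
    does not decrease, so the iteration is monotone by construction.
    """
    y = np.asarray(y, float)
    n = y.size
    t = n_traits
    trait = np.asarray(trait, int)
    unit = np.asarray(unit, int)
    # per-trait phenotypic variance floor
    var_y = np.array([np.var(y[trait == k]) if (trait == k).any() else 1.0 for k in range(t)])
    var_y = np.where(var_y > 0, var_y, 1.0)
    floor = 1e-8 * var_y
    S = np.diag(var_y)
    n_full = sum(1 for tm in terms if tm.structure == "full") + 1
    for tm in terms:
        if tm.theta is None:
            tm.theta = (S / n_full if tm.structure == "full"
                        else np.diag(0.1 * var_y))
        tm.theta = _bend_cov(np.asarray(tm.theta, float), floor)
    R = _bend_cov(S / n_full if R0 is None else np.asarray(R0, float), floor)

    unit_eq = unit[:, None] == unit[None, :]
    Ks = [tm.K[np.ix_(tm.rec_level, tm.rec_level)] for tm in terms]
    params = _param_list(terms, t)
    masks = []
    for owner, k, l in params:
        base = unit_eq if owner == -1 else Ks[owner]
        m = (trait[:, None] == k) & (trait[None, :] == l)
        if k != l:
            m = m | ((trait[:, None] == l) & (trait[None, :] == k))
        masks.append(base * m)

    def build_V():
        V = R[np.ix_(trait, trait)] * unit_eq
        for q, tm in enumerate(terms):
            V = V + tm.theta[np.ix_(trait, trait)] * Ks[q]
        return V

    def get_theta():
        v = []
        for owner, k, l in params:
            M = R if owner == -1 else terms[owner].theta
            v.append(M[k, l])
        return np.array(v)

    def set_theta(v):
        nonlocal R
        Ms = {q: tm.theta.copy() for q, tm in enumerate(terms)}
        Rn = R.copy()
        for (owner, k, l), val in zip(params, v):
            M = Rn if owner == -1 else Ms[owner]
            M[k, l] = val
            M[l, k] = val
        for q, tm in enumerate(terms):
            tm.theta = _bend_cov(Ms[q], 0.0 * floor if tm.structure == "diag" else floor)
            if tm.structure == "diag":
                tm.theta = np.diag(np.maximum(np.diag(tm.theta), 0.0))
        R = _bend_cov(Rn, floor)

    ll, beta, _, _ = _engine_ll(build_V(), X, y)
    ll_path = [ll]
    AI = np.eye(len(params))
    converged = False
    it = 0
    n_small = 0
    n_mid = 0
    for it in range(1, max_iter + 1):
        V = build_V()
        P, w = _engine_P_w(V, X, y)
        score = np.empty(len(params))
        U = np.empty((n, len(params)))
        for a, D in enumerate(masks):
            Dw = D @ w
            score[a] = -0.5 * (np.sum(P * D) - float(w @ Dw))
            U[:, a] = Dw
        AI = 0.5 * (U.T @ P @ U)
        AI = 0.5 * (AI + AI.T)
        theta0 = get_theta()
        scale = max(np.trace(AI) / len(params), 1.0)
        if np.linalg.norm(score) < 1e-7 * scale * np.sqrt(len(params)):
            converged = True
            break
        # active set: parameters pinned at a variance floor or correlation cap
        # with an outward-pointing gradient are frozen, so Newton steps stay
        # inside the parameter space instead of crawling along its boundary
        frozen = np.zeros(len(params), bool)
        for a, (owner, k, l) in enumerate(params):
            M = R if owner == -1 else terms[owner].theta
            if k == l:
                if M[k, k] <= 1.0001 * floor[k] and score[a] < 0:
                    frozen[a] = True
            else:
                den = np.sqrt(M[k, k] * M[l, l])
                if den > 0:
                    corr = M[k, l] / den
                    if abs(corr) >= CORR_CAP - 1e-6 and score[a] * np.sign(corr) > 0:
                        frozen[a] = True
        free = ~frozen
        if not free.any():
            converged = True
            break
        accepted = False
        damp = 1e-8
        # variances step on the log scale (multiplicative, positivity-safe);
        # covariances step linearly.  Marquardt damping scaled by the AI
        # diagonal keeps boundary-inflated parameters from freezing the rest.
        is_var = np.array([k == l for _, k, l in params])
        jac = np.where(is_var, np.maximum(np.abs(theta0), 1e-300), 1.0)
        score_t = jac * score
        AI_t = AI * np.outer(jac, jac)
        Dm = np.diag(np.maximum(np.diag(AI_t), 1e-10 * scale))
        for _ in range(4):
            step = np.zeros(len(params))
            step[free] = np.linalg.solve(
                (AI_t + damp * Dm)[np.ix_(free, free)], score_t[free])
            step = np.clip(step, -5.0, 5.0)
            frac = 1.0
            for _ in range(6):
                cand = np.where(is_var, theta0 * np.exp(frac * step),
                                theta0 + frac * step * jac)
                set_theta(cand)
                if np.array_equal(get_theta(), theta0):  # bent back to start
                    frac *= 0.5
                    continue
                try:
                    ll_new, beta, _, _ = _engine_ll(build_V(), X, y)
                except np.linalg.LinAlgError:
                    ll_new = -np.inf
                if np.isfinite(ll_new) and ll_new > ll + 1e-12:
                    accepted = True
                    break
                frac *= 0.5
            if accepted:
                break
            damp *= 1000.0
        if not accepted:
            set_theta(theta0)  # stay; gradient ~ 0 or boundary
            converged = True
            break
        dll = abs(ll_new - ll)
        dpar = np.max(np.abs(get_theta() - theta0)) / (1.0 + np.max(np.abs(theta0)))
        ll = ll_new
        if track_ll:
            ll_path.append(ll)
        n_small = n_small + 1 if dll < 0.1 * LL_TOL * (1.0 + abs(ll)) else 0
        n_mid = n_mid + 1 if dll < 100 * LL_TOL * (1.0 + abs(ll)) else 0
        if ((dll < LL_TOL * (1.0 + abs(ll)) and dpar < PAR_TOL)
                or n_small >= 4 or n_mid >= 8):
            converged = True
            break
    if not converged and it >= max_iter:
        grad = float(np.linalg.norm(score))
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations (last gradient norm {grad:.3g})"
        )
    V = build_V()
    P, w = _engine_P_w(V, X, y)
    ll, beta, _, _ = _engine_ll(V, X, y)
    try:
        pcov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        pcov = np.linalg.pinv(AI)
    return DenseFit(terms, R, ll, beta, w, pcov, it, True, ll_path)


# ---------------------------------------------------------------------------
# canonical (eigen-rotated) balanced multi-trait REML


class _Canonical:
    """Balanced complete records, one genomic kernel: block-diagonal REML.

    After rotating every trait by the eigenvectors of G, the covariance of the
    i-th rotated record vector (one value per trait) is Sigma_i = d_i T + R
    and blocks are independent; all REML quantities are O(n t^3).
    """

    def __init__(self, Y: np.ndarray, G: np.ndarray, diagonal: bool = False):
        self.n, self.t = Y.shape
        d, Uv = np.linalg.eigh(G)
        self.d = np.clip(d, 0.0, None)
        self.U = Uv
        self.ystar = Uv.T @ Y
        self.x = Uv.T @ np.ones(self.n)
        var_y = Y.var(axis=0, ddof=1)
        self.floor = 1e-8 * np.where(var_y > 0, var_y, 1.0)
        self.S = np.cov(Y, rowvar=False, ddof=1).reshape(self.t, self.t)
        # with diagonal=True the off-diagonals of T and R are pinned at zero
        self.pairs = [(k, k) for k in range(self.t)] if diagonal else _vech(self.t)
        self.bases = [_sym_basis(self.t, k, l) for k, l in self.pairs]
        self.diagonal = diagonal

    def _pieces(self, T, R):
        Sig = self.d[:, None, None] * T + R
        sign, logdet = np.linalg.slogdet(Sig)
        if (sign <= 0).any():
            return None
        B = np.linalg.inv(Sig)
        M = np.einsum("i,ijk->jk", self.x**2, B)
        cfM = np.linalg.cholesky(M)
        rhs = np.einsum("i,ijk,ik->j", self.x, B, self.ystar)
        beta = np.linalg.solve(cfM.T, np.linalg.solve(cfM, rhs))
        r = self.ystar - np.outer(self.x, beta)
        w = np.einsum("ijk,ik->ij", B, r)
        ll = -0.5 * (
            logdet.sum() + 2 * np.log(np.diag(cfM)).sum() + float(np.sum(r * w))
        )
        return ll, B, M, beta, r, w

    def loglik(self, T, R):
        out = self._pieces(T, R)
        return -np.inf if out is None else out[0]

    def score_ai(self, T, R):
        out = self._pieces(T, R)
        if out is None:
            raise np.linalg.LinAlgError("non-PD block covariance")
        ll, B, M, beta, r, w = out
        Minv = np.linalg.inv(M)
        q = 2 * len(self.pairs)
        cs = [self.d] * len(self.pairs) + [np.ones(self.n)] * len(self.pairs)
        Es = self.bases + self.bases
        score = np.empty(q)
        us = []
        for a in range(q):
            c, E = cs[a], Es[a]
            BE = np.einsum("ijk,kl->ijl", B, E)
            tr1 = np.einsum("i,ijj->", c, BE)
            F = np.einsum("ijk,ikl->ijl", BE, B)  # B E B
            S2 = np.einsum("i,ijk->jk", self.x**2 * c, F)
            trP = tr1 - float(np.sum(Minv * S2.T))
            u = c[:, None] * np.einsum("jk,ik->ij", E, w)
            score[a] = -0.5 * (trP - float(np.sum(w * u)))
            us.append(u)
        AI = np.empty((q, q))
        Bu = [np.einsum("ijk,ik->ij", B, u) for u in us]
        s = [np.einsum("i,ij->j", self.x, bu) for bu in Bu]
        for a in range(q):
            for b in range(a, q):
                AI[a, b] = AI[b, a] = 0.5 * (
                    float(np.sum(us[a] * Bu[b])) - float(s[a] @ Minv @ s[b])
                )
        return ll, score, AI

    def fit(self, T0=None, R0=None, max_iter: int = MAX_ITER):
        T = _bend_cov(0.5 * self.S if T0 is None else np.asarray(T0, float), self.floor)
        R = _bend_cov(0.5 * self.S if R0 is None else np.asarray(R0, float), self.floor)
        if self.diagonal:
            T, R = np.diag(np.diag(T)), np.diag(np.diag(R))
        npair = len(self.pairs)

        def unpack(v):
            Tm, Rm = np.zeros((self.t, self.t)), np.zeros((self.t, self.t))
            for a, (k, l) in enumerate(self.pairs):
                Tm[k, l] = Tm[l, k] = v[a]
                Rm[k, l] = Rm[l, k] = v[npair + a]
            return _bend_cov(Tm, self.floor), _bend_cov(Rm, self.floor)

        def pack(T, R):
            return np.array(
                [T[k, l] for k, l in self.pairs] + [R[k, l] for k, l in self.pairs]
            )

        ll = self.loglik(T, R)
        converged = False
        AI = np.eye(2 * npair)
        ll_path = [ll]
        n_small = 0
        n_mid = 0
        for it in range(1, max_iter + 1):
            ll, score, AI = self.score_ai(T, R)
            scale = max(np.trace(AI) / AI.shape[0], 1.0)
            if np.linalg.norm(score) < 1e-7 * scale * np.sqrt(AI.shape[0]):
                converged = True
                break
            v0 = pack(T, R)
            # freeze parameters pinned at a floor or correlation cap whose
            # gradient points outward (active-set; see dense_reml)
            frozen = np.zeros(2 * npair, bool)
            for a, (k, l) in enumerate(self.pairs + self.pairs):
                M = T if a < npair else R
                if k == l:
                    if M[k, k] <= 1.0001 * self.floor[k] and score[a] < 0:
                        frozen[a] = True
                else:
                    den = np.sqrt(M[k, k] * M[l, l])
                    if den > 0:
                        corr = M[k, l] / den
                        if (abs(corr) >= CORR_CAP - 1e-6
                                and score[a] * np.sign(corr) > 0):
                            frozen[a] = True
            free = ~frozen
            if not free.any():
                converged = True
                break
            accepted = False
            damp = 1e-8
            is_var = np.array([k == l for k, l in self.pairs] * 2)
            jac = np.where(is_var, np.maximum(np.abs(v0), 1e-300), 1.0)
            score_t = jac * score
            AI_t = AI * np.outer(jac, jac)
            D = np.diag(np.maximum(np.diag(AI_t), 1e-10 * scale))
            for _ in range(4):
                step = np.zeros(2 * npair)
                step[free] = np.linalg.solve(
                    (AI_t + damp * D)[np.ix_(free, free)], score_t[free])
                step = np.clip(step, -5.0, 5.0)
                frac = 1.0
                for _ in range(6):
                    cand = np.where(is_var, v0 * np.exp(frac * step),
                                    v0 + frac * step * jac)
                    Tn, Rn = unpack(cand)
                    ll_new = self.loglik(Tn, Rn)
                    if np.isfinite(ll_new) and ll_new > ll + 1e-12:
                        accepted = True
                        break
                    frac *= 0.5
                if accepted:
                    break
                damp *= 1000.0
            if not accepted:
                converged = True
                break
            dpar = np.max(np.abs(pack(Tn, Rn) - v0)) / (1.0 + np.max(np.abs(v0)))
            dll = abs(ll_new - ll)
            T, R, ll = Tn, Rn, ll_new
            ll_path.append(ll)
            n_small = n_small + 1 if dll < 0.1 * LL_TOL * (1.0 + abs(ll)) else 0
            n_mid = n_mid + 1 if dll < 100 * LL_TOL * (1.0 + abs(ll)) else 0
            if ((dll < LL_TOL * (1.0 + abs(ll)) and dpar < PAR_TOL)
                    or n_small >= 4 or n_mid >= 8):
                converged = True
                break
        if not converged:
            raise RuntimeError(f"canonical REML did not converge in {max_iter} iterations")
        out = self._pieces(T, R)
        ll, B, M, beta, r, w = out
        try:
            pcov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            pcov = np.linalg.pinv(AI)
        return T, R, ll, beta, w, pcov, ll_path

    def gebv(self, T, w):
        """Back-rotated conditional means of g for the fitted units."""
        return self.U @ (self.d[:, None] * (w @ T))


# ---------------------------------------------------------------------------
# public fits


def _align(blues: pd.DataFrame, grm: GRM, value_col: str):
    df = blues.dropna(subset=[value_col])
    ids = [i for i in df["accession"].unique() if i in set(grm.line_ids)]
    if len(ids) < len(df["accession"].unique()):
        missing = set(df["accession"]) - set(grm.line_ids)
        if missing:
            raise KeyError(f"accessions absent from GRM: {sorted(missing)[:3]} ...")
    return df, list(ids)


def fit_univariate(
    blues: pd.DataFrame, grm: GRM, value_col: str = "estimate"
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Single-trait GBLUP on accession BLUEs via the eigen-rotation fast path.

    ``blues`` needs columns accession and ``value_col`` (one record per
    accession).  Returns the REML variance components and a GEBV table.
    """
    df, ids = _align(blues, grm, value_col)
    if df["accession"].duplicated().any():
        raise ValueError("fit_univariate expects one record per accession")
    if len(ids) < 10:
        raise ValueError("need >= 10 accessions with both BLUE and GRM entries")
    sub = grm.subset(ids)
    y = df.set_index("accession")[value_col].loc[ids].to_numpy(float)
    n = len(y)
    vy = y.var(ddof=1)
    d, Uv = np.linalg.eigh(sub.values)
    d = np.clip(d, 0.0, None)
    ystar = Uv.T @ y
    xstar = Uv.T @ np.ones(n)

    floor = 1e-8 * max(vy, 1e-300)
    if vy <= 0:
        comps = VarianceComponents(floor, floor, "genomic", 0.0)
        gebv = pd.DataFrame({"accession": ids, "trait": value_col, "gebv": 0.0})
        return comps, gebv

    def pieces(lam):
        wts = 1.0 / (lam * d + 1.0)
        xtx = float(np.sum(xstar * wts * xstar))
        beta = float(np.sum(xstar * wts * ystar)) / xtx
        r = ystar - xstar * beta
        rss = float(np.sum(r * wts * r))
        se2 = max(rss / (n - 1), floor)
        ll = -0.5 * (
            n * np.log(se2)
            + np.sum(np.log(lam * d + 1.0))
            + np.log(xtx) - np.log(se2)
            + rss / se2
        )
        return ll, beta, se2, r, wts

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda x: -pieces(np.exp(x))[0], bounds=(-13.8, 13.8), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    ll0 = pieces(0.0)[0]
    ll_hat, beta, se2, r, wts = pieces(lam)
    if ll0 >= ll_hat:
        lam, (ll_hat, beta, se2, r, wts) = 0.0, pieces(0.0)
    sA2 = max(lam * se2, floor)
    u = Uv @ (lam * d * wts * r)
    u -= u.mean()  # GEBVs are reported as deviations from the population mean
    comps = VarianceComponents(sA2, se2, "genomic", float(ll_hat))
    gebv = pd.DataFrame({"accession": ids, "trait": value_col, "gebv": u})
    return comps, gebv


def _wide(blues: pd.DataFrame, traits: list[str] | None):
    """Long BLUE table (accession, trait, estimate) -> wide accession x trait."""
    if "trait" in blues.columns and "estimate" in blues.columns:
        wide = blues.pivot_table(index="accession", columns="trait",
                                 values="estimate", aggfunc="first")
    else:
        cols = [c for c in blues.columns if c not in ("site", "accession")]
        wide = blues.set_index("accession")[cols]
    if traits is not None:
        wide = wide[list(traits)]
    return wide


def fit_multitrait(
    blues: pd.DataFrame,
    grm: GRM,
    traits: list[str] | None = None,
    include_rowcol: bool = False,
    plots: pd.DataFrame | None = None,
    T0: np.ndarray | None = None,
    R0: np.ndarray | None = None,
    track_ll: bool = False,
    diagonal: bool = False,
) -> tuple[CovarianceComponents, pd.DataFrame, list[CorrelationEstimate]]:
    """Multi-trait GBLUP: genetic covariance T, residual covariance R.

    Accepts a long BLUE table (accession, trait, estimate; missing traits per
    accession allowed) or a wide frame.  Complete balanced data are fitted by
    the canonical eigen-rotation; incomplete data by the dense AI-REML engine.
    With ``include_rowcol`` and a plot-level table, independent row and column
    random effects (per-trait variances) are added.
    """
    if include_rowcol:
        if plots is None:
            raise ValueError("include_rowcol requires plot-level data")
        return _fit_mt_plots(plots, grm, traits, T0=T0, R0=R0)
    wide = _wide(blues, traits)
    trait_names = list(wide.columns)
    t = len(trait_names)
    if t < 2:
        raise ValueError("fit_multitrait needs >= 2 traits")
    ids = [i for i in wide.index if i in set(grm.line_ids)]
    if len(ids) < len(wide.index):
        raise KeyError("some accessions in the BLUE table are absent from the GRM")
    wide = wide.loc[ids]
    sub = grm.subset(ids)
    Y = wide.to_numpy(float)
    complete = not np.isnan(Y).any()
    if complete:
        can = _Canonical(Y, sub.values, diagonal=diagonal)
        T, R, ll, beta, w, pcov, ll_path = can.fit(T0=T0, R0=R0)
        U = can.gebv(T, w)
        fitinfo = {"ll_path": ll_path}
    else:
        if diagonal:
            raise ValueError("diagonal-constrained fits require complete records")
        rec = []
        for j, tr in enumerate(trait_names):
            obs = ~np.isnan(Y[:, j])
            for i in np.where(obs)[0]:
                rec.append((i, j, Y[i, j]))
        unit = np.array([r[0] for r in rec])
        trait_idx = np.array([r[1] for r in rec])
        yv = np.array([r[2] for r in rec])
        X = np.zeros((len(rec), t))
        X[np.arange(len(rec)), trait_idx] = 1.0
        term = VarTerm("additive", sub.values, unit, "full",
                       None if T0 is None else np.asarray(T0, float))
        fit = dense_reml(yv, X, trait_idx, unit, [term], t, R0=R0, track_ll=track_ll)
        T, R, ll = term.theta, fit.Rres, fit.log_likelihood
        pcov = fit.param_cov
        # GEBVs for every accession in the GRM subset
        U = np.empty((len(ids), t))
        for k in range(t):
            U[:, k] = sub.values[:, unit] @ (T[k, trait_idx] * fit.w)
        fitinfo = {"ll_path": fit.ll_path}
    U = U - U.mean(axis=0)  # deviations from the population mean
    comps = CovarianceComponents(trait_names, T, R, float(ll), param_cov=pcov)
    comps.ll_path = fitinfo["ll_path"]  # type: ignore[attr-defined]
    gebv = pd.DataFrame(
        {
            "accession": np.repeat(ids, t),
            "trait": np.tile(trait_names, len(ids)),
            "gebv": U.reshape(-1),
        }
    )
    corrs = [
        CorrelationEstimate(a, b, comps.r_A(a, b), comps.r_P(a, b))
        for ai, a in enumerate(trait_names)
        for b in trait_names[ai + 1:]
    ]
    return comps, gebv, corrs


def _fit_mt_plots(plots, grm, traits, T0=None, R0=None):
    """Plot-level multi-trait fit with row/column random effects (one site)."""
    traits = list(traits)
    t = len(traits)
    df = plots.reset_index(drop=True)
    if df["site"].nunique() != 1:
        raise ValueError("plot-level multi-trait fit expects a single site")
    ids = sorted(df["accession"].unique())
    sub = grm.subset([i for i in ids if i in set(grm.line_ids)])
    acc_pos = {a: i for i, a in enumerate(sub.line_ids)}
    rows = sorted(df["row"].unique())
    cols = sorted(df["col"].unique())
    row_pos = {r: i for i, r in enumerate(rows)}
    col_pos = {c: i for i, c in enumerate(cols)}
    rec_unit, rec_trait, rec_y, rec_acc, rec_row, rec_col, rec_rep = [], [], [], [], [], [], []
    for i, row in df.iterrows():
        for j, tr in enumerate(traits):
            v = row[tr]
            if pd.notna(v):
                rec_unit.append(i)
                rec_trait.append(j)
                rec_y.append(float(v))
                rec_acc.append(acc_pos[row["accession"]])
                rec_row.append(row_pos[row["row"]])
                rec_col.append(col_pos[row["col"]])
                rec_rep.append(row["rep"])
    yv = np.array(rec_y)
    trait_idx = np.array(rec_trait)
    unit = np.array(rec_unit)
    reps = sorted(set(rec_rep))
    # trait-specific intercept and replicate effects
    Xcols = []
    for j in range(t):
        Xcols.append((trait_idx == j).astype(float))
    for j in range(t):
        for rp in reps[1:]:
            Xcols.append(((trait_idx == j) & (np.array(rec_rep) == rp)).astype(float))
    X = np.column_stack(Xcols)
    terms = [
        VarTerm("additive", sub.values, np.array(rec_acc), "full",
                None if T0 is None else np.asarray(T0, float)),
        VarTerm("row", np.eye(len(rows)), np.array(rec_row), "diag"),
        VarTerm("col", np.eye(len(cols)), np.array(rec_col), "diag"),
    ]
    fit = dense_reml(yv, X, trait_idx, unit, terms, t, R0=R0)
    T = terms[0].theta
    U = np.empty((sub.n, t))
    for k in range(t):
        U[:, k] = sub.values[:, np.array(rec_acc)] @ (T[k, trait_idx] * fit.w)
    U = U - U.mean(axis=0)
    comps = CovarianceComponents(
        traits, T, fit.Rres, fit.log_likelihood,
        sigma2_row=np.diag(terms[1].theta).copy(),
        sigma2_col=np.diag(terms[2].theta).copy(),
        param_cov=fit.param_cov,
    )
    comps.ll_path = fit.ll_path  # type: ignore[attr-defined]
    gebv = pd.DataFrame(
        {
            "accession": np.repeat(sub.line_ids, t),
            "trait": np.tile(traits, sub.n),
            "gebv": U.reshape(-1),
        }
    )
    corrs = [
        CorrelationEstimate(a, b, comps.r_A(a, b), comps.r_P(a, b))
        for ai, a in enumerate(traits)
        for b in traits[ai + 1:]
    ]
    return comps, gebv, corrs


def fit_gxe(
    blues: pd.DataFrame,
    grm: GRM,
    trait: str | None = None,
    value_col: str = "estimate",
    fix_gxe_zero: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Single-trait multi-environment GBLUP with a g x E interaction term.

    y = site (fixed) + g (cov G sA2) + gE (cov blockdiag_site(G) sgxe2) + e.
    ``blues`` is long with columns site, accession and the value column (and
    optionally a trait column filtered by ``trait``).  Returns the variance
    components {sigma2_A, sigma2_gxe, sigma2_e, log_likelihood} and a GEBV
    table holding the across-site main effects plus per-site gE deviations.
    """
    df = blues
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    df = df.dropna(subset=[value_col]).reset_index(drop=True)
    sites = list(df["site"].unique())
    if len(sites) < 2:
        raise ValueError("fit_gxe needs >= 2 sites; use fit_univariate for one site")
    ids = sorted(df["accession"].unique())
    sub = grm.subset(ids)
    acc_pos = {a: i for i, a in enumerate(sub.line_ids)}
    site_pos = {s: i for i, s in enumerate(sites)}
    acc = df["accession"].map(acc_pos).to_numpy()
    sit = df["site"].map(site_pos).to_numpy()
    yv = df[value_col].to_numpy(float)
    n = len(yv)
    X = np.zeros((n, len(sites)))
    X[np.arange(n), sit] = 1.0
    G = sub.values
    K2 = G[np.ix_(acc, acc)] * (sit[:, None] == sit[None, :])
    terms = [
        VarTerm("additive", G, acc, "full"),
        VarTerm("gxe", K2, np.arange(n), "full"),
    ]
    if fix_gxe_zero:
        terms = [terms[0]]
    fit = dense_reml(yv, X, np.zeros(n, int), np.arange(n), terms, 1)
    sA2 = float(terms[0].theta[0, 0])
    sgxe2 = float(terms[1].theta[0, 0]) if not fix_gxe_zero else 0.0
    se2 = float(fit.Rres[0, 0])
    main = G @ np.bincount(acc, weights=sA2 * fit.w, minlength=sub.n)
    main -= main.mean()
    rows = [
        {"accession": a, "trait": trait or value_col, "site": None, "gebv": main[i]}
        for i, a in enumerate(sub.line_ids)
    ]
    if not fix_gxe_zero:
        for s, si in site_pos.items():
            m = sit == si
            dev = G[:, acc[m]] @ (sgxe2 * fit.w[m])
            for i, a in enumerate(sub.line_ids):
                rows.append({"accession": a, "trait": trait or value_col,
                             "site": s, "gebv": dev[i]})
    comps = {
        "sigma2_A": sA2,
        "sigma2_gxe": sgxe2,
        "sigma2_e": se2,
        "log_likelihood": fit.log_likelihood,
    }
    return comps, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conditional prediction (used by cross-validation)


def mt_predict_target(
    T: np.ndarray,
    R: np.ndarray,
    trait_names: list[str],
    target: str,
    G: GRM,
    obs: pd.DataFrame,
    predict_ids: list[str],
) -> np.ndarray:
    """Conditional mean of the target-trait breeding value for ``predict_ids``.

    ``obs`` is long (accession, trait, estimate) with the records visible to
    the model.  Fixed effects are per-trait means estimated by GLS under
    (T, R); prediction uses cov(g_target, y_obs) = T[target, trait_j] *
    G[pred, acc_j].
    """
    tpos = {tr: i for i, tr in enumerate(trait_names)}
    obs = obs.dropna(subset=["estimate"])
    acc_ids = list(dict.fromkeys(list(obs["accession"]) + list(predict_ids)))
    sub = G.subset(acc_ids)
    pos = {a: i for i, a in enumerate(sub.line_ids)}
    aj = obs["accession"].map(pos).to_numpy()
    tj = obs["trait"].map(tpos).to_numpy()
    yv = obs["estimate"].to_numpy(float)
    n = len(yv)
    t = len(trait_names)
    Gm = sub.values
    V = T[np.ix_(tj, tj)] * Gm[np.ix_(aj, aj)] + R[np.ix_(tj, tj)] * (aj[:, None] == aj[None, :])
    X = np.zeros((n, t))
    X[np.arange(n), tj] = 1.0
    keep = X.sum(axis=0) > 0
    X = X[:, keep]
    L = np.linalg.cholesky(V + 1e-10 * np.mean(np.diag(V)) * np.eye(n))
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, yv)
    beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    w = np.linalg.solve(L.T, ys - Xs @ beta)
    k = tpos[target]
    pidx = np.array([pos[a] for a in predict_ids])
    C = T[k, tj] * Gm[np.ix_(pidx, aj)]
    return C @ w
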