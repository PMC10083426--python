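"""Synthetic genotypes and multi-site field-trial phenotypes.

The generator mirrors the structure of a diverse-panel genomic-selection
study: a few hundred inbred-ish accessions scored at thousands of biallelic
SNPs, evaluated at several sites in replicated row-column field trials.
Phenotypes decompose as

    y(plot) = site mean + g (additive) + gE (site x accession) +
              row + column + spatial residual,

where the additive values ``g`` across traits have covariance ``T_target``,
the plot residual has marginal trait covariance ``R_target`` with a separable
AR1(rho_row) x AR1(rho_col) spatial correlation over the plot grid, and gE is
an independent site-specific deviation of each accession's genetic effect.

Marker effects are drawn i.i.d. normal and then rescaled so that the sample
covariance of the true breeding values equals ``T_target`` exactly; recovery
tests downstream are therefore sharp rather than subject to Monte-Carlo drift
in the truth itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "GenotypeMatrix",
    "TrueEffects",
    "default_params",
    "scaled_params",
    "simulate_genotypes",
    "simulate_true_effects",
    "simulate_trial",
    "simulate_accession_means",
]

TRIAL_COLUMNS = ("site", "rep", "row", "col", "accession")


def _as_cov(M, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be a symmetric square matrix")
    return 0.5 * (M + M.T)


def _require_pd(M: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(M)
    if w.min() <= 0:
        raise ValueError(f"{name} must be positive-definite (min eigenvalue {w.min():.3g})")


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Lower factor L with L L' = M for a PSD matrix (eigen-based, exact at 0)."""
    w, V = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


@dataclass(frozen=True)
class SimParams:
    """All knobs of the generative model.

    ``site_means`` is (n_sites, n_traits); ``T_target`` / ``R_target`` are the
    additive-genetic and plot-residual trait covariance matrices (trait
    units^2).  ``sigma2_gxe`` may be a scalar (shared across traits) or a
    per-trait vector.  A replicate occupies a contiguous block of columns of
    the ``layout_rows`` x ``layout_cols`` field.
    """

    n_lines: int
    n_markers: int
    seed: int
    traits: tuple[str, ...] = ("GY",)
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_sites: int = 1
    site_names: tuple[str, ...] | None = None
    site_means: np.ndarray | None = None
    T_target: np.ndarray = field(default_factory=lambda: np.eye(1))
    R_target: np.ndarray = field(default_factory=lambda: np.eye(1))
    rho_row: float = 0.0
    rho_col: float = 0.0
    sigma2_row: float = 0.0
    sigma2_col: float = 0.0
    sigma2_gxe: float | np.ndarray = 0.0
    n_reps: int = 2
    layout_rows: int | None = None
    layout_cols: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 2 or self.n_markers < 1:
            raise ValueError("need n_lines >= 2 and n_markers >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not (abs(self.rho_row) < 1 and abs(self.rho_col) < 1):
            raise ValueError("AR1 autocorrelations must have |rho| < 1")
        t = len(self.traits)
        T = _as_cov(self.T_target, "T_target")
        R = _as_cov(self.R_target, "R_target")
        if T.shape[0] != t or R.shape[0] != t:
            raise ValueError("T_target/R_target dimension must match traits")
        _require_pd(T, "T_target")
        if np.linalg.eigvalsh(R).min() < -1e-12:
            raise ValueError("R_target must be positive semi-definite")
        object.__setattr__(self, "T_target", T)
        object.__setattr__(self, "R_target", R)
        if self.site_names is None:
            object.__setattr__(
                self, "site_names", tuple(f"S{i + 1}" for i in range(self.n_sites))
            )
        if len(self.site_names) != self.n_sites:
            raise ValueError("site_names length must equal n_sites")
        if self.site_means is None:
            object.__setattr__(self, "site_means", np.zeros((self.n_sites, t)))
        sm = np.atleast_2d(np.asarray(self.site_means, dtype=float))
        if sm.shape != (self.n_sites, t):
            raise ValueError("site_means must be (n_sites, n_traits)")
        object.__setattr__(self, "site_means", sm)
        g = np.broadcast_to(np.asarray(self.sigma2_gxe, dtype=float).ravel(), (t,)).copy() \
            if np.ndim(self.sigma2_gxe) else np.full(t, float(self.sigma2_gxe))
        if (g < 0).any():
            raise ValueError("sigma2_gxe must be non-negative")
        object.__setattr__(self, "sigma2_gxe", g)
        if self.sigma2_row < 0 or self.sigma2_col < 0:
            raise ValueError("row/column variances must be non-negative")
        # default layout: square-ish grid, replicates side by side
        if self.layout_rows is None or self.layout_cols is None:
            rows = int(np.ceil(np.sqrt(self.n_lines)))
            cols_per_rep = int(np.ceil(self.n_lines / rows))
            object.__setattr__(self, "layout_rows", rows)
            object.__setattr__(self, "layout_cols", cols_per_rep * self.n_reps)
        cols_per_rep = self.layout_cols // self.n_reps
        if cols_per_rep * self.layout_rows < self.n_lines:
            raise ValueError(
                f"layout {self.layout_rows}x{self.layout_cols} with {self.n_reps} "
                f"replicates cannot hold {self.n_lines} accessions per replicate"
            )

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


def default_params(seed: int = 0) -> SimParams:
    """The study-scale default: 349 accessions x 6,911 SNPs, 4 sites, 2 reps.

    Focal traits GY (grain yield, t/ha), PH (plant height, cm), DF (days to
    flowering, d), OL (seed oil content, %).  Genetic variances follow the
    optimal-site estimates (GY 0.68, PH 176, DF 9.6, OL 11.7) with moderate
    GY-PH genetic correlation (0.45) and weak GY-DF (0.1) / GY-OL (0.19);
    residual variances 0.56 / 62 / 3.6 / 3.1.  Site means are set so a ~0.7
    t/ha yield gain at the optimal site corresponds to roughly a 23% increase.
    """
    traits = ("GY", "PH", "DF", "OL")
    sg = np.sqrt(np.array([0.682, 176.286, 9.621, 11.730]))
    Cg = np.array(
        [
            [1.00, 0.45, 0.10, 0.19],
            [0.45, 1.00, 0.20, 0.00],
            [0.10, 0.20, 1.00, 0.00],
            [0.19, 0.00, 0.00, 1.00],
        ]
    )
    T = np.outer(sg, sg) * Cg
    se = np.sqrt(np.array([0.557, 61.840, 3.594, 3.067]))
    Ce = np.eye(4)
    Ce[0, 1] = Ce[1, 0] = 0.2
    R = np.outer(se, se) * Ce
    site_means = np.array(
        [
            [3.0, 105.0, 100.0, 30.0],  # irrigated, optimal
            [1.7, 95.0, 97.0, 29.0],  # rainfed, flowering-stage stress
            [1.0, 75.0, 92.0, 27.0],  # low-rainfall zone
            [1.1, 80.0, 93.0, 28.0],  # high-rainfall zone
        ]
    )
    return SimParams(
        n_lines=349,
        n_markers=6911,
        seed=seed,
        traits=traits,
        maf_range=(0.02, 0.5),
        missing_rate=0.1,
        n_sites=4,
        site_names=("IR", "RF", "LR", "HR"),
        site_means=site_means,
        T_target=T,
        R_target=R,
        rho_row=0.4,
        rho_col=0.4,
        sigma2_row=0.1 * 0.557,
        sigma2_col=0.1 * 0.557,
        sigma2_gxe=0.3 * np.diag(T),
        n_reps=2,
        layout_rows=20,
        layout_cols=36,
    )


def scaled_params(
    seed: int,
    n_lines: int = 100,
    n_markers: int = 500,
    n_sites: int = 3,
    n_reps: int = 2,
    missing_rate: float = 0.05,
) -> SimParams:
    """The default generative model at a reduced problem size.

    Trait structure (covariances, spatial parameters, site means) is that of
    :func:`default_params`; only the panel size, marker count, number of sites
    and missingness change.  Used by the toy pipeline and the test suite.
    """
    base = default_params(seed)
    rows = int(np.ceil(np.sqrt(n_lines)))
    cols_per_rep = int(np.ceil(n_lines / rows))
    return replace(
        base,
        n_lines=n_lines,
        n_markers=n_markers,
        n_sites=n_sites,
        site_names=base.site_names[:n_sites],
        site_means=base.site_means[:n_sites],
        missing_rate=missing_rate,
        n_reps=n_reps,
        layout_rows=rows,
        layout_cols=cols_per_rep * n_reps,
    )


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dosage table with a missing mask.

    ``dosages`` holds counts of the alternate allele in {0, 1, 2}; entries
    flagged in ``missing_mask`` are unobserved (their dosage value is
    meaningless and set to -1).  After mean imputation dosages may be
    continuous; such matrices carry ``continuous=True``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    continuous: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lengths inconsistent with dosage matrix")
        if len(set(self.line_ids)) != n or len(set(self.marker_ids)) != m:
            raise ValueError("line/marker ids must be unique")
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape mismatch")
        obs = self.dosages[~self.missing_mask]
        if not self.continuous and obs.size and not np.isin(obs, (0, 1, 2)).all():
            raise ValueError("observed dosages must be in {0, 1, 2}")
        if self.continuous and obs.size and ((obs < 0).any() or (obs > 2).any()):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def filled(self, fill: np.ndarray | float | None = None) -> np.ndarray:
        """Float dosage matrix with missing entries replaced (default: marker mean)."""
        X = self.dosages.astype(float)
        if not self.missing_mask.any():
            return X
        if fill is None:
            obs = np.where(self.missing_mask, np.nan, X)
            fill = np.nanmean(obs, axis=0)
        X = np.where(self.missing_mask, np.broadcast_to(fill, X.shape), X)
        return X


@dataclass
class TrueEffects:
    """Latent truth retained for parameter-recovery tests."""

    traits: tuple[str, ...]
    line_ids: list[str]
    g: np.ndarray  # (n_lines, n_traits) additive values, sample cov == T_target
    gE: dict[str, np.ndarray]  # site -> (n_lines, n_traits) deviations
    marker_effects: np.ndarray  # (n_markers, n_traits) on the rescaled scale

    def g_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.g, index=self.line_ids, columns=list(self.traits))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genotypes(params: SimParams) -> GenotypeMatrix:
    """Independent biallelic markers under Hardy-Weinberg sampling.

    Per-marker allele frequencies are uniform on ``maf_range``; dosages are
    Binomial(2, p) per line; missingness is applied per call, completely at
    random at ``missing_rate``.
    """
    rng = _rng(params.seed, 1)
    p = rng.uniform(params.maf_range[0], params.maf_range[1], size=params.n_markers)
    dosages = rng.binomial(2, p, size=(params.n_lines, params.n_markers)).astype(np.int8)
    if params.missing_rate > 0:
        mask = rng.random((params.n_lines, params.n_markers)) < params.missing_rate
    else:
        mask = np.zeros((params.n_lines, params.n_markers), dtype=bool)
    dosages = np.where(mask, np.int8(-1), dosages)
    line_ids = [f"L{i + 1:04d}" for i in range(params.n_lines)]
    marker_ids = [f"M{j + 1:06d}" for j in range(params.n_markers)]
    return GenotypeMatrix(line_ids, marker_ids, dosages, mask)


def simulate_true_effects(genotypes: GenotypeMatrix, params: SimParams) -> TrueEffects:
    """Additive breeding values and site-specific interaction deviations.

    Breeding values are sums of i.i.d. normal marker effects over centred
    dosages, linearly rescaled so the realized (sample) covariance of ``g``
    across lines equals ``T_target`` exactly.  gE deviations are themselves
    genetic — independent marker-effect draws per site, rescaled to variance
    ``sigma2_gxe`` per trait — so their covariance across accessions follows
    the realized genomic relationship within each site, as an interaction
    between site and additive genetic effects should.
    """
    _require_pd(params.T_target, "T_target")
    rng = _rng(params.seed, 2)
    t = params.n_traits
    X = genotypes.filled()
    W = X - X.mean(axis=0)
    B = rng.standard_normal((genotypes.n_markers, t))
    U = W @ B
    U -= U.mean(axis=0)
    C = np.cov(U, rowvar=False, ddof=1).reshape(t, t)
    _require_pd(C, "raw breeding-value covariance (need n_lines > n_traits)")
    Lc = np.linalg.cholesky(C)
    Lt = np.linalg.cholesky(params.T_target)
    A = np.linalg.solve(Lc, np.eye(t)).T @ Lt.T  # U @ A has sample cov T exactly
    g = U @ A
    gE: dict[str, np.ndarray] = {}
    sd = np.sqrt(params.sigma2_gxe)
    for s in params.site_names:
        Bs = rng.standard_normal((genotypes.n_markers, t))
        Us = W @ Bs
        Us -= Us.mean(axis=0)
        scale = Us.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        gE[s] = Us / scale * sd
    return TrueEffects(params.traits, list(genotypes.line_ids), g, gE, B @ A)


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    C = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(C + 1e-12 * np.eye(n)) if abs(rho) > 0 else np.eye(n)


def simulate_trial(
    genotypes: GenotypeMatrix, effects: TrueEffects, params: SimParams
) -> pd.DataFrame:
    """Plot-level multi-site trial table.

    Returns a tidy frame with columns site, rep, row, col, accession and one
    column per trait.  Each replicate occupies a contiguous block of columns;
    accessions are completely randomized within replicate.  The plot residual
    field is drawn from the separable AR1 x AR1 process with marginal trait
    covariance ``R_target``.
    """
    rng = _rng(params.seed, 3)
    t = params.n_traits
    nr, nc = params.layout_rows, params.layout_cols
    cols_per_rep = nc // params.n_reps
    if cols_per_rep * nr < params.n_lines:
        raise ValueError("field layout too small for one replicate of all accessions")
    g_lookup = {lid: effects.g[i] for i, lid in enumerate(effects.line_ids)}
    Lr = _ar1_chol(nr, params.rho_row)
    Lc = _ar1_chol(nc, params.rho_col)
    L_traits = _psd_factor(params.R_target)
    records: list[dict] = []
    for si, site in enumerate(params.site_names):
        row_eff = rng.standard_normal((nr, t)) * np.sqrt(params.sigma2_row)
        col_eff = rng.standard_normal((nc, t)) * np.sqrt(params.sigma2_col)
        # separable spatial field with unit marginal variance, then trait mixing
        Z = rng.standard_normal((nr, nc, t))
        field_ = np.einsum("ab,bcs->acs", Lr, np.einsum("cd,ads->acs", Lc, Z))
        eps = field_ @ L_traits.T
        ge = effects.gE[site]
        for rep in range(params.n_reps):
            order = rng.permutation(params.n_lines)
            c0 = rep * cols_per_rep
            for k, li in enumerate(order):
                r, c = divmod(k, cols_per_rep)
                c += c0
                lid = effects.line_ids[li]
                val = (
                    params.site_means[si]
                    + g_lookup[lid]
                    + ge[li]
                    + row_eff[r]
                    + col_eff[c]
                    + eps[r, c]
                )
                rec = {
                    "site": site,
                    "rep": rep + 1,
                    "row": r + 1,
                    "col": c + 1,
                    "accession": lid,
                }
                rec.update({tr: val[j] for j, tr in enumerate(params.traits)})
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    dup = df.duplicated(subset=["site", "row", "col"])
    assert not dup.any(), "internal error: plot coordinates collide"
    return df


def simulate_accession_means(
    genotypes: GenotypeMatrix,
    effects: TrueEffects,
    params: SimParams,
    sites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Accession-level phenotypes (stage-2 input) bypassing the field layer.

    For each requested site, returns site mean + g + gE + e with e drawn i.i.d.
    per accession from N(0, R_target).  This is what stage-1 BLUEs estimate;
    it lets stage-2 models be exercised at scale without refitting the spatial
    stage.  Long format: site, accession, one column per trait.
    """
    rng = _rng(params.seed, 4)
    sites = list(params.site_names) if sites is None else list(sites)
    L = _psd_factor(params.R_target)
    frames = []
    for site in sites:
        si = params.site_names.index(site)
        e = rng.standard_normal((genotypes.n_lines, params.n_traits)) @ L.T
        vals = params.site_means[si] + effects.g + effects.gE[site] + e
        df = pd.DataFrame(vals, columns=list(params.traits))
        df.insert(0, "accession", effects.line_ids)
        df.insert(0, "site", site)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
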