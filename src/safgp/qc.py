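"""Marker QC, missing-genotype imputation, and the genomic relationship matrix.

Filtering follows the usual GBS panel rules — drop markers with a missing-call
rate of 50% or more, or a minor allele frequency of 0.01 or less (both
inequalities strict on the retained side) — and the relationship matrix is
VanRaden's method 1 with observed allele frequencies:

    G = W W' / (2 * sum_j p_j (1 - p_j)),   W_ij = x_ij - 2 p_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import GenotypeMatrix

__all__ = [
    "MarkerStats",
    "GRM",
    "compute_marker_stats",
    "filter_markers",
    "impute_missing",
    "vanraden_grm",
    "condition_grm",
]


@dataclass(frozen=True)
class MarkerStats:
    marker_id: str
    missing_rate: float
    maf: float  # NaN when no call observed


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over accessions."""

    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square over line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def subset(self, ids: list[str]) -> "GRM":
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"{len(missing)} ids absent from GRM (e.g. {missing[0]!r})")
        idx = np.array([pos[i] for i in ids])
        return GRM(list(ids), self.values[np.ix_(idx, idx)])


def compute_marker_stats(geno: GenotypeMatrix) -> list[MarkerStats]:
    """Per-marker missing-call rate and minor allele frequency.

    MAF uses non-missing calls only: p = (dosage sum)/(2 * n_obs), maf =
    min(p, 1-p).  An all-missing marker is flagged with missing_rate 1 and
    maf = NaN rather than dropped.
    """
    n = geno.n_lines
    miss = geno.missing_mask.sum(axis=0)
    obs = n - miss
    dos = np.where(geno.missing_mask, 0, geno.dosages).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(obs > 0, dos / (2.0 * np.maximum(obs, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return [
        MarkerStats(mid, miss[j] / n, float(maf[j]) if obs[j] > 0 else float("nan"))
        for j, mid in enumerate(geno.marker_ids)
    ]


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.5, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Retain markers with missing_rate < max_missing and maf > min_maf.

    Both comparisons are strict; marker order and the line set are preserved.
    Raises if nothing survives.
    """
    stats = compute_marker_stats(geno)
    keep = np.array(
        [s.missing_rate < max_missing and np.nan_to_num(s.maf, nan=-1.0) > min_maf
         for s in stats]
    )
    if not keep.any():
        raise ValueError("no markers pass the QC thresholds (empty panel)")
    return GenotypeMatrix(
        list(geno.line_ids),
        [m for m, k in zip(geno.marker_ids, keep) if k],
        geno.dosages[:, keep],
        geno.missing_mask[:, keep],
        continuous=geno.continuous,
    )


def impute_missing(geno: GenotypeMatrix, method: str = "mean_dosage", k: int = 5) -> GenotypeMatrix:
    """Fill missing calls; observed calls are never altered.

    ``mean_dosage`` fills each gap with the marker's mean observed dosage (a
    continuous value, stored separately from the integer calls), the standard
    centring-compatible filler for GRM construction.  ``knn`` fills with the
    modal dosage among the k lines most similar to the target line over their
    shared non-missing markers (similarity = mean absolute dosage agreement).
    """
    all_missing = geno.missing_mask.all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        raise ValueError(f"marker {geno.marker_ids[j]!r} has no observed calls; cannot impute")
    if not geno.missing_mask.any():
        return GenotypeMatrix(
            list(geno.line_ids), list(geno.marker_ids),
            geno.dosages.copy(), geno.missing_mask.copy(),
            continuous=geno.continuous,
        )
    X = geno.dosages.astype(float)
    mask = geno.missing_mask
    if method == "mean_dosage":
        filled = geno.filled()
    elif method == "knn":
        filled = X.copy()
        obs = ~mask
        Xz = np.where(obs, X, 0.0)
        n = geno.n_lines
        # pairwise mean |dosage difference| over shared observed markers
        for i in np.where(mask.any(axis=1))[0]:
            shared = obs & obs[i]
            cnt = shared.sum(axis=1)
            diff = np.abs(Xz - Xz[i]) * shared
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(cnt > 0, diff.sum(axis=1) / np.maximum(cnt, 1), np.inf)
            dist[i] = np.inf
            order = np.argsort(dist, kind="stable")
            for j in np.where(mask[i])[0]:
                donors = [o for o in order if obs[o, j] and np.isfinite(dist[o])][:k]
                if not donors:
                    filled[i, j] = np.nanmean(np.where(obs[:, j], X[:, j], np.nan))
                else:
                    vals = X[donors, j].astype(int)
                    counts = np.bincount(vals, minlength=3)
                    filled[i, j] = float(np.argmax(counts))  # tie -> lowest dosage
        filled = np.where(mask, filled, X)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return GenotypeMatrix(
        list(geno.line_ids),
        list(geno.marker_ids),
        np.where(mask, filled, X),
        np.zeros_like(mask),
        continuous=True,
    )


def vanraden_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM from a fully imputed dosage matrix.

    Monomorphic markers contribute nothing to either W or the denominator.
    """
    if geno.missing_mask.any():
        raise ValueError("GRM requires imputed genotypes (no missing calls)")
    X = geno.dosages.astype(float)
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    return GRM(list(geno.line_ids), G)


def condition_grm(grm: GRM, epsilon: float = 1e-6) -> GRM:
    """Add a small ridge to the diagonal so the GRM is safely invertible."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not np.allclose(grm.values, grm.values.T, atol=1e-8):
        raise ValueError("condition_grm requires a symmetric matrix")
    return GRM(list(grm.line_ids), grm.values + epsilon * np.eye(grm.n))
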