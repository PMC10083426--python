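"""Selection indices, truncation selection and the breeder's-equation response.

Six index families are compared for grain-yield (and oil) selection:

* PS     — phenotypic selection on the trait BLUEs;
* SGS    — GEBVs from the univariate GBLUP;
* MGS    — target-trait GEBVs from the multi-trait GBLUP;
* MTGS1  — equal weights on standardized GEBVs of two traits;
* MTGS2  — Smith-Hazel weights b = P^-1 g on raw GEBVs, where P is the
  phenotypic variance-covariance matrix and g the vector of additive genetic
  variances (raw scores because b already carries units);
* gxEGS / gxEMTGS1 — the same built from the across-site main-effect GEBVs of
  the g x E model.

Selection takes the top floor(0.2 n) accessions (ties broken by ascending
accession id); the response is R = h2 * S with S the selection differential,
and the percentage gain is 100 * R / (evaluation-site population mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "SelectionReport",
    "standardize",
    "smith_hazel_weights",
    "build_index",
    "select_top_fraction",
    "selection_response",
    "cross_site_response",
]

INDEX_LABELS = ("PS", "SGS", "MGS", "MTGS1", "MTGS2", "gxEGS", "gxEMTGS1")


@dataclass(frozen=True)
class IndexSpec:
    label: str
    traits: tuple[str, ...]
    weights: tuple[float, ...]
    standardized: bool
    source: str  # BLUE | GEBV_UV | GEBV_MT | GEBV_gxE

    def __post_init__(self) -> None:
        if self.label not in INDEX_LABELS:
            raise ValueError(f"unknown index label {self.label!r}")
        if len(self.traits) != len(self.weights):
            raise ValueError("one weight per trait required")
        if not np.isfinite(self.weights).all():
            raise ValueError("index weights must be finite")
        if self.label == "MTGS1" and len(set(self.weights)) != 1:
            raise ValueError("MTGS1 uses equal weights")
        if self.label == "PS" and self.source != "BLUE":
            raise ValueError("PS operates on BLUEs")


@dataclass(frozen=True)
class SelectionReport:
    index_label: str
    selection_site: str
    evaluation_site: str
    trait: str
    selected: tuple[str, ...]
    S: float
    R: float
    percent_gain: float
    h2: float
    n_excluded: int = 0


def standardize(values: pd.Series | np.ndarray) -> pd.Series:
    """Z-scores with the sample SD (n-1); mean 0, SD 1 on output."""
    s = pd.Series(values, dtype=float)
    if s.nunique() < 2:
        raise ValueError("standardize requires >= 2 distinct values")
    return (s - s.mean()) / s.std(ddof=1)


def smith_hazel_weights(P: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Smith-Hazel index weights b solving P b = g.

    P is the phenotypic variance-covariance matrix of the index traits and g
    the vector of their additive genetic variances.
    """
    P = np.asarray(P, float)
    g = np.asarray(g, float).ravel()
    if P.shape != (g.size, g.size):
        raise ValueError("P must be square and conformable with g")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("P must be symmetric")
    try:
        return np.linalg.solve(P, g)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"phenotypic covariance matrix is singular: {exc}")


def build_index(scores: pd.DataFrame, spec: IndexSpec) -> pd.Series:
    """Linear combination of per-trait scores (accession x trait frame).

    Traits are standardized first when the spec says so (MTGS1); Smith-Hazel
    weights are applied to raw scores.
    """
    missing = [t for t in spec.traits if t not in scores.columns]
    if missing:
        raise KeyError(f"missing trait scores: {missing}")
    sub = scores[list(spec.traits)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)][0]
        raise ValueError(f"accession {bad!r} lacks a score for an index trait")
    out = pd.Series(0.0, index=scores.index)
    for tr, wgt in zip(spec.traits, spec.weights):
        col = standardize(sub[tr]) if spec.standardized else sub[tr].astype(float)
        out = out + wgt * col
    out.name = spec.label
    return out


def select_top_fraction(index: pd.Series, fraction: float = 0.2) -> list[str]:
    """Ids of the floor(fraction * n) highest-scoring accessions.

    Ties at the cutoff are broken by ascending accession id, so the selected
    set is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_sel = int(np.floor(fraction * len(index)))
    if n_sel == 0:
        raise ValueError("selection fraction rounds down to zero accessions")
    order = sorted(index.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [k for k, _ in order[:n_sel]]


def selection_response(
    population: pd.Series,
    selected: list[str],
    h2: float,
    site_mean: float | None = None,
    index_label: str = "",
    selection_site: str = "",
    evaluation_site: str = "",
    trait: str = "",
) -> SelectionReport:
    """Breeder's-equation response for a selected set on evaluation values.

    S = mean(selected) - mean(all); R = h2 * S; percent gain = 100 R / mean.
    ``population`` holds every accession's evaluation value (BLUEs at the
    evaluation site); ``site_mean`` defaults to its mean.
    """
    if len(selected) == 0:
        raise ValueError("selected set is empty")
    sel = [s for s in selected if s in population.index]
    n_excluded = len(selected) - len(sel)
    if not sel:
        raise ValueError("no selected accession has an evaluation value")
    S = float(population.loc[sel].mean() - population.mean())
    R = h2 * S
    mean = float(population.mean()) if site_mean is None else float(site_mean)
    pct = 100.0 * R / mean if mean != 0 else float("nan")
    return SelectionReport(
        index_label, selection_site, evaluation_site or selection_site, trait,
        tuple(sel), S, R, pct, h2, n_excluded,
    )


def cross_site_response(
    selection_site: str,
    index_values: pd.Series,
    evaluation: dict[str, pd.Series],
    h2_by_site: dict[str, float],
    fraction: float = 0.2,
    index_label: str = "",
    trait: str = "",
) -> list[SelectionReport]:
    """Score ONE selected set (chosen at ``selection_site``) at several sites.

    ``evaluation`` maps each evaluation site to its per-accession values
    (e.g. BLUEs); each site uses its own univariate h2.  Selected accessions
    missing at an evaluation site are excluded from that site's means and
    counted in the report.
    """
    selected = select_top_fraction(index_values, fraction)
    reports = []
    for site, values in evaluation.items():
        reports.append(
            selection_response(
                values.dropna(), selected, h2_by_site[site],
                index_label=index_label, selection_site=selection_site,
                evaluation_site=site, trait=trait,
            )
        )
    return reports


def reports_frame(reports: list[SelectionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": r.index_label,
                "selection_site": r.selection_site,
                "evaluation_site": r.evaluation_site,
                "trait": r.trait,
                "n_selected": len(r.selected),
                "S": r.S,
                "R": r.R,
                "percent_gain": r.percent_gain,
                "h2": r.h2,
                "n_excluded": r.n_excluded,
            }
            for r in reports
        ]
    )
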