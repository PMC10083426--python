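"""Five-fold x five-repeat cross-validated genomic prediction accuracy.

Accuracy is the Pearson correlation between validation-set GEBVs and the
held-out target-trait BLUEs (no disattenuation by sqrt(h2)).  Two multivariate
scenarios are distinguished:

* CV1 — validation accessions keep their secondary-trait BLUEs; only the
  target trait is masked.  The model can borrow information from the observed
  secondary phenotypes of the very accessions being predicted.
* CV2 — validation accessions are masked for every trait; only the genomic
  relationship links them to the training set.

Variance components are re-estimated inside every training fold from the
records visible under the scenario, so no information leaks from the
validation target values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GRM
from . import reml

__all__ = ["FoldPlan", "AccuracyResult", "make_folds", "run_cv", "summarize_accuracy"]


@dataclass(frozen=True)
class FoldPlan:
    k: int
    repeats: int
    seed: int
    membership: pd.DataFrame  # columns: repeat, fold, accession

    def fold_ids(self, repeat: int, fold: int) -> list[str]:
        m = self.membership
        sel = m[(m["repeat"] == repeat) & (m["fold"] == fold)]
        return list(sel["accession"])


@dataclass(frozen=True)
class AccuracyResult:
    model: str
    scenario: str
    accuracies: np.ndarray  # (repeats * k,)
    detail: pd.DataFrame  # repeat, fold, accuracy

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def make_folds(accessions: list[str], k: int = 5, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded shuffle split into k near-equal folds, repeated ``repeats`` times."""
    accessions = list(accessions)
    n = len(accessions)
    if n < k:
        raise ValueError(f"cannot split {n} accessions into {k} folds")
    if len(set(accessions)) != n:
        raise ValueError("accession ids must be unique")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    rows = []
    for rep in range(1, repeats + 1):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, idx in enumerate(folds, start=1):
            for i in idx:
                rows.append((rep, f, accessions[i]))
    return FoldPlan(k, repeats, int(seed), pd.DataFrame(rows, columns=["repeat", "fold", "accession"]))


def summarize_accuracy(accs) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1) of per-fold accuracies."""
    accs = np.asarray(accs, float)
    if accs.size < 2:
        raise ValueError("need at least 2 accuracy values")
    return float(accs.mean()), float(accs.std(ddof=1))


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_cv(
    blues: pd.DataFrame,
    grm: GRM,
    plan: FoldPlan,
    model: str = "UV",
    scenario: str = "CV1",
    target: str = "GY",
    secondary: list[str] | None = None,
) -> AccuracyResult:
    """Cross-validated prediction accuracy for the target trait at one site.

    ``blues`` is wide (accession + trait columns) or long (accession, trait,
    estimate).  Accessions lacking a target BLUE are excluded before folding
    (the plan must have been built on the same accession set).  ``model`` is
    "UV" (univariate GBLUP) or "MT" (multi-trait with ``secondary``).
    """
    if model not in ("UV", "MT"):
        raise ValueError("model must be UV or MT")
    if scenario not in ("CV1", "CV2"):
        raise ValueError("scenario must be CV1 or CV2")
    secondary = list(secondary or [])
    if model == "MT" and not secondary:
        raise ValueError("MT model requires at least one secondary trait")
    wide = reml._wide(blues, None)
    wide = wide.dropna(subset=[target])
    ids = [a for a in wide.index]
    plan_ids = set(plan.membership["accession"])
    if set(ids) - plan_ids:
        raise ValueError("fold plan does not cover every accession with a target BLUE")
    traits = [target] + secondary
    rows = []
    for rep in sorted(plan.membership["repeat"].unique()):
        for fold in sorted(plan.membership["fold"].unique()):
            val = [a for a in plan.fold_ids(rep, fold) if a in wide.index]
            if len(val) < 3:
                raise ValueError(f"fold {fold} of repeat {rep} has < 3 validation accessions")
            train = [a for a in ids if a not in set(val)]
            y_val = wide.loc[val, target].to_numpy(float)
            if model == "UV":
                tr_df = pd.DataFrame({"accession": train,
                                      "estimate": wide.loc[train, target].to_numpy(float)})
                comps, _ = reml.fit_univariate(tr_df, grm)
                sub = grm.subset(train + val)
                nt = len(train)
                Gm = sub.values
                Vtr = comps.sigma2_A * Gm[:nt, :nt] + comps.sigma2_e * np.eye(nt)
                yt = wide.loc[train, target].to_numpy(float)
                L = np.linalg.cholesky(Vtr)
                ones = np.ones(nt)
                sol = np.linalg.solve(L.T, np.linalg.solve(L, np.column_stack([yt, ones])))
                beta = float(ones @ sol[:, 0]) / float(ones @ sol[:, 1])
                w = np.linalg.solve(L.T, np.linalg.solve(L, yt - beta))
                pred = comps.sigma2_A * Gm[nt:, :nt] @ w
            else:
                sub_wide = wide[traits]
                train_long = sub_wide.loc[train].reset_index().melt(
                    id_vars="accession", var_name="trait", value_name="estimate")
                if scenario == "CV1":
                    val_long = sub_wide.loc[val, secondary].reset_index().melt(
                        id_vars="accession", var_name="trait", value_name="estimate")
                    visible = pd.concat([train_long, val_long], ignore_index=True)
                else:
                    visible = train_long
                comps_tr, _, _ = reml.fit_multitrait(train_long, grm, traits=traits)
                if scenario == "CV1":
                    # a warm start sitting on a correlation cap or variance
                    # floor stalls the dense fit; start cold in that case
                    sd = np.sqrt(np.diag(comps_tr.T))
                    corr = comps_tr.T / np.outer(sd, sd)
                    off = np.abs(corr - np.diag(np.diag(corr))).max()
                    boundary = off > 0.98 or (
                        np.diag(comps_tr.T).min()
                        < 1e-6 * np.diag(comps_tr.T + comps_tr.Rres).max())
                    comps_mt, _, _ = reml.fit_multitrait(
                        visible, grm, traits=traits,
                        T0=None if boundary else comps_tr.T,
                        R0=None if boundary else comps_tr.Rres)
                else:
                    comps_mt = comps_tr
                pred = reml.mt_predict_target(
                    comps_mt.T, comps_mt.Rres, traits, target, grm, visible, val)
            rows.append((rep, fold, _pearson(pred, y_val)))
    detail = pd.DataFrame(rows, columns=["repeat", "fold", "accuracy"])
    label = "UV" if model == "UV" else "MT"
    scen = "UV" if model == "UV" else f"MT-{scenario}"
    return AccuracyResult(label, scen, detail["accuracy"].to_numpy(), detail)
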