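import numpy as np
import pandas as pd
import pytest

from safgp import qc, sim


def make_panel(seed, n_lines, n_markers, traits, T, R, n_sites=1, sigma2_gxe=0.0,
               site_means=None, **kw):
    """Genotypes, true effects, accession-level phenotypes and a conditioned GRM."""
    params = sim.SimParams(
        n_lines=n_lines, n_markers=n_markers, seed=seed, traits=tuple(traits),
        T_target=np.asarray(T, float), R_target=np.asarray(R, float),
        n_sites=n_sites, sigma2_gxe=sigma2_gxe,
        site_means=site_means if site_means is not None else np.zeros((n_sites, len(traits))),
        **kw,
    )
    geno = sim.simulate_genotypes(params)
    eff = sim.simulate_true_effects(geno, params)
    means = sim.simulate_accession_means(geno, eff, params)
    grm = qc.condition_grm(qc.vanraden_grm(qc.impute_missing(geno)))
    return params, geno, eff, means, grm


@pytest.fixture(scope="session")
def small_geno():
    params = sim.SimParams(n_lines=40, n_markers=60, seed=11, missing_rate=0.1)
    return sim.simulate_genotypes(params)


@pytest.fixture(scope="session")
def bivariate_panel():
    """300 lines x 2000 markers, h2 = (0.3, 0.7), rA = 0.5 — shared across tests."""
    T = np.array([[3.0, 0.5 * np.sqrt(21)], [0.5 * np.sqrt(21), 7.0]])
    R = np.array([[7.0, 0.0], [0.0, 3.0]])
    return make_panel(101, 300, 2000, ("t1", "t2"), T, R)


def geno_from_dosages(dosages, line_ids=None, marker_ids=None):
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    mask = dosages < 0
    return sim.GenotypeMatrix(
        line_ids or [f"L{i}" for i in range(n)],
        marker_ids or [f"M{j}" for j in range(m)],
        np.where(mask, -1, dosages).astype(np.int8),
        mask,
    )
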