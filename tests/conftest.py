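import numpy as np
import pytest

from beegs.breeding import BreedingConfig, run_breeding_program
from beegs.genome import (
    GenomeSpec,
    assign_qtl_effects,
    filter_loci_by_maf,
    simulate_historical_panel,
)
from beegs.trait_model import MOD

#: scaled-down study conditions used by simulation-based tests: the full
#: program's structure (16 chromosomes, 10 years, stations of 8 sister
#: DPQ, 12 drones per queen, burn-in then truncation selection) with the
#: yearly cohort reduced to 40 BQ and the SNP panel to ~2400 loci
SMALL_CONFIG = BreedingConfig(
    years=10,
    n_bq_per_year=40,
    n_stations=4,
    n_dpq_per_station=8,
    n_dams_bq=8,
    n_dams_dpq=4,
    n_drones_per_queen=12,
    n_workers=40,
)


@pytest.fixture(scope="session")
def small_panel():
    spec = GenomeSpec.uniform(n_loci=2400, n_chromosomes=16)
    panel = simulate_historical_panel(
        spec, 25, 150, seed=10, expansion_size=60, expansion_years=4
    )
    panel, _ = filter_loci_by_maf(panel, 0.05)
    return panel


@pytest.fixture(scope="session")
def small_history(small_panel):
    """One selected breeding population at the scaled-down conditions."""
    qtl = assign_qtl_effects(small_panel, 100, MOD.V_a, seed=2)
    return run_breeding_program(SMALL_CONFIG, small_panel, qtl, MOD, seed=3)


@pytest.fixture(scope="session")
def replicate_runs(small_panel):
    """20 replicate populations with fresh QTL each, plus PBLUP tables.

    ``pblup`` is the final pedigree-BLUP analysis (phenotypes through the
    next-to-last year); ``pblup_y7`` the snapshot available when dams of
    DPQ for the last deployment were chosen.
    """
    from beegs.genomic import run_analysis

    out = []
    rng = np.random.default_rng(42)
    for _ in range(20):
        qtl = assign_qtl_effects(small_panel, 150, MOD.V_a, seed=rng)
        hist = run_breeding_program(SMALL_CONFIG, small_panel, qtl, MOD, seed=rng)
        out.append(
            {
                "history": hist,
                "pblup": run_analysis(hist, "PBLUP", MOD),
                "pblup_y7": run_analysis(hist, "PBLUP", MOD, upto_year=7),
            }
        )
    return out


def gls_oracle(history, trait, K):
    """Generalized-least-squares solution of the direct+maternal model.

    Built from the full covariance of y (no mixed-model equations), so
    it is an independent check of the MME solver.  ``K`` is the dense
    relationship kernel (A, or H recovered from H-inverse).
    """
    phen = history.phenotype_frame()
    ped = history.pedigree()
    idx = ped.index
    n = len(ped)
    y = phen.phenotype.to_numpy(float)
    years, codes = np.unique(phen.year.to_numpy(), return_inverse=True)
    X = np.zeros((len(y), len(years)))
    X[np.arange(len(y)), codes] = 1.0
    Za = np.zeros((len(y), n))
    Za[np.arange(len(y)), [idx[i] for i in phen.id]] = 1.0
    Zm = np.zeros((len(y), n))
    Zm[np.arange(len(y)), [idx[i] for i in phen.queen_id]] = 1.0
    Ca = trait.sigma_a2 * K
    Cm = trait.sigma_m2 * K
    Cam = trait.sigma_am * K
    V = (
        Za @ Ca @ Za.T
        + Za @ Cam @ Zm.T
        + Zm @ Cam @ Za.T
        + Zm @ Cm @ Zm.T
        + trait.sigma_e2 * np.eye(len(y))
    )
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = Vi @ (y - X @ b)
    a_hat = (Ca @ Za.T + Cam @ Zm.T) @ resid
    m_hat = (Cam @ Za.T + Cm @ Zm.T) @ resid
    return ped.ids, a_hat, m_hat, dict(zip(years, b))
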