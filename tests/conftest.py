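import warnings

import numpy as np
import pytest

from gestarch.data import PhenotypeTable
from gestarch.gwas import NullModel, association_scan, compute_grm, fit_null_model, variant_qc
from gestarch.simulate import (
    SimConfig,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_trait,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_individuals=400, n_variants=1500, seed=7)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def annotation(small_config):
    genes, gene_sets, enrichable = simulate_gene_annotation(small_config)
    return genes, gene_sets, enrichable


@pytest.fixture(scope="session")
def fitted_gwas(small_genotypes):
    """QC'd genotypes, GRM, null model and association scan for one trait."""
    pheno, truth = simulate_trait(small_genotypes, h2=0.4, n_causal=100, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        geno, qc_log = variant_qc(small_genotypes)
        grm = compute_grm(geno)
        null = fit_null_model(pheno, grm)
        assoc = association_scan(geno, pheno, null)
    return geno, pheno, truth, grm, null, assoc


def plain_null_model(y: np.ndarray, ids: np.ndarray) -> NullModel:
    """Null model with no polygenic term and homogeneous unit residuals."""
    n = len(y)
    return NullModel(
        mu=float(np.mean(y)),
        sigma2_g=0.0,
        sigma2_e=float(np.var(y)),
        individual_id=ids,
        inv_sqrt_R=np.ones(n),
        eigvals=np.zeros(n),
        eigvecs=None,
        y_rot=np.asarray(y, float).copy(),
        x0_rot=np.ones(n),
    )


def unit_phenotypes(y: np.ndarray, ids: np.ndarray) -> PhenotypeTable:
    """Phenotypes with reliability 0.5 everywhere, i.e. residual weight 1 (R = I)."""
    return PhenotypeTable(ids, y, np.full(len(y), 0.5))
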