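"""Shared fixtures: simulated datasets and fitted models reused across tests."""

import numpy as np
import pytest

import mtorsig as m

#: forest settings used for full LOOCV runs: final forests at full size,
#: tuning-only forests scaled down so repeated runs stay desk-scale
DESK_FOREST = dict(n_trees=500, tune_n_trees=100,
                   mtry_grid=(2, 4, 6, 8, 10, 12, 14),
                   inner_folds=5, inner_repeats=5)


@pytest.fixture(scope="session")
def cell_sim():
    """Default paired cell-line simulation (9 lines x 2 conditions)."""
    return m.simulate_cell_lines(m.CellLineSimConfig(seed=7))


@pytest.fixture(scope="session")
def filtered_cells(cell_sim):
    matrix, conditions, truth = cell_sim
    return m.filter_low_info(matrix), conditions, truth


@pytest.fixture(scope="session")
def signature_results(filtered_cells):
    matrix, conditions, _ = filtered_cells
    return m.SignatureModel(matrix, conditions).fit()


@pytest.fixture(scope="session")
def patient_sim(signature_results):
    """Default 23-patient cohort with planted response, overlapping the
    fitted in vitro signature."""
    return m.simulate_patient_cohort(m.PatientSimConfig(seed=13),
                                     signature_results.gene_set)


@pytest.fixture(scope="session")
def patient_loocv(patient_sim, signature_results):
    """Out-of-fold patient LOOCV on the default strong-signal cohort."""
    matrix, pheno, truth = patient_sim
    std = m.standardize_genes(matrix)
    labels = m.label_response(pheno)
    model = m.IntegrativeModel(std, labels, signature_results.gene_set,
                               m.ForestConfig(seed=17, **DESK_FOREST))
    return model.loocv()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_matrix(values, gene_prefix="g", sample_prefix="s",
                 scale_tag="log2_tpm_plus1"):
    values = np.asarray(values, dtype=float)
    return m.ExpressionMatrix(
        [f"{gene_prefix}{i+1}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j+1}" for j in range(values.shape[1])],
        values, scale_tag)
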