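"""Shared fixtures: the reference synthetic dataset and fitted models.

The reference conditions (12 x 10 x 10 grid, 80% mask fill, L=5 sources
of which one is gene-only, R=[60, 30] features, SNR 10, 0.8% missing
entries) exercise every pipeline stage; fits are session-scoped because
several test modules interrogate the same decomposition.
"""

import numpy as np
import pytest

from voxlica.linked_ica import LinkedModelConfig, fit
from voxlica.preprocess import build_mask, flatten, impute_missing
from voxlica.synthetic import (
    SyntheticSpec,
    generate_annotation_universe,
    generate_linked_dataset,
)


@pytest.fixture(scope="session")
def ref_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def ref_dataset(ref_spec):
    return generate_linked_dataset(ref_spec)


@pytest.fixture(scope="session")
def ref_matrices(ref_dataset):
    volumes, mask, annot, _ = ref_dataset
    gene = impute_missing(flatten(volumes[0], mask, "gene"), annot)
    proj = flatten(volumes[1], mask, "proj")
    return [gene, proj]


@pytest.fixture(scope="session")
def ref_truth(ref_dataset):
    return ref_dataset[3]


@pytest.fixture(scope="session")
def ref_mask(ref_dataset):
    return ref_dataset[1]


@pytest.fixture(scope="session")
def ref_annot(ref_dataset):
    return ref_dataset[2]


@pytest.fixture(scope="session")
def ref_decomp(ref_matrices):
    """Linked ICA fit at the true model order."""
    return fit(ref_matrices, LinkedModelConfig(L=5, seed=1))


@pytest.fixture(scope="session")
def overfit_decomp(ref_matrices):
    """Linked ICA fit with twice the true model order (ARD test bed)."""
    return fit(ref_matrices, LinkedModelConfig(L=10, seed=1))


@pytest.fixture(scope="session")
def toy_universe():
    """200-gene universe, 30 terms, one planted 30-gene term."""
    genes = [f"gene{r:04d}" for r in range(200)]
    planted_genes = set(genes[:30])
    return generate_annotation_universe(
        n_genes=200, n_terms=30, planted=[("PLANTED", planted_genes)],
        seed=11, gene_ids=genes,
    ), planted_genes
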