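import numpy as np
import pytest
import scipy.sparse as sp

from detrem.reference import ReferenceCounts, build_signature
from detrem.synthetic import SyntheticReferenceSpec, make_reference


@pytest.fixture(scope="session")
def tiny_ref() -> ReferenceCounts:
    """Hand-built 2-gene reference: one type-A cell [2,2], one type-B cell [0,4]."""
    return ReferenceCounts(
        counts=sp.csr_matrix(np.array([[2, 0], [2, 4]], dtype=float)),
        gene_ids=["g1", "g2"],
        cell_type_of=["A", "B"],
        subject_of=["s1", "s1"],
    )


def random_reference(rng, n_types=3, n_genes=40, n_subjects=3, cells=8):
    """Unstructured random reference for brute-force oracle comparisons."""
    n_cells = n_types * n_subjects * cells
    counts = rng.poisson(3.0, size=(n_genes, n_cells))
    counts[rng.random((n_genes, n_cells)) < 0.3] = 0
    # guarantee every gene and every (subject, type) group has some signal
    counts[:, 0] += 1
    types = np.repeat([f"t{k}" for k in range(n_types)], n_subjects * cells)
    subjects = np.tile(
        np.repeat([f"s{j}" for j in range(n_subjects)], cells), n_types
    )
    counts += 1  # keep all groups expressed
    return ReferenceCounts(
        counts=sp.csr_matrix(counts.astype(float)),
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_type_of=types,
        subject_of=subjects,
    )


@pytest.fixture(scope="session")
def default_spec() -> SyntheticReferenceSpec:
    return SyntheticReferenceSpec(seed=0)


@pytest.fixture(scope="session")
def synth_ref(default_spec):
    return make_reference(default_spec)


@pytest.fixture(scope="session")
def synth_signature(synth_ref):
    return build_signature(synth_ref.reference)
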