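import numpy as np
import pytest

from klsnet.density import RegionPDF, build_similarity_matrix, cohort_grid_bounds, make_grid
from klsnet.simulate import generate_cohort, planted_test_spec, small_test_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_bin(p: float) -> RegionPDF:
    """Two-point distribution (p, 1-p) on a shared grid."""
    return RegionPDF(grid=np.array([0.0, 1.0]), probs=np.array([p, 1.0 - p]))


@pytest.fixture(scope="session")
def planted_cohort():
    """One planted-effect desk-scale cohort with its KLS matrices (shared
    across tests; treat as read-only)."""
    spec = planted_test_spec(seed=11)
    parcs, phenotype, truth = generate_cohort(spec)
    grid = make_grid(cohort_grid_bounds(parcs), 256)
    mats = [build_similarity_matrix(p, grid=grid) for p in parcs]
    return {
        "spec": spec,
        "parcs": parcs,
        "phenotype": phenotype,
        "truth": truth,
        "matrices": mats,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """One effect-free desk-scale cohort with its KLS matrices."""
    spec = small_test_spec(seed=21)
    parcs, phenotype, truth = generate_cohort(spec)
    grid = make_grid(cohort_grid_bounds(parcs), 256)
    mats = [build_similarity_matrix(p, grid=grid) for p in parcs]
    return {
        "spec": spec,
        "parcs": parcs,
        "phenotype": phenotype,
        "truth": truth,
        "matrices": mats,
    }
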