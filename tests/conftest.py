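import numpy as np
import pytest

from idscn import CohortSpec, ThicknessMatrix, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_thickness(rng):
    """10 subjects x 6 regions with mild block correlation."""
    from idscn import block_correlation

    corr = block_correlation(6, 2, 0.4, 0.0)
    root = np.linalg.cholesky(corr + 1e-12 * np.eye(6))
    values = 2.5 + 0.25 * (rng.standard_normal((10, 6)) @ root.T)
    return ThicknessMatrix(
        [f"s{i}" for i in range(10)], [f"r{j}" for j in range(6)], values
    )


@pytest.fixture
def small_cohort():
    """Small null cohort shared across tests (no perturbation)."""
    spec = CohortSpec(n_controls=30, n_patients=12, n_regions=8,
                      n_blocks=2, r_within=0.3, seed=7)
    return generate_cohort(spec)
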