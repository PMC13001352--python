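import numpy as np
import pandas as pd
import pytest

from acuteomix.core import OmicsMatrix
from acuteomix.synthetic import CohortConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Small all-arm cohort with planted effects, shared across tests."""
    cfg = CohortConfig(
        n_participants=30,
        seed=11,
        n_genes=80,
        n_tfs=5,
        n_peaks=60,
        n_phosphosites=50,
        n_metabolites=30,
        n_perturbed={"protein": 5, "rna": 5},
        arm_probs={"Early": 0.0, "Middle": 0.0, "Late": 0.0, "All": 1.0},
    )
    return generate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def gaussian_matrix(rng, n_feat=20, n_samp=10, ome="protein", prefix="F"):
    vals = pd.DataFrame(
        rng.normal(0, 1, (n_feat, n_samp)),
        index=[f"{prefix}{i}" for i in range(n_feat)],
        columns=[f"S{j}" for j in range(n_samp)],
    )
    return OmicsMatrix(vals, ome)
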