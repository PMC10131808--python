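import warnings

import numpy as np
import pytest

from fracopd.synthdata import SyntheticSpec, simulate_fractional_system


def canonical_coupling(n: int = 4) -> np.ndarray:
    """Damped nearest-neighbor coupling: the identification fixture."""
    A = -0.5 * np.eye(n)
    for i in range(n - 1):
        A[i, i + 1] = 0.1
        A[i + 1, i] = 0.1
    return A


CANON_ALPHA = np.array([0.15, 0.25, 0.30, 0.35])


@pytest.fixture(scope="session")
def canon_system():
    """(A_true, alpha) of the 4-channel identification fixture."""
    return canonical_coupling(), CANON_ALPHA


def simulate_canon(T=2000, noise_sd=0.0, seed=7, B=None, u_kind="none", x0=None):
    if x0 is None and noise_sd == 0.0:
        x0 = np.array([1.0, -1.0, 0.5, -0.5])
    spec = SyntheticSpec(
        n_channels=4, n_samples=T, alpha=CANON_ALPHA, A_true=canonical_coupling(),
        B_true=B, u_kind=u_kind, noise_sd=noise_sd, seed=seed, x0=x0,
    )
    return simulate_fractional_system(spec)


@pytest.fixture(scope="session")
def separable_dataset():
    """Feature dataset of the default (separable) staged cohort."""
    from fracopd.pipeline import dataset_from_records
    from fracopd.synthdata import CohortSpec, gen_staged_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = gen_staged_cohort(CohortSpec(seed=42))
        return dataset_from_records(records)


@pytest.fixture(scope="session")
def null_dataset():
    """Same cohort conditions with coupling_shift = 0: no stage signal."""
    from fracopd.pipeline import dataset_from_records
    from fracopd.synthdata import CohortSpec, gen_staged_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = gen_staged_cohort(CohortSpec(seed=43, coupling_shift=0.0))
        return dataset_from_records(records)
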