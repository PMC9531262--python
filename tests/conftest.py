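import numpy as np
import pytest

from acg import CohortConfig, generate_cohort


def compose_matrix_with_profile(fractions, t=40, f=None, seed=0, scale=3.0):
    """T×F matrix whose centred SVD has exactly the given variance fractions.

    Built as Q·diag(s)·Vᵀ with Q orthonormal and orthogonal to the all-ones
    vector (zero column means), so centring leaves the spectrum untouched.
    """
    fractions = np.asarray(fractions, dtype=float)
    k = fractions.size
    f = f if f is not None else k
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((t, k))
    a -= a.mean(axis=0)                      # column space ⟂ 1
    q, _ = np.linalg.qr(a)
    v, _ = np.linalg.qr(rng.standard_normal((f, k)))
    s = np.sqrt(fractions * scale)
    return q @ np.diag(s) @ v.T


def cumulative_count_oracle(fractions, threshold):
    """Closed-form dimensionality: first k with Σ_{i<=k} fraction_i >= τ."""
    cum = 0.0
    for i, r in enumerate(sorted(fractions, reverse=True), start=1):
        cum += r
        if cum >= threshold - 1e-12:
            return i
    return len(fractions)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_sg=3, n_cg=3, t_samples=48, n_measurements=4, smoothing=8)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(), seed=1)
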