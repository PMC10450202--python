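import numpy as np
import pytest
from hypothesis import settings

from paedomains.synthetic import default_spec, generate_model, generate_pae

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def quaternion_superpose_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Independent closed-form superposition RMSD via Horn's quaternion method.

    Builds the 4x4 symmetric key matrix from the covariance of the centred
    point sets; the largest eigenvalue gives the optimal rotation without
    ever constructing it, so this shares no code path with the SVD-based
    implementation under test.
    """
    X = np.asarray(X, float) - np.mean(X, axis=0)
    Y = np.asarray(Y, float) - np.mean(Y, axis=0)
    S = X.T @ Y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (np.sum(X**2) + np.sum(Y**2) - 2.0 * lam) / len(X)
    return float(np.sqrt(max(sq, 0.0)))


@pytest.fixture(scope="session")
def bench_spec():
    """Default benchmark chain: 3 domains, 1 assembly (A+B), 1 split (B)."""
    return default_spec(seed=1)


@pytest.fixture(scope="session")
def bench_model(bench_spec):
    model, truth = generate_model(bench_spec)
    return model, truth


@pytest.fixture(scope="session")
def bench_pae(bench_spec):
    return generate_pae(bench_spec)
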