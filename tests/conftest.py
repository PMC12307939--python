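import numpy as np
import pytest

from bioecon import FlowTable


@pytest.fixture
def e2() -> FlowTable:
    """Two-sector worked economy: every derived quantity checkable by hand.

    Rows: 10+20+70=100, 30+40+130=200.  Columns: 100-(10+30)=60,
    200-(20+40)=140.  Coefficients A=[[0.1,0.1],[0.3,0.2]], det(I-A)=0.69.
    """
    return FlowTable(
        labels=["agriculture", "R&D"],
        Z=np.array([[10.0, 20.0], [30.0, 40.0]]),
        x=np.array([100.0, 200.0]),
        f=np.array([70.0, 130.0]),
        va=np.array([60.0, 140.0]),
    )


def neumann_inverse(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Truncated Neumann series sum_k A^k, independent oracle for (I-A)^-1.

    The truncation order K is chosen from the spectral radius so the
    remainder bound rho^(K+1)/(1-rho) falls below ``tol``.
    """
    rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    assert rho < 1.0
    K = 1
    while rho ** (K + 1) / (1.0 - rho) >= tol:
        K += 1
    total = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for _ in range(K):
        term = term @ A
        total = total + term
    return total


def random_productive_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Nonnegative matrix with column sums (hence spectral radius) below 1."""
    raw = rng.uniform(0.0, 1.0, size=(n, n))
    target = rng.uniform(0.1, 0.9, size=n)
    return raw / raw.sum(axis=0, keepdims=True) * target
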