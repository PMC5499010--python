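import numpy as np
import pytest

from deconartifact import SignatureMatrix, make_synthetic_signature


@pytest.fixture
def toy_sig() -> SignatureMatrix:
    """4 genes x 2 cell types, hand-enterable values."""
    return SignatureMatrix(
        ["G1", "G2", "G3", "G4"], ["A", "B"],
        np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 4.0], [4.0, 3.0]]),
    )


@pytest.fixture(scope="session")
def small_sig() -> SignatureMatrix:
    """Well-conditioned 60-gene x 5-cell-type synthetic signature."""
    return make_synthetic_signature(60, 5, seed=42)


@pytest.fixture(scope="session")
def sig22() -> SignatureMatrix:
    """Default-scale 250-gene x 22-cell-type signature, near-orthogonal
    focal pair."""
    return make_synthetic_signature(250, 22, rho_spec=[((0, 1), 0.0)], seed=7)
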