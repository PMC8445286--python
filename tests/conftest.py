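import numpy as np
import pytest

from mpclasso.fields import FieldParams
from mpclasso.runtime import PARTIES, ProtocolContext
from mpclasso.shamir import ShamirEngine


@pytest.fixture
def field() -> FieldParams:
    return FieldParams()


@pytest.fixture
def make_engine(field):
    """Factory for a seeded three-party engine; contexts closed on teardown."""
    contexts = []

    def _make(seed: int = 1, fld: FieldParams | None = None):
        ctx = ProtocolContext(seed=seed)
        contexts.append(ctx)
        return ShamirEngine(ctx, fld or field), ctx

    yield _make
    for ctx in contexts:
        ctx.close()


@pytest.fixture(scope="session")
def he_keypair():
    from mpclasso import paillier

    return paillier.keygen(512)


@pytest.fixture
def small_regression():
    from mpclasso.datasets import generate_regression

    full, gt = generate_regression(30, 5, 0.01, 0.4, seed=5)
    y = full.column("target")
    X = full.features[:, :-1]
    return X, y, gt
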