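import numpy as np
import pandas as pd
import pytest

from mgidi import IdeotypeSpec, LongTable, MeansTable


def random_correlation(rng: np.random.Generator, p: int, min_eig: float = 0.05):
    """Well-conditioned random correlation matrix (random orthogonal
    eigenvectors, eigenvalues bounded away from zero, rescaled to unit
    diagonal)."""
    Q, _ = np.linalg.qr(rng.standard_normal((p, p)))
    lam = rng.uniform(min_eig, 2.0, p)
    S = Q @ np.diag(lam) @ Q.T
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def random_means(rng: np.random.Generator, g: int, p: int) -> MeansTable:
    vals = rng.uniform(10.0, 90.0, (g, p))
    df = pd.DataFrame(
        vals,
        index=[f"T{i+1}" for i in range(g)],
        columns=[f"V{j+1}" for j in range(p)],
    )
    return MeansTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_trial() -> LongTable:
    """2x2 factorial x 2 blocks, 2 traits, small integers (hand-checkable)."""
    gen = np.random.default_rng(7)
    rows = []
    for a in ["a1", "a2"]:
        for b in ["b1", "b2"]:
            for blk in ["B1", "B2"]:
                y1, y2 = gen.integers(1, 20, size=2)
                rows.append(
                    {"A": a, "B": b, "BLOCK": blk,
                     "Y1": float(y1), "Y2": float(y2)}
                )
    return LongTable(
        data=pd.DataFrame(rows),
        factor_columns=["A", "B", "BLOCK"],
        trait_columns=["Y1", "Y2"],
    )


@pytest.fixture
def uniform_spec():
    def make(traits, direction="higher"):
        return IdeotypeSpec.uniform(traits, direction)

    return make
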