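"""Exploratory factor analysis of the rescaled means table.

The chain is: Pearson correlation matrix R of the rescaled means →
eigendecomposition → Guttman-Kaiser retention (eigenvalues > 1, floor
of one factor) → initial loadings by principal-component extraction
(eigenvector * sqrt(eigenvalue)) → varimax rotation → factor scores

    F = Z (A' R^-) '

where Z holds the column-standardized rescaled means, A the rotated
loadings and R^- the Moore-Penrose pseudo-inverse of R. The
pseudo-inverse matters: with g treatments and p >> g traits (e.g. four
treatments, 22 traits) R has rank at most g - 1 and a plain inverse
does not exist.

Varimax uses iterative pairwise (Givens) rotations maximizing the
variance of squared loadings per factor; Kaiser row-normalization
(normalize rows to unit communality, rotate, denormalize) is applied by
default, matching the dominant convention of reference varimax
implementations — it changes loadings at the second decimal, so a
``kaiser_normalize=False`` switch is provided for cross-checks.

Every loading/score sign is pinned by a deterministic convention (the
largest-|loading| entry of each factor is positive); the downstream
distance index is invariant to these sign choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rescale import RescaledTable

__all__ = [
    "FactorModel",
    "standardize",
    "retain_factors",
    "initial_loadings",
    "varimax_rotate",
    "factor_scores",
    "fit_factor_model",
]


def standardize(table: RescaledTable | pd.DataFrame) -> pd.DataFrame:
    """Column-standardize (mean 0, sd 1 with denominator g-1)."""
    df = table.values if isinstance(table, RescaledTable) else table
    sd = df.std(ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"zero-variance column(s): {bad} (drop upstream)")
    return (df - df.mean()) / sd


def retain_factors(eigenvalues: np.ndarray) -> int:
    """Guttman-Kaiser rule: number of eigenvalues strictly greater than
    one, with a floor of one factor."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    return max(int((lam > 1.0).sum()), 1)


def _pin_signs(L: np.ndarray) -> np.ndarray:
    """Flip factor signs so the largest-|value| entry per column is
    positive (ties resolved by lowest row index)."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def _corr_eig(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0.0, None), V[:, order]


def initial_loadings(R: np.ndarray, f: int) -> np.ndarray:
    """Principal-component extraction: column j of the p x f loading
    matrix is eigenvector_j * sqrt(eigenvalue_j)."""
    w, V = _corr_eig(np.asarray(R, dtype=float))
    L = V[:, :f] * np.sqrt(w[:f])
    return _pin_signs(L)


def _varimax_criterion(L: np.ndarray) -> float:
    # sum over factors of the population variance of squared loadings
    sq = np.asarray(L) ** 2
    return float(sq.var(axis=0).sum())


def varimax_rotate(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by cyclic pairwise plane rotations.

    Returns ``(rotated, T)`` with T orthogonal. Without Kaiser
    normalization ``rotated = loadings @ T`` exactly; with it the
    identity holds on the row-normalized loadings (the usual
    convention). For a single factor there is nothing to rotate and the
    input is returned with an identity T.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, f = L.shape
    T = np.eye(f)
    if f == 1:
        return L.copy(), T
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h = np.where(h > 0, h, 1.0)
        W = L / h[:, None]
    else:
        h = np.ones(p)
        W = L.copy()
    crit = _varimax_criterion(W)
    for _ in range(max_sweeps):
        for a in range(f - 1):
            for b in range(a + 1, f):
                x, y = W[:, a], W[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = (2.0 * u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                W[:, [a, b]] = W[:, [a, b]] @ G
                T[:, [a, b]] = T[:, [a, b]] @ G
        new_crit = _varimax_criterion(W)
        if new_crit - crit < tol:
            break
        crit = new_crit
    rotated = W * h[:, None]
    # pin signs on the rotated solution and fold the flips into T
    pinned = _pin_signs(rotated)
    flips = np.ones(f)
    for j in range(f):
        if not np.allclose(pinned[:, j], rotated[:, j]):
            flips[j] = -1.0
    return pinned, T * flips[None, :]


def factor_scores(
    Z: np.ndarray | pd.DataFrame,
    A: np.ndarray,
    R: np.ndarray,
    rank_tol: float = 1e-10,
) -> np.ndarray:
    """Regression-style factor scores F = Z (A' R^-)'.

    ``R^-`` is the Moore-Penrose pseudo-inverse (the exact inverse when
    R is nonsingular); a warning is logged when rank(R) < p, which is
    the normal situation when treatments are fewer than traits.
    """
    Zv = np.asarray(Z, dtype=float)
    R = np.asarray(R, dtype=float)
    s = np.linalg.svd(R, compute_uv=False)
    rank = int((s > s[0] * rank_tol).sum()) if s.size else 0
    if rank < R.shape[0]:
        warnings.warn(
            f"correlation matrix has rank {rank} < {R.shape[0]}; "
            "using pseudo-inverse for factor scores",
            RuntimeWarning,
        )
    Rinv = np.linalg.pinv(R, rcond=rank_tol)
    return Zv @ (A.T @ Rinv).T


@dataclass
class FactorModel:
    """Fitted exploratory factor model of a rescaled means table."""

    correlation: pd.DataFrame  # p x p
    eigenvalues: np.ndarray  # length p, descending
    explained: np.ndarray  # % of total variance per eigenvalue (pre-rotation)
    cumulative: np.ndarray
    n_factors: int
    loadings_initial: pd.DataFrame  # p x f
    loadings: pd.DataFrame  # p x f, varimax-rotated
    rotation: np.ndarray  # f x f orthogonal
    communalities: pd.Series  # length p
    z: pd.DataFrame  # g x p standardized rescaled means
    scores: pd.DataFrame  # g x f
    kaiser_normalize: bool

    @property
    def traits(self) -> list[str]:
        return list(self.correlation.index)

    @property
    def treatments(self) -> list[str]:
        return list(self.scores.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def trait_assignment(self) -> pd.Series:
        """Factor of each trait's largest absolute rotated loading."""
        return self.loadings.abs().idxmax(axis=1)

    def explained_rotated(self) -> np.ndarray:
        """% of total variance per retained factor after rotation
        (column sums of squared rotated loadings over p)."""
        p = len(self.traits)
        return 100.0 * (self.loadings.to_numpy() ** 2).sum(axis=0) / p

    def loadings_table(self) -> pd.DataFrame:
        """Rotated loadings with eigenvalue / variance / cumulative rows
        appended (the conventional reporting layout)."""
        tab = self.loadings.copy()
        f = self.n_factors
        tab.loc["Eigenvalues"] = self.eigenvalues[:f]
        tab.loc["Variance (%)"] = self.explained[:f]
        tab.loc["Cumulative (%)"] = self.cumulative[:f]
        return tab

    def summary(self) -> pd.DataFrame:
        return self.loadings_table()


def fit_factor_model(
    table: RescaledTable,
    n_factors: int | None = None,
    kaiser_normalize: bool = True,
) -> FactorModel:
    """Fit the full factor-analysis chain on a rescaled means table.

    Parameters
    ----------
    table : RescaledTable
        g x p rescaled treatment means (g >= 2, p >= 2).
    n_factors : int, optional
        Override the Guttman-Kaiser retention rule.
    kaiser_normalize : bool
        Kaiser row-normalization inside varimax (default True).
    """
    df = table.values
    g, p = df.shape
    if g < 2 or p < 2:
        raise ValueError(f"need >= 2 treatments and >= 2 traits, got {df.shape}")
    Z = standardize(table)
    R = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    w, _ = _corr_eig(R)
    f = retain_factors(w) if n_factors is None else int(n_factors)
    if not 1 <= f <= p:
        raise ValueError(f"n_factors must be in [1, {p}]")
    L0 = initial_loadings(R, f)
    L, T = varimax_rotate(L0, kaiser_normalize=kaiser_normalize)
    F = factor_scores(Z, L, R)
    factor_names = [f"FA{j + 1}" for j in range(f)]
    explained = 100.0 * w / p
    return FactorModel(
        correlation=pd.DataFrame(R, index=df.columns, columns=df.columns),
        eigenvalues=w,
        explained=explained,
        cumulative=np.cumsum(explained),
        n_factors=f,
        loadings_initial=pd.DataFrame(L0, index=df.columns, columns=factor_names),
        loadings=pd.DataFrame(L, index=df.columns, columns=factor_names),
        rotation=T,
        communalities=pd.Series((L**2).sum(axis=1), index=df.columns),
        z=Z,
        scores=pd.DataFrame(F, index=df.index, columns=factor_names),
        kaiser_normalize=kaiser_normalize,
    )
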