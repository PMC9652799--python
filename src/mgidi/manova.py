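"""Factorial MANOVA with Pillai's trace.

Screens which model terms (main effects, interactions) show a joint
multivariate effect before a treatment-by-trait means table is built
for them. The linear model is Y = X b + e with a fixed design matrix
holding the intercept, optionally the block term, and the factorial
terms in a stated order. On balanced data the sequential sums-of-squares
and cross-products (SSCP) decomposition is orthogonal, so the term order
does not matter; unbalanced data is rejected rather than silently
re-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import LongTable, SchemaError, _check_balance

__all__ = [
    "ManovaResult",
    "FactorialManova",
    "sscp_decomposition",
    "pillai_trace",
    "pillai_f_approx",
    "manova_table",
    "expand_factorial_terms",
]


def expand_factorial_terms(factors: list[str]) -> list[tuple[str, ...]]:
    """All main effects and interactions of ``factors``, mains first,
    then two-way terms, etc., preserving the declared factor order."""
    from itertools import combinations

    terms: list[tuple[str, ...]] = []
    for k in range(1, len(factors) + 1):
        terms.extend(combinations(factors, k))
    return terms


def _term_label(term: tuple[str, ...]) -> str:
    return " x ".join(term)


def _dummy_block(data: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Full-interaction indicator columns for one term (no reference
    level dropped; rank handled by sequential projection)."""
    key = data[list(term)].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(key, dtype=float).to_numpy()


def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto col(X) and its rank, via SVD."""
    if X.size == 0:
        return np.zeros((X.shape[0], X.shape[0])), 0
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int((s > tol).sum())
    U = U[:, :r]
    return U @ U.T, r


def sscp_decomposition(
    data: LongTable,
    terms: list[tuple[str, ...]],
) -> tuple[dict[str, tuple[np.ndarray, int]], tuple[np.ndarray, int]]:
    """Sequential SSCP decomposition of the trial responses.

    Parameters
    ----------
    data : LongTable
        Unit-averaged, balanced long table.
    terms : list of tuples
        Model terms in fitting order (e.g. ``[("BLOCK",), ("TRT",)]``);
        each term is a tuple of factor names whose full interaction is
        fitted.

    Returns
    -------
    (hypothesis, error)
        ``hypothesis`` maps term label → (H, df_h); ``error`` is
        (E, df_e). H and E are p x p SSCP matrices.

    Raises
    ------
    SchemaError
        If the design is unbalanced or a term is aliased (adds no new
        columns to the model space).
    """
    if data.unit_column is not None:
        raise ValueError("average within units before MANOVA")
    _check_balance(data)
    Y = data.data[data.trait_columns].to_numpy(dtype=float)
    n = Y.shape[0]
    X = np.ones((n, 1))
    P_prev, r_prev = _projection(X)
    hypothesis: dict[str, tuple[np.ndarray, int]] = {}
    for term in terms:
        unknown = [f for f in term if f not in data.factor_columns]
        if unknown:
            raise SchemaError(f"unknown factor(s) in term: {', '.join(unknown)}")
        X = np.hstack([X, _dummy_block(data.data, term)])
        P_cur, r_cur = _projection(X)
        df_h = r_cur - r_prev
        expected = int(
            np.prod([data.data[f].nunique() - 1 for f in term])
        )
        if df_h < expected:
            raise SchemaError(
                f"term {_term_label(term)} is aliased with earlier terms "
                f"(adds rank {df_h}, expected {expected})"
            )
        D = P_cur - P_prev
        hypothesis[_term_label(term)] = (Y.T @ D @ Y, df_h)
        P_prev, r_prev = P_cur, r_cur
    E = Y.T @ (np.eye(n) - P_prev) @ Y
    df_e = n - r_prev
    if df_e <= 0:
        raise SchemaError("saturated model: no residual degrees of freedom")
    return hypothesis, (E, df_e)


def pillai_trace(H: np.ndarray, E: np.ndarray) -> float:
    """Pillai's trace V = tr[H (H + E)^-1].

    Equivalently the sum of lambda/(1+lambda) over eigenvalues lambda of
    H E^-1. A pseudo-inverse is used (with a warning) when H + E is
    singular on the trait space.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    T = H + E
    cond = np.linalg.cond(T)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("H + E is singular; using pseudo-inverse", RuntimeWarning)
        Tinv = np.linalg.pinv(T)
    else:
        Tinv = np.linalg.inv(T)
    return float(np.trace(H @ Tinv))


def pillai_f_approx(
    V: float, p: int, q: int, v_e: int
) -> tuple[float, int, int, float]:
    """F approximation for Pillai's trace.

    With s = min(p, q), m = (|p - q| - 1)/2 and n = (v_e - p - 1)/2:

        F = ((2n + s + 1) / (2m + s + 1)) * (V/s) / (1 - V/s)

    on (s(2m + s + 1), s(2n + s + 1)) degrees of freedom. For p = 1 this
    reduces to the exact univariate F with (q, v_e) df.
    """
    s = min(p, q)
    if s < 1:
        raise ValueError("need at least one trait and one hypothesis df")
    m = (abs(p - q) - 1) / 2.0
    nn = (v_e - p - 1) / 2.0
    ratio = V / s
    if ratio >= 1.0:
        warnings.warn(
            f"Pillai V = {V:.6g} at its upper bound s = {s}; clamping",
            RuntimeWarning,
        )
        ratio = 1.0 - 1e-12
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * nn + s + 1)))
    F = ((2 * nn + s + 1) / (2 * m + s + 1)) * ratio / (1.0 - ratio)
    p_value = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p_value


@dataclass
class ManovaResult:
    """Per-term Pillai statistics with the underlying SSCP matrices."""

    table: pd.DataFrame  # term, pillai, approx_F, df_h, df_e, p_value, significant
    hypothesis_sscp: dict[str, np.ndarray]
    error_sscp: np.ndarray
    error_df: int
    alpha: float

    def significant_terms(self) -> list[str]:
        mask = self.table["significant"] & (self.table["term"] != "Intercept")
        return self.table.loc[mask, "term"].tolist()

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def manova_table(
    data: LongTable,
    design: list[str] | None = None,
    include_block: bool = True,
    block: str = "BLOCK",
    alpha: float = 0.05,
    intercept_row: bool = True,
) -> ManovaResult:
    """Factorial MANOVA table with Pillai's trace per term.

    Parameters
    ----------
    data : LongTable
        Unit-averaged balanced trial data.
    design : list of str, optional
        Treatment factors; defaults to all factor columns except
        ``block``. All main effects and interactions are fitted.
    include_block : bool
        Whether to fit an additive block term before the treatment
        terms. Blocks never interact with treatment factors.
    alpha : float
        Significance level for the advisory ``significant`` flag.
    intercept_row : bool
        Also report the (rarely interesting) test of the grand mean.
    """
    if design is None:
        design = [f for f in data.factor_columns if f != block]
    terms: list[tuple[str, ...]] = []
    if include_block:
        if block not in data.factor_columns:
            raise SchemaError(f"block column {block!r} not in factor columns")
        terms.append((block,))
    terms.extend(expand_factorial_terms(design))
    hyp, (E, df_e) = sscp_decomposition(data, terms)
    p = len(data.trait_columns)

    rows = []
    hyp_out: dict[str, np.ndarray] = {}
    if intercept_row:
        n = data.n_records
        Y = data.data[data.trait_columns].to_numpy(dtype=float)
        ybar = Y.mean(axis=0, keepdims=True)
        H0 = n * (ybar.T @ ybar)
        V0 = pillai_trace(H0, E)
        F0, d1, d2, pv0 = pillai_f_approx(V0, p, 1, df_e)
        rows.append(("Intercept", V0, F0, d1, d2, pv0))
        hyp_out["Intercept"] = H0
    for label, (H, df_h) in hyp.items():
        V = pillai_trace(H, E)
        F, d1, d2, pv = pillai_f_approx(V, p, df_h, df_e)
        rows.append((label, V, F, d1, d2, pv))
        hyp_out[label] = H
    table = pd.DataFrame(
        rows, columns=["term", "pillai", "approx_F", "df_h", "df_e", "p_value"]
    )
    table["significant"] = table["p_value"] <= alpha
    return ManovaResult(
        table=table,
        hypothesis_sscp=hyp_out,
        error_sscp=E,
        error_df=df_e,
        alpha=alpha,
    )


class FactorialManova:
    """Model-style front-end: build from a long table, ``fit()`` returns
    a :class:`ManovaResult`."""

    def __init__(
        self,
        data: LongTable,
        design: list[str] | None = None,
        include_block: bool = True,
        block: str = "BLOCK",
    ) -> None:
        self.data = data
        self.design = design
        self.include_block = include_block
        self.block = block

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        factors: list[str],
        traits: list[str],
        **kwargs,
    ) -> "FactorialManova":
        table = LongTable(
            data=df, factor_columns=factors, trait_columns=traits
        )
        return cls(table, **kwargs)

    def fit(self, alpha: float = 0.05) -> ManovaResult:
        return manova_table(
            self.data,
            design=self.design,
            include_block=self.include_block,
            block=self.block,
            alpha=alpha,
        )
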