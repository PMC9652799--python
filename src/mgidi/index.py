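"""The multi-trait genotype-ideotype distance index (MGIDI).

Given a treatment-by-trait means table and an ideotype declaration
(direction + optional weight per trait), the index is built in four
steps:

1. rescale every trait to [0, 100] with 100 at the desired pole;
2. factor-analyze the rescaled table (correlation → Guttman-Kaiser
   retention → varimax → scores);
3. score the *ideal* treatment — the row of all 100s — through the same
   standardization and score projection, optionally after multiplying
   its standardized entries by the trait weights;
4. rank treatments by the Euclidean distance between their factor
   scores and the ideal's:  MGIDI_i = sqrt( sum_j (F_ij - gamma_j)^2 ).

The treatment with the smallest MGIDI is closest to the ideal. The
per-factor share of each treatment's distance (omega) exposes its
strengths (small share: that factor's traits are near the ideal) and
weaknesses; selection differentials report, per trait and on the
original mean scale, what selecting the top-k treatments changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factor_model import FactorModel, fit_factor_model
from .rescale import RescaledTable, rescale_table
from .trial_data import IdeotypeSpec, LongTable, MeansTable, average_within_units, cell_means

__all__ = [
    "MGIDI",
    "MGIDIResults",
    "ideal_scores",
    "compute_mgidi",
    "strengths_weaknesses",
    "selection_differentials",
    "rank_and_select",
    "run_pipeline",
]


def ideal_scores(
    model: FactorModel,
    spec: IdeotypeSpec,
    rescaled: RescaledTable,
    weight_mode: str = "trait",
    factor_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Factor scores gamma of the ideal treatment.

    The ideal row is 100 in every rescaled trait. It is standardized
    with the *treatment table's* column means and sds, then projected
    through the fitted model's score equation. Trait weights multiply
    the standardized ideal entries before projection (``weight_mode
    "trait"``, the default); ``weight_mode "factor"`` instead multiplies
    the projected scores by ``factor_weights`` (length = retained
    factors), the literal factor-level reading of the weighting text.
    """
    from .factor_model import factor_scores

    traits = model.traits
    spec.validate_for(traits)
    df = rescaled.values[traits]
    mu = df.mean().to_numpy()
    sd = df.std(ddof=1).to_numpy()
    z_ideal = (np.full(len(traits), 100.0) - mu) / sd
    A = model.loadings.to_numpy()
    R = model.correlation.to_numpy()
    if weight_mode == "trait":
        theta = spec.weights(traits)
        return factor_scores((z_ideal * theta)[None, :], A, R)[0]
    if weight_mode != "factor":
        raise ValueError("weight_mode must be 'trait' or 'factor'")
    gamma = factor_scores(z_ideal[None, :], A, R)[0]
    fw = (
        np.ones(model.n_factors)
        if factor_weights is None
        else np.asarray(factor_weights, dtype=float)
    )
    if fw.shape != (model.n_factors,):
        raise ValueError(f"factor_weights must have length {model.n_factors}")
    return gamma * fw


def compute_mgidi(scores: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Euclidean distance of each treatment's factor scores from the
    ideal's: MGIDI_i = sqrt( sum_j (F_ij - gamma_j)^2 )."""
    F = np.asarray(scores, dtype=float)
    g = np.asarray(gamma, dtype=float)
    return np.sqrt(((F - g[None, :]) ** 2).sum(axis=1))


def strengths_weaknesses(
    scores: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-factor share of each treatment's distance from the ideal.

    D_ij = |F_ij - gamma_j|; omega_ij = D_ij / sum_j D_ij. A treatment
    exactly at the ideal (all D zero) has omega undefined; a uniform
    1/f row is returned for it with its flag set.

    Returns
    -------
    (omega, D, at_ideal) : ndarray (g, f), ndarray (g, f), bool ndarray (g,)
    """
    F = np.asarray(scores, dtype=float)
    g = np.asarray(gamma, dtype=float)
    D = np.abs(F - g[None, :])
    totals = D.sum(axis=1)
    at_ideal = totals == 0.0
    safe = np.where(at_ideal, 1.0, totals)
    omega = D / safe[:, None]
    f = D.shape[1]
    omega[at_ideal] = 1.0 / f
    return omega, D, at_ideal


def selection_differentials(
    means: MeansTable,
    selected: list[str],
    spec: IdeotypeSpec,
) -> pd.DataFrame:
    """Per-trait selection differentials on the original mean scale.

    SD% = 100 * (mean of selected treatments - overall mean) / overall
    mean. The ``desired`` flag marks traits whose differential moved in
    (or stayed at) the declared direction; ``n_desired`` is its column
    sum. A trait with overall mean 0 gets the absolute difference
    instead (``relative`` False).
    """
    if not selected:
        raise ValueError("selected set is empty")
    missing = [t for t in selected if t not in means.treatments]
    if missing:
        raise KeyError(f"unknown treatment(s): {', '.join(missing)}")
    spec.validate_for(means.traits)
    overall = means.values.mean(axis=0)
    sel_mean = means.values.loc[selected].mean(axis=0)
    diff = sel_mean - overall
    relative = overall != 0
    sd = pd.Series(np.where(relative, 100.0 * diff / overall.where(relative, 1.0), diff),
                   index=means.values.columns)
    directions = pd.Series(
        {t: spec.traits[t].direction for t in means.traits}
    )
    desired = np.where(directions == "higher", sd >= 0, sd <= 0)
    out = pd.DataFrame(
        {
            "mean_all": overall,
            "mean_selected": sel_mean,
            "sd_percent": sd,
            "relative": relative,
            "direction": directions,
            "desired": desired,
        }
    )
    out.index.name = "trait"
    return out


def rank_and_select(
    distances: np.ndarray | pd.Series, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ascending-distance ranks (1 = best) and the top-k selection mask.

    Ties are broken by input order (stable sort); a tie exactly at the
    selection boundary triggers a warning.
    """
    d = np.asarray(distances, dtype=float)
    g = len(d)
    if not 1 <= k <= g:
        raise ValueError(f"k must be in [1, {g}], got {k}")
    order = np.argsort(d, kind="stable")
    ranks = np.empty(g, dtype=int)
    ranks[order] = np.arange(1, g + 1)
    selected = ranks <= k
    if k < g and d[order[k - 1]] == d[order[k]]:
        warnings.warn(
            "tie at the selection boundary; earlier input order wins",
            RuntimeWarning,
        )
    return ranks, selected


@dataclass
class MGIDIResults:
    """Everything the index run produced, ready for reporting."""

    means: MeansTable
    rescaled: RescaledTable
    factor_model: FactorModel
    spec: IdeotypeSpec
    gamma: np.ndarray  # ideal factor scores, length f
    distances: pd.Series  # MGIDI per treatment
    ranks: pd.Series
    selected: list[str]
    contributions: pd.DataFrame  # omega, g x f
    factor_distances: pd.DataFrame  # D, g x f
    at_ideal: pd.Series
    differentials: pd.DataFrame
    weight_mode: str

    @property
    def n_desired(self) -> int:
        """Traits whose selection differential moved the desired way."""
        return int(self.differentials["desired"].sum())

    def summary(self) -> pd.DataFrame:
        """Ranking table: treatment, MGIDI, rank, selected flag."""
        return pd.DataFrame(
            {
                "MGIDI": self.distances,
                "rank": self.ranks,
                "selected": self.distances.index.isin(self.selected),
            }
        ).sort_values("rank")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        top = ", ".join(self.selected)
        return (
            f"<MGIDIResults: {len(self.distances)} treatments, "
            f"{self.factor_model.n_factors} factors, selected [{top}]>"
        )


class MGIDI:
    """Genotype-ideotype distance model over a treatment-by-trait table.

    Parameters
    ----------
    means : MeansTable
        g x p estimated treatment means.
    spec : IdeotypeSpec
        Per-trait direction and weight declaration.
    n_factors : int, optional
        Override the eigenvalue-greater-than-one retention rule.
    kaiser_normalize : bool
        Kaiser row-normalization inside varimax.
    weight_mode : {"trait", "factor"}
        Whether weights act on the standardized ideal's trait entries
        (default) or on its projected factor scores.

    Examples
    --------
    >>> model = MGIDI(means, spec)
    >>> res = model.fit(k=2)
    >>> res.summary()
    """

    def __init__(
        self,
        means: MeansTable,
        spec: IdeotypeSpec,
        n_factors: int | None = None,
        kaiser_normalize: bool = True,
        weight_mode: str = "trait",
        factor_weights: np.ndarray | None = None,
        strict_rescale: bool = False,
    ) -> None:
        if weight_mode not in ("trait", "factor"):
            raise ValueError("weight_mode must be 'trait' or 'factor'")
        spec.validate_for(means.traits)
        self.means = means
        self.spec = spec
        self.n_factors = n_factors
        self.kaiser_normalize = kaiser_normalize
        self.weight_mode = weight_mode
        self.factor_weights = factor_weights
        self.strict_rescale = strict_rescale

    @classmethod
    def from_long(
        cls,
        data: LongTable,
        spec: IdeotypeSpec,
        term: list[str] | None = None,
        **kwargs,
    ) -> "MGIDI":
        """Build from long-format trial data: average pseudo-replicates
        (if a unit column is present) and take the marginal means of
        ``term`` (default: all non-block factors)."""
        if data.unit_column is not None:
            data = average_within_units(data)
        if term is None:
            term = [f for f in data.factor_columns if f.upper() != "BLOCK"]
        means = cell_means(data, term)
        return cls(means, spec, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: IdeotypeSpec, **kwargs
    ) -> "MGIDI":
        """Build from a treatments-in-rows DataFrame of means."""
        return cls(MeansTable(df), spec, **kwargs)

    # -- fitting ---------------------------------------------------------

    def _ideal_gamma(self, model: FactorModel, rescaled: RescaledTable) -> np.ndarray:
        return ideal_scores(
            model,
            self.spec,
            rescaled,
            weight_mode=self.weight_mode,
            factor_weights=self.factor_weights,
        )

    def fit(self, k: int | None = None) -> MGIDIResults:
        """Run the full index: rescale, factor-analyze, score the ideal,
        rank by distance and compute the selection differentials.

        Parameters
        ----------
        k : int, optional
            Number of treatments to select; defaults to ceil(g / 2).
        """
        rescaled = rescale_table(self.means, self.spec, strict=self.strict_rescale)
        model = fit_factor_model(
            rescaled,
            n_factors=self.n_factors,
            kaiser_normalize=self.kaiser_normalize,
        )
        gamma = self._ideal_gamma(model, rescaled)
        F = model.scores.to_numpy()
        d = compute_mgidi(F, gamma)
        g = len(d)
        if k is None:
            k = math.ceil(g / 2)
        ranks, selected_mask = rank_and_select(d, k)
        omega, D, at_ideal = strengths_weaknesses(F, gamma)
        treatments = model.treatments
        distances = pd.Series(d, index=treatments, name="MGIDI")
        selected = [t for t, s in zip(treatments, selected_mask) if s]
        diff = selection_differentials(self.means, selected, self.spec)
        return MGIDIResults(
            means=self.means,
            rescaled=rescaled,
            factor_model=model,
            spec=self.spec,
            gamma=gamma,
            distances=distances,
            ranks=pd.Series(ranks, index=treatments, name="rank"),
            selected=selected,
            contributions=pd.DataFrame(
                omega, index=treatments, columns=model.factor_names
            ),
            factor_distances=pd.DataFrame(
                D, index=treatments, columns=model.factor_names
            ),
            at_ideal=pd.Series(at_ideal, index=treatments),
            differentials=diff,
            weight_mode=self.weight_mode,
        )


def run_pipeline(
    data: LongTable | MeansTable,
    spec: IdeotypeSpec,
    term: list[str] | None = None,
    k: int | None = None,
    weights: dict[str, float] | None = None,
    **kwargs,
) -> MGIDIResults:
    """One-call orchestration from raw data to a full MGIDIResults.

    ``data`` may be long-format trial observations (pseudo-replicates
    are averaged and the marginal means of ``term`` taken) or an
    already-computed means table.
    """
    if weights:
        spec = spec.with_weights(weights)
    if isinstance(data, MeansTable):
        model = MGIDI(data, spec, **kwargs)
    else:
        model = MGIDI.from_long(data, spec, term=term, **kwargs)
    return model.fit(k=k)
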