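"""Direction-aware 0-100 rescaling of a treatment-by-trait means table.

Each trait column is mapped linearly so that, with the default bounds,
the desired pole is always 100: for a "higher is better" trait the
column maximum maps to 100 and the minimum to 0; for a "lower is
better" trait the assignment is reversed. The linear map is

    rX_ij = (eta_n - phi_n) / (eta_o - phi_o) * (x_ij - eta_o) + eta_n

where (eta_o, phi_o) are the observed column max/min and (eta_n, phi_n)
the new bounds, (100, 0) for "higher" and (0, 100) for "lower". After
rescaling the hypothetical ideal treatment scores 100 in every column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import IdeotypeSpec, MeansTable

__all__ = ["RescaledTable", "DegenerateTraitError", "rescale_trait", "rescale_table"]

logger = logging.getLogger(__name__)


class DegenerateTraitError(ValueError):
    """A trait column is constant, so the rescaling map is undefined."""


@dataclass
class RescaledTable:
    """Rescaled means (same shape and labels as the source MeansTable)."""

    values: pd.DataFrame

    @property
    def treatments(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


def rescale_trait(
    values: np.ndarray,
    direction: str,
    new_max: float = 100.0,
    new_min: float = 0.0,
) -> np.ndarray:
    """Rescale one trait column so the desired pole is ``new_max``.

    ``direction`` "higher" sends the observed maximum to ``new_max``;
    "lower" sends the observed *minimum* there (the bounds swap roles).
    """
    x = np.asarray(values, dtype=float)
    eta_o, phi_o = x.max(), x.min()
    if eta_o == phi_o:
        raise DegenerateTraitError("constant trait column cannot be rescaled")
    if direction == "higher":
        eta_n, phi_n = new_max, new_min
    elif direction == "lower":
        eta_n, phi_n = new_min, new_max
    else:
        raise ValueError(f"direction must be 'higher'/'lower', got {direction!r}")
    return (eta_n - phi_n) / (eta_o - phi_o) * (x - eta_o) + eta_n


def rescale_table(
    means: MeansTable,
    spec: IdeotypeSpec,
    strict: bool = False,
) -> RescaledTable:
    """Column-wise rescaling of a means table per the ideotype spec.

    Constant columns carry no ranking information and are dropped with a
    logged warning (``strict=True`` raises instead).
    """
    spec.validate_for(means.traits)
    out = {}
    for trait in means.traits:
        ts = spec.traits[trait]
        col = means.values[trait].to_numpy(dtype=float)
        try:
            out[trait] = rescale_trait(col, ts.direction, ts.new_max, ts.new_min)
        except DegenerateTraitError:
            if strict:
                raise DegenerateTraitError(
                    f"trait {trait!r} is constant across treatments"
                ) from None
            logger.warning("dropping constant trait %r", trait)
    if len(out) < 2:
        raise DegenerateTraitError(
            "fewer than 2 informative traits remain after dropping constants"
        )
    df = pd.DataFrame(out, index=means.values.index)
    return RescaledTable(df)
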