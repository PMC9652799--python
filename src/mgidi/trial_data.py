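"""Data model and I/O for multi-trait trial observations.

A trial is stored long-format: one row per experimental unit (or per
plant when a within-plot unit column is present), categorical design
factors (treatment factors plus block), and numeric trait columns.
Treatment-by-trait mean tables (``MeansTable``) are the input to the
downstream ranking pipeline; the ``IdeotypeSpec`` declares, per trait,
which direction is desirable and an optional weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LongTable",
    "MeansTable",
    "IdeotypeSpec",
    "SchemaError",
    "read_long_table",
    "average_within_units",
    "cell_means",
    "lab_to_lch",
    "STRAWBERRY_LOWER_TRAITS",
]

#: Traits of the strawberry ideotype for which lower values are desired:
#: non-commercial fruit number/weight, water use, phenological delays,
#: phyllochron and acidity.
STRAWBERRY_LOWER_TRAITS = frozenset(
    {"NNCF", "WNCF", "AWNCF", "WUE", "NDBF", "NDFF", "NDBH", "PHYL", "TA"}
)


class SchemaError(ValueError):
    """Input file or table does not match the declared schema."""


@dataclass
class LongTable:
    """Long-format trial data: design factors + numeric traits.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per observation.
    factor_columns : list of str
        Ordered categorical design factors (treatment factors + block).
    trait_columns : list of str
        Ordered numeric trait names.
    unit_column : str or None
        Within-plot pseudo-replication identifier (e.g. plant); ``None``
        once plants have been averaged into plot values.
    """

    data: pd.DataFrame
    factor_columns: list[str]
    trait_columns: list[str]
    unit_column: str | None = None

    def __post_init__(self) -> None:
        cols = list(self.factor_columns) + list(self.trait_columns)
        if self.unit_column is not None:
            cols.append(self.unit_column)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        traits = self.data[self.trait_columns]
        bad = ~np.isfinite(traits.to_numpy(dtype=float, na_value=np.nan))
        if bad.any() and self.unit_column is None:
            rows = sorted(set(np.nonzero(bad)[0].tolist()))
            raise SchemaError(f"non-finite trait value(s) at row(s) {rows[:5]}")
        if self.unit_column is None and len(self.data):
            dup = self.data.duplicated(subset=self.factor_columns)
            if dup.any():
                raise SchemaError(
                    "duplicate factor-level combinations in unit-averaged data"
                )

    @property
    def n_records(self) -> int:
        return len(self.data)


@dataclass
class MeansTable:
    """Treatment-by-trait matrix of estimated means (g x p)."""

    values: pd.DataFrame  # index = treatments, columns = traits

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise SchemaError(
                f"means table needs >= 2 treatments and >= 2 traits, "
                f"got {self.values.shape}"
            )
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate treatment labels")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate trait names")
        arr = self.values.to_numpy(dtype=float, na_value=np.nan)
        if not np.isfinite(arr).all():
            raise SchemaError("means table has missing or non-finite cells")

    @property
    def treatments(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_csv(cls, path) -> "MeansTable":
        df = pd.read_csv(path)
        return cls(df.set_index(df.columns[0]))

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "treatment"
        out.to_csv(path)


@dataclass
class TraitSpec:
    """Direction, weight and rescaling bounds for one trait."""

    direction: str  # "higher" or "lower"
    weight: float = 1.0
    new_max: float = 100.0
    new_min: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError(f"direction must be 'higher'/'lower', got {self.direction!r}")
        if self.weight < 0:
            raise ValueError("trait weight must be non-negative")
        if self.new_max == self.new_min:
            raise ValueError("new_max must differ from new_min")


@dataclass
class IdeotypeSpec:
    """Per-trait selection directions and weights defining the ideal treatment."""

    traits: dict[str, TraitSpec] = field(default_factory=dict)

    @classmethod
    def from_directions(
        cls,
        directions: dict[str, str],
        weights: dict[str, float] | None = None,
    ) -> "IdeotypeSpec":
        weights = weights or {}
        return cls(
            {
                name: TraitSpec(direction=d, weight=float(weights.get(name, 1.0)))
                for name, d in directions.items()
            }
        )

    @classmethod
    def uniform(cls, trait_names, direction: str = "higher") -> "IdeotypeSpec":
        return cls({t: TraitSpec(direction=direction) for t in trait_names})

    @classmethod
    def strawberry(cls, trait_names) -> "IdeotypeSpec":
        """Preset for the 22-trait strawberry ideotype (9 lower-is-better)."""
        return cls(
            {
                t: TraitSpec("lower" if t in STRAWBERRY_LOWER_TRAITS else "higher")
                for t in trait_names
            }
        )

    def validate_for(self, trait_names) -> None:
        missing = [t for t in trait_names if t not in self.traits]
        if missing:
            raise SchemaError(f"no direction declared for trait(s): {', '.join(missing)}")
        w = [self.traits[t].weight for t in trait_names]
        if not any(x > 0 for x in w):
            raise ValueError("at least one trait weight must be positive")

    def directions(self, trait_names) -> list[str]:
        return [self.traits[t].direction for t in trait_names]

    def weights(self, trait_names) -> np.ndarray:
        return np.array([self.traits[t].weight for t in trait_names], dtype=float)

    def with_weights(self, weights: dict[str, float]) -> "IdeotypeSpec":
        new = dict(self.traits)
        for name, w in weights.items():
            if name not in new:
                raise SchemaError(f"weight given for undeclared trait {name!r}")
            new[name] = replace(new[name], weight=float(w))
        return IdeotypeSpec(new)

    @classmethod
    def from_yaml(cls, path) -> "IdeotypeSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = {}
        for name, entry in raw.items():
            if isinstance(entry, str):
                traits[name] = TraitSpec(direction=entry)
            else:
                traits[name] = TraitSpec(
                    direction=entry["direction"],
                    weight=float(entry.get("weight", 1.0)),
                    new_max=float(entry.get("new_max", 100.0)),
                    new_min=float(entry.get("new_min", 0.0)),
                )
        return cls(traits)


def read_long_table(
    path,
    factor_names: list[str],
    trait_names: list[str],
    unit_column: str | None = None,
) -> LongTable:
    """Read a delimited text file into a validated :class:`LongTable`.

    Raises
    ------
    SchemaError
        If a declared column is missing or a trait cell is non-numeric
        (the error names the offending row).
    """
    df = pd.read_csv(path)
    declared = list(factor_names) + list(trait_names) + (
        [unit_column] if unit_column else []
    )
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for t in trait_names:
        coerced = pd.to_numeric(df[t], errors="coerce")
        bad = coerced.isna() & df[t].notna()
        if bad.any():
            idx = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(f"non-numeric value in trait {t!r} at row {idx}")
        df[t] = coerced
    for f in factor_names:
        if df[f].isna().any():
            idx = int(np.nonzero(df[f].isna().to_numpy())[0][0])
            raise SchemaError(f"missing level for factor {f!r} at row {idx}")
        df[f] = df[f].astype(str)
    return LongTable(
        data=df[declared].copy(),
        factor_columns=list(factor_names),
        trait_columns=list(trait_names),
        unit_column=unit_column,
    )


def average_within_units(table: LongTable) -> LongTable:
    """Average pseudo-replicates (plants) within each plot.

    Missing trait values at the unit level are dropped from that mean;
    a plot cell with no observed value for some trait is an error.
    Idempotent in the sense that re-averaging a unit-averaged table is a
    no-op (but requires ``unit_column`` to be set, so this function is
    only called once per pipeline).
    """
    if table.unit_column is None:
        raise ValueError("table has no unit column; nothing to average")
    grouped = table.data.groupby(table.factor_columns, sort=False, observed=True)
    means = grouped[table.trait_columns].mean().reset_index()
    if means[table.trait_columns].isna().any().any():
        bad = [
            t for t in table.trait_columns if means[t].isna().any()
        ]
        raise SchemaError(
            f"plot(s) with no observed value for trait(s) {', '.join(bad)}"
        )
    return LongTable(
        data=means,
        factor_columns=list(table.factor_columns),
        trait_columns=list(table.trait_columns),
        unit_column=None,
    )


def _check_balance(table: LongTable) -> None:
    counts = table.data.groupby(table.factor_columns, observed=True).size()
    n_cells = int(np.prod([table.data[f].nunique() for f in table.factor_columns]))
    if counts.nunique() != 1 or len(counts) != n_cells:
        raise SchemaError(
            "unbalanced design: cell counts vary (or cells are missing) across "
            f"the full factorial x block layout ({len(counts)}/{n_cells} cells, "
            f"min {counts.min()}, max {counts.max()})"
        )


def cell_means(table: LongTable, term: list[str], label_sep: str = "_") -> MeansTable:
    """Marginal means of a factorial term, averaged over blocks and the
    factors not in ``term``.

    The design must be balanced over the ignored factors (checked),
    otherwise the marginal means would depend on the sum-of-squares
    convention. Row labels join the term's factor levels with ``"_"`` in
    factor-declaration order.
    """
    if table.unit_column is not None:
        raise ValueError("average within units before computing cell means")
    if not term:
        raise ValueError("term must name at least one factor")
    unknown = [f for f in term if f not in table.factor_columns]
    if unknown:
        raise SchemaError(f"unknown factor(s) in term: {', '.join(unknown)}")
    _check_balance(table)
    # balance of the requested term over the ignored factors
    ordered = [f for f in table.factor_columns if f in term]
    counts = table.data.groupby(ordered, observed=True).size()
    if counts.nunique() != 1:
        raise SchemaError(
            f"unbalanced cell counts for term {'*'.join(ordered)}: "
            f"{counts.to_dict()}"
        )
    means = (
        table.data.groupby(ordered, observed=True, sort=False)[table.trait_columns]
        .mean()
    )
    if len(ordered) == 1:
        labels = [str(v) for v in means.index]
    else:
        labels = [label_sep.join(map(str, key)) for key in means.index]
    out = means.copy()
    out.index = pd.Index(labels, name="treatment")
    return MeansTable(out)


def lab_to_lch(a_star: float, b_star: float) -> tuple[float, float]:
    """Convert CIELab chromatic coordinates to CIELCh polar form.

    Chroma is the Euclidean norm of ``(a*, b*)``; the hue angle is the
    quadrant-correct two-argument arctangent mapped to [0, 360) degrees
    (the textbook one-argument ``arctan(b*/a*)`` loses the quadrant).

    Returns
    -------
    (chroma, hue_deg)
        ``hue_deg`` is ``nan`` when ``a* = b* = 0`` (hue undefined).
    """
    chroma = math.hypot(a_star, b_star)
    if chroma == 0.0:
        return 0.0, float("nan")
    hue = math.degrees(math.atan2(b_star, a_star)) % 360.0
    return chroma, hue
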