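"""Individual-level trait tables and species-level summaries.

The central container is :class:`TraitMeasurementTable`: a validated
long-format table of (species, individual, trait, value) records — the shape
individual measurements take in large plant-trait compilations.  Values are
unit-free by contract; unit consistency is the caller's responsibility.

:func:`summarize` collapses one trait to species level under a chosen
transformation, computing BOTH aggregation orders at once:

* ``mean_transformed`` — transform-then-aggregate, mean of f(x_j);
* ``transform_of_mean`` — aggregate-then-transform, f(mean of x_j).

For a non-linear f the two differ by the Jensen gap (see
:mod:`traitagg.aggregation`).  The stored within-species variance is the
population variance (divide by n), matching the curvature-correction formula
literally; sample variance (n-1) is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transforms import DomainError, TransformSpec, apply_transform

__all__ = [
    "ValidationError",
    "TraitMeasurementTable",
    "SpeciesTraitSummary",
    "read_trait_csv",
    "summarize",
    "write_summary_csv",
    "read_summary_csv",
]

logger = logging.getLogger(__name__)

#: Canonical column order for trait tables.
TRAIT_COLUMNS = ("species", "individual", "trait", "value")

#: Canonical column order for summary tables.
SUMMARY_COLUMNS = (
    "species",
    "trait",
    "n",
    "mean_raw",
    "var_raw_pop",
    "mean_transformed",
    "transform_of_mean",
)


class ValidationError(ValueError):
    """A trait table violates its structural invariants."""


class TraitMeasurementTable:
    """Validated long-format table of individual trait measurements.

    Invariants enforced at construction:

    * (species, individual, trait) triples are unique;
    * values are finite;
    * every individual belongs to exactly one species.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table is missing columns: {missing}")
        df = df.loc[:, list(TRAIT_COLUMNS)].copy()
        df["species"] = df["species"].astype(str)
        df["individual"] = df["individual"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = pd.to_numeric(df["value"])
        if not np.isfinite(df["value"].to_numpy()).all():
            bad = df.index[~np.isfinite(df["value"].to_numpy())][0]
            raise ValidationError(f"non-finite value in row {bad}")
        dup = df.duplicated(subset=["species", "individual", "trait"])
        if dup.any():
            s, i, t = df.loc[dup.idxmax(), ["species", "individual", "trait"]]
            raise ValidationError(
                f"duplicate (species, individual, trait) triple: ({s!r}, {i!r}, {t!r})"
            )
        n_species_per_ind = df.groupby("individual")["species"].nunique()
        multi = n_species_per_ind[n_species_per_ind > 1]
        if len(multi):
            raise ValidationError(
                f"individual {multi.index[0]!r} is assigned to {multi.iloc[0]} species"
            )
        self._df = df.reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (do not mutate)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def species(self) -> list[str]:
        return sorted(self._df["species"].unique())

    def traits(self) -> list[str]:
        return sorted(self._df["trait"].unique())

    def n_individuals(self) -> int:
        return self._df["individual"].nunique()

    def trait_frame(self, trait: str) -> pd.DataFrame:
        """Records of one trait, columns (species, individual, value)."""
        sub = self._df[self._df["trait"] == trait]
        if sub.empty:
            raise ValidationError(f"trait {trait!r} not present in table")
        return sub[["species", "individual", "value"]].reset_index(drop=True)

    def with_records(self, records: pd.DataFrame) -> "TraitMeasurementTable":
        """A new table with extra records appended (revalidated)."""
        return TraitMeasurementTable(pd.concat([self._df, records], ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, float]]
    ) -> "TraitMeasurementTable":
        return cls(pd.DataFrame(records, columns=list(TRAIT_COLUMNS)))


@dataclass(frozen=True)
class SpeciesTraitSummary:
    """Per species x trait summary under a chosen transformation.

    ``var_raw_pop`` is the population variance sum((x_j - mean)^2)/n, zero
    whenever n = 1.  ``mean_transformed`` is None when the summary was built
    from species-level input that lacked individual values.
    """

    species_id: str
    trait: str
    n: int
    mean_raw: float
    var_raw_pop: float
    transform_of_mean: float
    mean_transformed: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"summary for {self.species_id!r} has n < 1")
        if self.var_raw_pop < 0:
            raise ValidationError(f"summary for {self.species_id!r} has negative variance")


def read_trait_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> TraitMeasurementTable:
    """Read a long-format trait CSV into a validated table.

    Parameters
    ----------
    path:
        Comma-delimited UTF-8 file with a header row.
    column_map:
        Optional mapping from canonical names (``species``, ``individual``,
        ``trait``, ``value``) to the file's column names.

    Rows with a missing value are dropped with a logged count; a non-numeric
    (non-blank) value is a parse error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trait CSV not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in TRAIT_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    df = df.rename(columns=rename)

    raw = df["value"]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        # +2: header line plus 1-based numbering, i.e. the line in the file
        raise ValidationError(
            f"{path}: non-numeric value {raw[row]!r} in data row {row + 1} (file line {row + 2})"
        )
    df["value"] = numeric
    n_missing = int(numeric.isna().sum())
    if n_missing:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_missing)
        df = df[numeric.notna()]
    return TraitMeasurementTable(df)


def summarize(
    table: TraitMeasurementTable,
    trait: str,
    t: TransformSpec,
    variance: str = "population",
) -> list[SpeciesTraitSummary]:
    """Collapse one trait to species level under both aggregation orders.

    Returns one :class:`SpeciesTraitSummary` per species holding at least one
    measurement of ``trait``, sorted by species identifier.  ``variance``
    selects the divisor of the stored raw variance: ``"population"`` (n, the
    default, matching the curvature-correction formula) or ``"sample"``
    (n-1; zero when n = 1).

    Raises
    ------
    DomainError
        If any value lies outside the transform's domain, naming the species
        and value.
    """
    if variance not in ("population", "sample"):
        raise ValueError(f"variance must be 'population' or 'sample', got {variance!r}")
    frame = table.trait_frame(trait)
    out: list[SpeciesTraitSummary] = []
    for species, grp in frame.groupby("species", sort=True):
        values = grp["value"].to_numpy(dtype=float)
        try:
            transformed = apply_transform(t, values)
        except DomainError as e:
            raise DomainError(
                f"species {species!r}, trait {trait!r}: {e}"
            ) from e
        n = len(values)
        if np.all(values == values[0]):
            # zero spread: short-circuit so the gap closes exactly, not to fp noise
            v = float(values[0])
            fv = float(transformed[0])
            out.append(
                SpeciesTraitSummary(
                    species_id=str(species), trait=trait, n=n, mean_raw=v,
                    var_raw_pop=0.0, mean_transformed=fv, transform_of_mean=fv,
                )
            )
            continue
        mean_raw = float(values.mean())
        if variance == "population":
            var = float(values.var(ddof=0))
        else:
            var = float(values.var(ddof=1)) if n > 1 else 0.0
        out.append(
            SpeciesTraitSummary(
                species_id=str(species),
                trait=trait,
                n=n,
                mean_raw=mean_raw,
                var_raw_pop=var,
                mean_transformed=float(transformed.mean()),
                transform_of_mean=float(apply_transform(t, [mean_raw])[0]),
            )
        )
    return out


def write_summary_csv(
    summaries: Sequence[SpeciesTraitSummary], path: str | Path
) -> None:
    """Write summaries as CSV, one row per species x trait.

    Floats are written with 12 significant digits so a write/read round trip
    is lossless well below 1e-10.
    """
    if not summaries:
        raise ValidationError("refusing to write an empty summary list")
    rows = [
        {
            "species": s.species_id,
            "trait": s.trait,
            "n": s.n,
            "mean_raw": s.mean_raw,
            "var_raw_pop": s.var_raw_pop,
            "mean_transformed": s.mean_transformed,
            "transform_of_mean": s.transform_of_mean,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_summary_csv(path: str | Path) -> list[SpeciesTraitSummary]:
    """Read a summary CSV written by :func:`write_summary_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"summary CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing summary columns {missing}")
    out = []
    for _, row in df.iterrows():
        mt = row["mean_transformed"]
        out.append(
            SpeciesTraitSummary(
                species_id=str(row["species"]),
                trait=str(row["trait"]),
                n=int(row["n"]),
                mean_raw=float(row["mean_raw"]),
                var_raw_pop=float(row["var_raw_pop"]),
                mean_transformed=None if pd.isna(mt) else float(mt),
                transform_of_mean=float(row["transform_of_mean"]),
            )
        )
    return out
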