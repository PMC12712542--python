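"""Root-trait demonstration: the SRL-RTD-D identity under both aggregation orders.

Assuming cylindrical fine-root geometry, specific root length (root length
per unit dry mass) is fixed by diameter D and root tissue density RTD:

    SRL = 4 / (pi * RTD * D^2),
    ln SRL = ln(4/pi) - ln RTD - 2 ln D.

The identity holds per individual root segment, so averaging the *log*
values per species preserves it exactly: regressing species mean-log SRL on
mean-log RTD and mean-log D must return intercept ln(4/pi) ~ 0.2416,
coefficients -1 (lnRTD) and -2 (lnD), and R^2 = 1 for any data in which SRL
was derived from the other two traits.  Averaging raw values first and
transforming the species means breaks the identity: each species picks up
its own Jensen offset, the fit degrades, and the coefficients drift.

:func:`run_demo` runs both trivariate fits plus the six pairwise
regressions (three trait pairs x two aggregation orders) and reports them
side by side.  Units must be mutually consistent (e.g. D in cm, RTD in
g cm^-3, SRL in cm g^-1); the constant 4/pi is dimensionless only then —
an inconsistent unit choice shifts the intercept but not the slopes or fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ols import RegressionFit, ols_fit
from .trait_data import TraitMeasurementTable, summarize
from .transforms import DomainError, get_transform

__all__ = ["DemoReport", "compute_srl", "derive_srl_column", "run_demo"]

logger = logging.getLogger(__name__)

#: Intercept of the log-linear identity.
LN_4_OVER_PI = math.log(4.0 / math.pi)

#: (response, predictor) pairs reported in the pairwise comparison.
PAIRS = (("SRL", "RTD"), ("SRL", "D"), ("RTD", "D"))

#: Aggregation-order labels.
ORDERS = ("transform_first", "aggregate_first")


@dataclass(frozen=True)
class DemoReport:
    """Side-by-side regression results under both aggregation orders."""

    trivariate_transform_first: RegressionFit
    trivariate_transform_last: RegressionFit
    pairwise: dict[tuple[str, str, str], RegressionFit]
    species_count: int
    individual_count: int
    skipped_individuals: int


def compute_srl(rtd: float, d: float) -> float:
    """Specific root length from tissue density and diameter: 4/(pi RTD D^2).

    Caller guarantees unit consistency.  Nonpositive inputs are a domain
    error (the cylindrical formula has no meaning there).
    """
    if rtd <= 0:
        raise DomainError(f"RTD must be > 0, got {rtd}")
    if d <= 0:
        raise DomainError(f"D must be > 0, got {d}")
    return 4.0 / (math.pi * rtd * d * d)


def derive_srl_column(
    table: TraitMeasurementTable,
    rtd_trait: str = "RTD",
    d_trait: str = "D",
    srl_trait: str = "SRL",
) -> tuple[TraitMeasurementTable, int]:
    """Add an SRL record for every individual measured for both RTD and D.

    Individuals missing either trait are skipped; the skip count is returned
    alongside the augmented table (and logged).  It is an error if no
    individual carries both traits.
    """
    df = table.df
    wide = (
        df[df["trait"].isin([rtd_trait, d_trait])]
        .pivot_table(index=["species", "individual"], columns="trait",
                     values="value", aggfunc="first")
        .reset_index()
    )
    for col in (rtd_trait, d_trait):
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide.dropna(subset=[rtd_trait, d_trait])
    skipped = len(wide) - len(complete)
    if complete.empty:
        raise ValueError(
            f"no individual has both {rtd_trait!r} and {d_trait!r}; cannot derive {srl_trait!r}"
        )
    if skipped:
        logger.info("skipped %d individual(s) missing %r or %r", skipped, rtd_trait, d_trait)
    srl = [
        compute_srl(rtd, d)
        for rtd, d in zip(complete[rtd_trait].to_numpy(), complete[d_trait].to_numpy())
    ]
    new = pd.DataFrame(
        {
            "species": complete["species"].to_numpy(),
            "individual": complete["individual"].to_numpy(),
            "trait": srl_trait,
            "value": srl,
        }
    )
    return table.with_records(new), skipped


def _species_log_frame(
    table: TraitMeasurementTable, traits: tuple[str, str, str],
    split_individuals: bool,
) -> pd.DataFrame:
    """Species-level mean-of-log and log-of-mean values for three traits.

    With ``split_individuals`` the response trait (first in ``traits``) is
    summarised from the second half of each species' individuals and the
    predictors from the first half (odd individual to the predictors),
    emulating traits measured on disjoint individual sets.
    """
    log_t = get_transform("log")
    if not split_individuals:
        frames = {tr: summarize(table, tr, log_t) for tr in traits}
    else:
        df = table.df
        halves: dict[str, set[str]] = {"first": set(), "second": set()}
        for _, grp in df.groupby("species", sort=True):
            inds = sorted(grp["individual"].unique())
            half = (len(inds) + 1) // 2
            halves["first"].update(inds[:half])
            halves["second"].update(inds[half:])
        response, *predictors = traits
        sub_resp = TraitMeasurementTable(df[df["individual"].isin(halves["second"])])
        sub_pred = TraitMeasurementTable(df[df["individual"].isin(halves["first"])])
        frames = {response: summarize(sub_resp, response, log_t)}
        frames.update({tr: summarize(sub_pred, tr, log_t) for tr in predictors})

    cols = {}
    for tr, summaries in frames.items():
        cols[tr] = pd.DataFrame(
            {
                "species": [s.species_id for s in summaries],
                f"mean_ln_{tr}": [s.mean_transformed for s in summaries],
                f"ln_mean_{tr}": [s.transform_of_mean for s in summaries],
            }
        ).set_index("species")
    merged = pd.concat(cols.values(), axis=1, join="inner").sort_index()
    return merged


def run_demo(
    table: TraitMeasurementTable,
    rtd_trait: str = "RTD",
    d_trait: str = "D",
    srl_trait: str = "SRL",
    split_individuals: bool = False,
) -> DemoReport:
    """Derive SRL, aggregate under both orders, and fit all regressions.

    Fits, on species-level values of the three traits under log transform:

    * transform-first trivariate: mean-ln SRL ~ mean-ln RTD + mean-ln D
      (exact identity: intercept ln(4/pi), slopes -1 and -2, R^2 = 1
      whenever SRL was derived per individual and individuals are shared);
    * aggregate-first trivariate: ln-mean SRL ~ ln-mean RTD + ln-mean D;
    * the six pairwise fits (SRL~RTD, SRL~D, RTD~D) x two orders.

    ``split_individuals=True`` summarises SRL from a disjoint half of each
    species' individuals (the unequal-sample-size scenario), under which the
    transform-first fit is only approximate.
    """
    augmented, skipped = derive_srl_column(table, rtd_trait, d_trait, srl_trait)
    traits = (srl_trait, rtd_trait, d_trait)
    merged = _species_log_frame(augmented, traits, split_individuals)
    n_species = len(merged)
    if n_species < 4:
        raise ValueError(f"need >= 4 species with all three traits, found {n_species}")

    def fit(response: str, predictors: list[str], order: str) -> RegressionFit:
        prefix = "mean_ln_" if order == "transform_first" else "ln_mean_"
        return ols_fit(
            merged[f"{prefix}{response}"].to_numpy(),
            {f"ln{p}": merged[f"{prefix}{p}"].to_numpy() for p in predictors},
        )

    tri_first = fit(srl_trait, [rtd_trait, d_trait], "transform_first")
    tri_last = fit(srl_trait, [rtd_trait, d_trait], "aggregate_first")
    pairs = ((srl_trait, rtd_trait), (srl_trait, d_trait), (rtd_trait, d_trait))
    pairwise = {
        (resp, pred, order): fit(resp, [pred], order)
        for resp, pred in pairs
        for order in ORDERS
    }
    return DemoReport(
        trivariate_transform_first=tri_first,
        trivariate_transform_last=tri_last,
        pairwise=pairwise,
        species_count=n_species,
        individual_count=augmented.n_individuals(),
        skipped_individuals=skipped,
    )
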