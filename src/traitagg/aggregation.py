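"""Jensen gap between the two aggregation orders and its quadratic correction.

For a species with individual measurements x_1..x_n and a non-linear
transformation f, averaging transformed values and transforming the average
disagree.  The *Jensen gap* is defined here as

    gap = mean of f(x_j)  -  f(mean of x_j),

which is <= 0 for concave f (log, sqrt) and >= 0 for convex f, with equality
iff the within-species variance is zero or f is linear.  A second-order
Taylor expansion of f about the raw mean gives the quadratic approximation

    gap  ~=  f''(x_bar) * s2 / 2,       s2 = sum((x_j - x_bar)^2) / n,

so the mean of transformed values can be recovered from species-level
summaries alone as f(x_bar) + f''(x_bar) * s2 / 2.  For the log transform
this reads ln(x_bar) - s2 / (2 * x_bar^2): the distortion grows with the
ratio of within-species variance to the squared species mean.

:func:`species_offset_C` evaluates the species-specific offset by which an
aggregate-then-transform trait relationship deviates from the linearised
individual-level relationship f(y) = a + b g(x): since the offset depends on
each species' own means and variances, it bends an exactly linear
individual-level law into a noisy, usually non-linear species-level one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trait_data import SpeciesTraitSummary
from .transforms import TransformSpec, apply_transform, second_derivative_at

__all__ = [
    "JensenGapResult",
    "jensen_gap_exact",
    "jensen_gap_quadratic",
    "jensen_gap",
    "corrected_transformed_mean",
    "species_offset_C",
]


@dataclass(frozen=True)
class JensenGapResult:
    """Exact gap, its quadratic approximation, and their absolute difference."""

    exact_gap: float
    approx_gap: float

    @property
    def abs_error(self) -> float:
        return abs(self.exact_gap - self.approx_gap)


def jensen_gap_exact(values: Sequence[float] | np.ndarray, t: TransformSpec) -> float:
    """mean(f(x)) - f(mean(x)) for one species' measurements.

    Zero for linear transforms or zero spread; strictly negative for strictly
    concave f on non-degenerate data.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    transformed = apply_transform(t, arr)
    mean_raw = float(arr.mean())
    return float(transformed.mean() - apply_transform(t, [mean_raw])[0])


def jensen_gap_quadratic(mean_raw: float, var_raw_pop: float, t: TransformSpec) -> float:
    """Second-order approximation f''(mean) * var / 2 of the Jensen gap.

    ``var_raw_pop`` is the population (divide-by-n) within-species variance.
    """
    if var_raw_pop < 0:
        raise ValueError(f"var_raw_pop must be >= 0, got {var_raw_pop}")
    return 0.5 * second_derivative_at(t, mean_raw) * var_raw_pop


def jensen_gap(values: Sequence[float] | np.ndarray, t: TransformSpec) -> JensenGapResult:
    """Exact and quadratic gap for one species' measurements."""
    arr = np.asarray(values, dtype=float)
    exact = jensen_gap_exact(arr, t)
    approx = jensen_gap_quadratic(float(arr.mean()), float(arr.var(ddof=0)), t)
    return JensenGapResult(exact_gap=exact, approx_gap=approx)


def corrected_transformed_mean(
    mean_raw: float,
    sd_raw: float,
    n: int,
    t: TransformSpec,
    sd_convention: str = "population",
) -> float:
    """Estimate the mean of transformed values from species-level summaries.

    When only (mean, SD, n) per species are available — the usual shape of
    database summaries — the transform-then-aggregate species value can still
    be approximated as f(mean) + f''(mean) * var_pop / 2.

    Parameters
    ----------
    sd_convention:
        ``"population"`` if ``sd_raw`` is the divide-by-n SD, ``"sample"``
        if it is the divide-by-(n-1) SD reported by most sources; sample SD
        is converted to population variance via (n-1)/n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sd_raw < 0:
        raise ValueError(f"sd_raw must be >= 0, got {sd_raw}")
    if sd_convention == "population":
        var_pop = sd_raw**2
    elif sd_convention == "sample":
        var_pop = sd_raw**2 * (n - 1) / n
    else:
        raise ValueError(f"sd_convention must be 'population' or 'sample', got {sd_convention!r}")
    f_of_mean = float(apply_transform(t, [mean_raw])[0])
    return f_of_mean + jensen_gap_quadratic(mean_raw, var_pop, t)


def species_offset_C(
    summary_x: SpeciesTraitSummary,
    summary_y: SpeciesTraitSummary,
    b: float,
    t_f: TransformSpec,
    t_g: TransformSpec,
) -> float:
    """Species-specific offset of the aggregate-then-transform relationship.

    If the individual-level law is f(y_j) = a + b g(x_j), substituting the
    quadratic Jensen correction for both traits shows that the species-level
    aggregate-then-transform values obey approximately

        f(y_bar) ~= a + b g(x_bar) + C,
        C = b * g''(x_bar) * var_x / 2  -  f''(y_bar) * var_y / 2,

    where var are the population within-species variances (the 1/n of the
    summed squared deviations is already inside ``var_raw_pop``).  C varies
    across species, so the species-level relation is linear plus a
    species-specific perturbation.
    """
    half_x = jensen_gap_quadratic(summary_x.mean_raw, summary_x.var_raw_pop, t_g)
    half_y = jensen_gap_quadratic(summary_y.mean_raw, summary_y.var_raw_pop, t_f)
    return b * half_x - half_y
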