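"""Exact decomposition of aggregation-order effects on slope and correlation.

Let x, y be the species-level trait values under one aggregation order (the
reference, by default transform-then-aggregate) and x*, y* the values under
the other order.  Define the per-species bias vectors

    theta = x - x*,        omega = y - y*,

so that x* = x - theta and y* = y - omega.  Bilinearity of the covariance
then decomposes the slope of the starred regression exactly:

    b(x*, y*) = cov(x*, y*) / var(x*)
              = [cov(x,y) - cov(x,omega) - cov(theta,y) + cov(theta,omega)]
                / [var(x) + var(theta) - 2 cov(x,theta)]

and analogously for the Pearson correlation with the matching denominator
for y*.  The identity is algebraic — exact for any common covariance divisor
(n or n-1; this module uses n-1 throughout, matching OLS conventions) — and
shows that the difference between the two orders is governed entirely by the
variance-covariance structure of (x, y, theta, omega); a constant (mean)
bias drops out.

Note on sign convention: with theta defined as x - x*, the starred values
are x - theta, so the cross terms enter with minus signs; a rendering of the
decomposition as cov(x+theta, y+omega)/var(x+theta) is consistent only with
the opposite sign of the bias vectors.  The direct and reconstructed routes
are always computed independently here, and their agreement is asserted in
the test suite to 1e-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trait_data import TraitMeasurementTable, summarize
from .transforms import TransformSpec

__all__ = [
    "BiasDecomposition",
    "bias_vectors",
    "slope_decomposition",
    "correlation_decomposition",
    "compare_aggregation_orders",
]

logger = logging.getLogger(__name__)

#: Component names, in reporting order.
COMPONENT_FIELDS = (
    "cov_xy",
    "cov_x_omega",
    "cov_theta_y",
    "cov_theta_omega",
    "var_x",
    "var_theta",
    "cov_x_theta",
    "var_y",
    "var_omega",
    "cov_y_omega",
)


@dataclass(frozen=True)
class BiasDecomposition:
    """Covariance components plus direct and reconstructed slope/correlation.

    ``slope_direct`` and ``corr_direct`` are computed from the starred
    vectors (x - theta, y - omega) directly; the ``_reconstructed``
    counterparts are assembled from the ten components.  ``slope_unbiased``
    and ``corr_unbiased`` describe the reference (x, y) regression.
    All components share the same covariance divisor (``ddof``).
    """

    cov_xy: float
    cov_x_omega: float
    cov_theta_y: float
    cov_theta_omega: float
    var_x: float
    var_theta: float
    cov_x_theta: float
    var_y: float
    var_omega: float
    cov_y_omega: float
    slope_direct: float
    slope_reconstructed: float
    slope_unbiased: float
    corr_direct: float
    corr_reconstructed: float
    corr_unbiased: float
    n_species: int
    ddof: int = 1

    def components(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in COMPONENT_FIELDS}


def bias_vectors(
    x: Sequence[float],
    x_star: Sequence[float],
    y: Sequence[float],
    y_star: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-species bias vectors theta = x - x*, omega = y - y*."""
    x, x_star, y, y_star = (np.asarray(v, dtype=float) for v in (x, x_star, y, y_star))
    lengths = {v.size for v in (x, x_star, y, y_star)}
    if len(lengths) != 1:
        raise ValueError(f"vectors must share one length, got sizes {sorted(lengths)}")
    if x.size < 2:
        raise ValueError("need at least 2 species")
    return x - x_star, y - y_star


def _cov(a: np.ndarray, b: np.ndarray, ddof: int) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b) / (a.size - ddof)


def _decompose(
    x: np.ndarray, y: np.ndarray, theta: np.ndarray, omega: np.ndarray, ddof: int
) -> BiasDecomposition:
    x_star = x - theta
    y_star = y - omega

    comp = {
        "cov_xy": _cov(x, y, ddof),
        "cov_x_omega": _cov(x, omega, ddof),
        "cov_theta_y": _cov(theta, y, ddof),
        "cov_theta_omega": _cov(theta, omega, ddof),
        "var_x": _cov(x, x, ddof),
        "var_theta": _cov(theta, theta, ddof),
        "cov_x_theta": _cov(x, theta, ddof),
        "var_y": _cov(y, y, ddof),
        "var_omega": _cov(omega, omega, ddof),
        "cov_y_omega": _cov(y, omega, ddof),
    }

    var_x_star = _cov(x_star, x_star, ddof)
    var_y_star = _cov(y_star, y_star, ddof)
    if var_x_star <= 0:
        raise ZeroDivisionError("starred predictor x* has zero variance (degenerate regressor)")

    num = (
        comp["cov_xy"]
        - comp["cov_x_omega"]
        - comp["cov_theta_y"]
        + comp["cov_theta_omega"]
    )
    den_x = comp["var_x"] + comp["var_theta"] - 2.0 * comp["cov_x_theta"]
    den_y = comp["var_y"] + comp["var_omega"] - 2.0 * comp["cov_y_omega"]

    slope_direct = _cov(x_star, y_star, ddof) / var_x_star
    slope_reconstructed = num / den_x
    slope_unbiased = comp["cov_xy"] / comp["var_x"] if comp["var_x"] > 0 else np.nan

    if var_y_star <= 0 or comp["var_y"] <= 0 or comp["var_x"] <= 0:
        corr_direct = corr_reconstructed = corr_unbiased = np.nan
    else:
        corr_direct = _cov(x_star, y_star, ddof) / np.sqrt(var_x_star * var_y_star)
        corr_reconstructed = num / np.sqrt(den_x * den_y)
        corr_unbiased = comp["cov_xy"] / np.sqrt(comp["var_x"] * comp["var_y"])

    return BiasDecomposition(
        **comp,
        slope_direct=float(slope_direct),
        slope_reconstructed=float(slope_reconstructed),
        slope_unbiased=float(slope_unbiased),
        corr_direct=float(corr_direct),
        corr_reconstructed=float(corr_reconstructed),
        corr_unbiased=float(corr_unbiased),
        n_species=x.size,
        ddof=ddof,
    )


def slope_decomposition(
    x: Sequence[float],
    y: Sequence[float],
    theta: Sequence[float],
    omega: Sequence[float],
    ddof: int = 1,
) -> BiasDecomposition:
    """Decompose the starred-regression slope into covariance components.

    ``slope_direct`` is cov(x*, y*)/var(x*) with x* = x - theta,
    y* = y - omega; ``slope_reconstructed`` assembles the same quantity from
    the ten components; ``slope_unbiased`` is cov(x, y)/var(x).
    """
    x, y, theta, omega = (np.asarray(v, dtype=float) for v in (x, y, theta, omega))
    if not (x.size == y.size == theta.size == omega.size):
        raise ValueError("x, y, theta, omega must share one length")
    if x.size < 3:
        raise ValueError("need at least 3 species")
    return _decompose(x, y, theta, omega, ddof)


def correlation_decomposition(
    x: Sequence[float],
    y: Sequence[float],
    theta: Sequence[float],
    omega: Sequence[float],
    ddof: int = 1,
) -> BiasDecomposition:
    """Same decomposition, ensuring both starred variances are positive."""
    result = slope_decomposition(x, y, theta, omega, ddof)
    if not np.isfinite(result.corr_direct):
        raise ZeroDivisionError("zero variance in x, y, x* or y*: correlation undefined")
    return result


def compare_aggregation_orders(
    table: TraitMeasurementTable,
    trait_x: str,
    trait_y: str,
    t_x: TransformSpec,
    t_y: TransformSpec,
    reference: str = "transform_first",
) -> BiasDecomposition:
    """Full decomposition between aggregation orders for a pair of traits.

    Species values are computed under both orders from the individual-level
    table: transform-then-aggregate (mean of transformed values) and
    aggregate-then-transform (transform of the raw mean).  ``reference``
    selects which order plays the unbiased role (x, y): the default
    ``"transform_first"`` follows the recommendation that transformed values
    be averaged; ``"aggregate_first"`` flips the labelling.

    Species lacking either trait are excluded (and logged); alignment is by
    species identifier, sorted lexicographically.
    """
    if reference not in ("transform_first", "aggregate_first"):
        raise ValueError(
            f"reference must be 'transform_first' or 'aggregate_first', got {reference!r}"
        )
    sum_x = {s.species_id: s for s in summarize(table, trait_x, t_x)}
    sum_y = {s.species_id: s for s in summarize(table, trait_y, t_y)}
    shared = sorted(set(sum_x) & set(sum_y))
    dropped = (set(sum_x) | set(sum_y)) - set(shared)
    if dropped:
        logger.info(
            "excluding %d species lacking %r or %r: %s",
            len(dropped), trait_x, trait_y, ", ".join(sorted(dropped)[:10]),
        )
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 species with both {trait_x!r} and {trait_y!r}, found {len(shared)}"
        )
    tta_x = np.array([sum_x[s].mean_transformed for s in shared])
    att_x = np.array([sum_x[s].transform_of_mean for s in shared])
    tta_y = np.array([sum_y[s].mean_transformed for s in shared])
    att_y = np.array([sum_y[s].transform_of_mean for s in shared])

    if reference == "transform_first":
        x, x_star, y, y_star = tta_x, att_x, tta_y, att_y
    else:
        x, x_star, y, y_star = att_x, tta_x, att_y, tta_y
    theta, omega = bias_vectors(x, x_star, y, y_star)
    return _decompose(x, y, theta, omega, ddof=1)
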