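"""Minimal ordinary least squares with classical standard errors and R^2.

A deliberately small, self-contained fitting routine so the rest of the
toolkit has no hidden statistical dependencies.  The solve goes through a QR
decomposition (never an explicit inversion of X'X): the demonstration
pipeline produces exact algebraic fits whose residuals sit at machine zero,
a regime where normal equations lose digits.  Perfect fits therefore report
R^2 = 1 and standard errors at floating-point noise — they are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["RegressionFit", "SingularDesignError", "ols_fit"]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient to machine precision."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS result: coefficients and SEs keyed by term name, R^2, residuals."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    r_squared: float
    n_obs: int
    residuals: np.ndarray = field(repr=False)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)


def ols_fit(
    response: Sequence[float] | np.ndarray,
    predictors: Mapping[str, Sequence[float] | np.ndarray],
    include_intercept: bool = True,
) -> RegressionFit:
    """Fit ``response ~ predictors`` by least squares.

    Parameters
    ----------
    response:
        Length-n vector.
    predictors:
        Ordered mapping term name -> length-n vector.
    include_intercept:
        Prepend a constant term named ``"intercept"``.

    Returns classical (homoskedastic) standard errors from the residual
    variance with divisor n - p, and R^2 = 1 - SSE/SST with SST centred
    when an intercept is present.

    Raises
    ------
    SingularDesignError
        If the design is rank-deficient.
    ValueError
        If there are fewer observations than terms or lengths disagree.
    """
    y = np.asarray(response, dtype=float)
    names = list(predictors)
    cols = [np.asarray(predictors[k], dtype=float) for k in names]
    for k, c in zip(names, cols):
        if c.shape != y.shape:
            raise ValueError(f"predictor {k!r} has length {c.size}, response has {y.size}")
    if include_intercept:
        names = ["intercept"] + names
        cols = [np.ones_like(y)] + cols
    X = np.column_stack(cols)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many observations ({n}) as terms ({p})")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = np.max(np.abs(X), axis=0)
    scale[scale == 0.0] = 1.0
    if np.any(diag <= n * np.finfo(float).eps * scale):
        raise SingularDesignError(
            "design matrix is rank-deficient (collinear predictors)"
        )
    beta = np.linalg.solve(R, Q.T @ y)

    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    if include_intercept:
        sst = float(np.sum((y - y.mean()) ** 2))
    else:
        sst = float(y @ y)
    r_squared = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0.0 else np.nan)

    # a saturated design (n == p) interpolates exactly: zero residual variance
    sigma2 = sse / (n - p) if n > p else 0.0
    r_inv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.sum(r_inv**2, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag)

    return RegressionFit(
        coefficients=dict(zip(names, beta.astype(float))),
        standard_errors=dict(zip(names, se.astype(float))),
        r_squared=float(r_squared),
        n_obs=n,
        residuals=resid,
    )
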