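"""Monotone transformations with second derivatives and strict domain checks.

The aggregation-order machinery needs, for every transformation ``f`` applied
to trait values, both the forward map and its second derivative ``f''`` (the
curvature term of the quadratic Jensen correction).  Each transformation is a
:class:`TransformSpec` carrying those two callables together with an open
validity domain.  Domain checks are strict and raise :class:`DomainError`
rather than letting ``log(0)`` & co. seed non-finite values into downstream
covariances.

Built-in registry: ``log``, ``sqrt``, ``asin_sqrt``, ``identity`` and the
parametric ``power`` family.  The "arcsine" transform is implemented as
arcsine-of-square-root (the variance-stabilising form used on proportions),
valid on the open interval (0, 1); plain ``arcsin(x)`` is deliberately not
aliased to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TransformSpec",
    "DomainError",
    "RegistryError",
    "get_transform",
    "register_transform",
    "available_transforms",
    "apply_transform",
    "second_derivative_at",
]


class DomainError(ValueError):
    """A value lies outside a transformation's open validity domain."""


class RegistryError(KeyError):
    """Unknown transformation name."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0]


@dataclass(frozen=True)
class TransformSpec:
    """A named transformation ``f`` with its second derivative ``f''``.

    Parameters
    ----------
    name:
        Short identifier (e.g. ``"log"``, ``"power(2)"``).
    forward:
        Vectorised map ``f(x)``; must be finite everywhere strictly inside
        the domain.
    second_deriv:
        Vectorised map ``f''(x)``.
    domain_lo, domain_hi:
        Open bounds of validity; values at or beyond a bound are rejected.
    is_linear:
        True iff ``f'' == 0`` identically, in which case both aggregation
        orders coincide exactly.
    """

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    second_deriv: Callable[[np.ndarray], np.ndarray]
    domain_lo: float = -math.inf
    domain_hi: float = math.inf
    is_linear: bool = False

    def check_domain(self, values: np.ndarray | float) -> np.ndarray:
        """Validate values, returning them as a float array.

        Raises
        ------
        DomainError
            Naming the first offending index and value.
        """
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        bad = ~np.isfinite(arr) | (arr <= self.domain_lo) | (arr >= self.domain_hi)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DomainError(
                f"value {arr[i]!r} at index {i} is outside the open domain "
                f"({self.domain_lo}, {self.domain_hi}) of transform {self.name!r}"
            )
        return arr

    def __call__(self, values: np.ndarray | float) -> np.ndarray | float:
        arr = self.check_domain(values)
        out = np.asarray(self.forward(arr), dtype=float)
        return float(out[0]) if np.isscalar(values) or np.ndim(values) == 0 else out


def _log_spec() -> TransformSpec:
    return TransformSpec(
        name="log",
        forward=np.log,
        second_deriv=lambda x: -1.0 / np.square(x),
        domain_lo=0.0,
    )


def _sqrt_spec() -> TransformSpec:
    return TransformSpec(
        name="sqrt",
        forward=np.sqrt,
        second_deriv=lambda x: -0.25 * np.power(x, -1.5),
        domain_lo=0.0,
    )


def _asin_sqrt_spec() -> TransformSpec:
    # f(x) = arcsin(sqrt(x));  f''(x) = -(1 - 2x) / (4 (x(1-x))^{3/2})
    return TransformSpec(
        name="asin_sqrt",
        forward=lambda x: np.arcsin(np.sqrt(x)),
        second_deriv=lambda x: -(1.0 - 2.0 * x) / (4.0 * np.power(x * (1.0 - x), 1.5)),
        domain_lo=0.0,
        domain_hi=1.0,
    )


def _identity_spec() -> TransformSpec:
    return TransformSpec(
        name="identity",
        forward=lambda x: np.asarray(x, dtype=float),
        second_deriv=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        is_linear=True,
    )


def _power_spec(p: float) -> TransformSpec:
    p = float(p)
    return TransformSpec(
        name=f"power({p:g})",
        forward=lambda x: np.power(x, p),
        second_deriv=lambda x: p * (p - 1.0) * np.power(x, p - 2.0),
        domain_lo=0.0,
        is_linear=(p == 1.0),
    )


_REGISTRY: dict[str, Callable[..., TransformSpec]] = {
    "log": _log_spec,
    "sqrt": _sqrt_spec,
    "asin_sqrt": _asin_sqrt_spec,
    "identity": _identity_spec,
    "power": _power_spec,
}

_NEEDS_PARAM = {"power"}


def available_transforms() -> list[str]:
    """Names accepted by :func:`get_transform`."""
    return sorted(_REGISTRY)


def get_transform(name: str, params: float | None = None) -> TransformSpec:
    """Look up a transformation by name.

    ``power`` requires ``params`` (the exponent); all other built-ins take
    none.

    Raises
    ------
    RegistryError
        If the name is unknown, listing the available names.
    ValueError
        If a required parameter is missing or an unexpected one is given.
    """
    if name not in _REGISTRY:
        raise RegistryError(
            f"unknown transform {name!r}; available: {', '.join(available_transforms())}"
        )
    factory = _REGISTRY[name]
    if name in _NEEDS_PARAM:
        if params is None:
            raise ValueError(f"transform {name!r} requires a parameter (the exponent)")
        return factory(params)
    if params is not None:
        raise ValueError(f"transform {name!r} takes no parameter")
    return factory()


def register_transform(name: str, factory: Callable[..., TransformSpec], *, needs_param: bool = False) -> None:
    """Register a custom transformation factory at runtime.

    The factory must return a fully specified :class:`TransformSpec`
    (forward and second-derivative callables supplied by the caller; no
    symbolic differentiation is attempted).
    """
    _REGISTRY[name] = factory
    if needs_param:
        _NEEDS_PARAM.add(name)


def apply_transform(t: TransformSpec, values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Elementwise ``f(x)`` with strict domain validation.

    Raises :class:`DomainError` naming the first offending index and value;
    never returns non-finite numbers.
    """
    arr = t.check_domain(np.asarray(values, dtype=float))
    return np.asarray(t.forward(arr), dtype=float)


def second_derivative_at(t: TransformSpec, x: float) -> float:
    """``f''(x)``, with the same strict domain check as the forward map."""
    arr = t.check_domain(x)
    return float(np.asarray(t.second_deriv(arr), dtype=float)[0])
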