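"""Standardisation of environmental covariates and Legendre design matrices.

A reaction-norm model expresses a phenotype as a linear combination of
Legendre polynomials :math:`L_0 \\dots L_M` evaluated at a covariate that has
been affinely mapped onto ``[-1, 1]``.  This module owns that mapping
(:class:`GradientScale`) and the construction of design rows/matrices
(:func:`legendre_row`, :func:`build_design`).

Raw (unnormalised) Legendre polynomials are used throughout: ``P_0 = 1``,
``P_1 = x``, ``P_m(1) = 1``.  Normalised variants only rescale regression
coefficients; every derived variance function in :mod:`reactnorm.genpar` is
invariant as long as the same basis is used consistently, which the package
guarantees by routing all basis evaluations through here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

logger = logging.getLogger(__name__)

__all__ = ["GradientScale", "BasisMatrix", "standardize", "legendre_row", "build_design"]


class InvalidScaleError(ValueError):
    """Raised when a gradient scale is degenerate (max_x <= min_x)."""


class InvalidOrderError(ValueError):
    """Raised for a negative polynomial order."""


@dataclass(frozen=True)
class GradientScale:
    """Affine map from a raw environmental covariate onto ``[-1, 1]``.

    ``min_x`` maps to -1 and ``max_x`` to +1 exactly.  The scale is computed
    once from the training data of a fit and stored with the fit, so that
    predictions and derived parameter curves always use the same mapping.
    """

    min_x: float
    max_x: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_x) or not np.isfinite(self.max_x):
            raise InvalidScaleError("gradient scale endpoints must be finite")
        if self.max_x <= self.min_x:
            raise InvalidScaleError(
                f"degenerate gradient scale: max_x={self.max_x} <= min_x={self.min_x}"
            )

    @classmethod
    def from_data(cls, xs) -> "GradientScale":
        xs = np.asarray(xs, dtype=float)
        return cls(float(np.min(xs)), float(np.max(xs)))

    def to_dict(self) -> dict:
        return {"min_x": self.min_x, "max_x": self.max_x}

    @classmethod
    def from_dict(cls, d: dict) -> "GradientScale":
        return cls(float(d["min_x"]), float(d["max_x"]))


@dataclass(frozen=True)
class BasisMatrix:
    """Legendre design matrix: row i is ``[L_0(x'_i), ..., L_M(x'_i)]``."""

    order: int
    rows: np.ndarray  # shape (n, order + 1)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != self.order + 1:
            raise ValueError(
                f"rows must have {self.order + 1} columns, got shape {rows.shape}"
            )
        object.__setattr__(self, "rows", rows)


def standardize(x, scale: GradientScale):
    """Map raw covariate values onto the standardized gradient.

    ``x' = 2 (x - min) / (max - min) - 1``.  Values outside the training
    range are returned (extrapolation is permitted) but logged as a warning,
    since reaction norms are only inferred over the tested range.
    """
    x = np.asarray(x, dtype=float)
    out = 2.0 * (x - scale.min_x) / (scale.max_x - scale.min_x) - 1.0
    if np.any(np.abs(out) > 1.0 + 1e-12):
        logger.warning(
            "covariate value(s) outside the gradient scale [%g, %g]: extrapolating",
            scale.min_x,
            scale.max_x,
        )
    if out.ndim == 0:
        return float(out)
    return out


def legendre_row(x_std, order: int) -> np.ndarray:
    """Evaluate ``[P_0(x'), ..., P_M(x')]`` at standardized value(s) ``x_std``.

    Uses the Bonnet three-term recurrence via numpy's Legendre module.
    Returns shape ``(order + 1,)`` for a scalar input, ``(n, order + 1)``
    for a vector input.
    """
    if order < 0:
        raise InvalidOrderError(f"polynomial order must be >= 0, got {order}")
    x_std = np.asarray(x_std, dtype=float)
    v = npleg.legvander(np.atleast_1d(x_std), order)
    if x_std.ndim == 0:
        return v[0]
    return v


def build_design(xs, scale: GradientScale, order: int) -> BasisMatrix:
    """Standardize raw covariates and stack their Legendre rows."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    if xs.size == 0:
        raise ValueError("empty covariate sequence")
    x_std = standardize(xs, scale)
    return BasisMatrix(order=order, rows=legendre_row(np.atleast_1d(x_std), order))
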