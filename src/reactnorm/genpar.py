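"""Environment-dependent genetic parameters from fitted coefficient covariances.

A random-regression fit summarises each random term by the covariance
matrix of its basis coefficients.  Because an additive value at gradient
point x is the linear combination ``sum_m a_m L_m(x')``, the additive
variance there is the quadratic form

    sigma2_A(x) = L(x') V_A L(x')^t,      L(x') = [L_0(x') ... L_M(x')]

and the cross-trait additive covariance is the bilinear form in the
cross-trait coefficient block C_A.  From these follow narrow-sense
heritability, its hybrid analogues (share of hybrid phenotypic variance due
to the additive inheritance from one parental side) and the additive
correlation between traits, all as functions of the gradient:

    h2_T(x)    = sigma2_A(x) / (sigma2_A(x) + sigma2_P(x) + sigma2_R)
    h2_HE(x)   = sigma2_HE(x) / (0.5 sigma2_HE(x) + 0.5 sigma2_HJ(x)
                                 + sigma2_P(x) + sigma2_R)
    r_A(x)     = c_A(x) / sqrt(sigma2_T1(x) sigma2_T2(x))

Permanent-environment variance and covariance functions are computed the
same way from Sigma_P.  Posterior summaries apply the functions to every
retained draw and report pointwise MAP and credible bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import GradientScale, legendre_row, standardize
from .model import FitResult, credible_interval, map_estimate

__all__ = [
    "trait_block",
    "variance_function",
    "covariance_function",
    "heritability",
    "heritability_hybrid",
    "additive_correlation",
    "covariance_function_set",
]

_CLIP = 1e-8  # tolerated floating-point excursion of |r| beyond 1


def trait_block(Sigma: np.ndarray, order: int, t1: int, t2: int) -> np.ndarray:
    """Extract the (M+1)x(M+1) coefficient block for a trait pair.

    With trait-major coefficient stacking, block (t1, t2) holds the
    covariances between trait t1's and trait t2's basis coefficients.
    """
    b = order + 1
    return Sigma[t1 * b : (t1 + 1) * b, t2 * b : (t2 + 1) * b]


def _basis_rows(x_grid, scale: GradientScale, order: int) -> np.ndarray:
    xg = np.atleast_1d(np.asarray(x_grid, dtype=float))
    return legendre_row(np.atleast_1d(standardize(xg, scale)), order)


def variance_function(V: np.ndarray, x_grid, scale: GradientScale) -> np.ndarray:
    """sigma2(x) = L(x') V L(x')^t at each grid point."""
    V = np.asarray(V, dtype=float)
    order = V.shape[0] - 1
    if V.shape[0] != V.shape[1]:
        raise ValueError(f"coefficient covariance block must be square, got {V.shape}")
    Lg = _basis_rows(x_grid, scale, order)
    return np.einsum("gi,ij,gj->g", Lg, V, Lg)


def covariance_function(C: np.ndarray, x_grid, scale: GradientScale) -> np.ndarray:
    """c(x) = L(x') C L(x')^t; C need not be symmetric."""
    C = np.asarray(C, dtype=float)
    if C.shape[0] != C.shape[1]:
        raise ValueError(f"cross-trait block must be square, got {C.shape}")
    order = C.shape[0] - 1
    Lg = _basis_rows(x_grid, scale, order)
    return np.einsum("gi,ij,gj->g", Lg, C, Lg)


def heritability(sigma2_A, sigma2_P, sigma2_R) -> np.ndarray:
    """Narrow-sense heritability h2(x), pure-species form."""
    sigma2_A = np.asarray(sigma2_A, dtype=float)
    denom = sigma2_A + np.asarray(sigma2_P, dtype=float) + sigma2_R
    if np.any(denom <= 0):
        raise ZeroDivisionError("phenotypic variance is zero at some grid point")
    return sigma2_A / denom


def heritability_hybrid(sigma2_HE, sigma2_HJ, sigma2_P, sigma2_R, side: str = "E"):
    """Heritability in hybridization for one parental side.

    h2_HE(x) = sigma2_HE(x) / (0.5 sigma2_HE + 0.5 sigma2_HJ + sigma2_P + sigma2_R);
    the numerator carries the full per-side variance, the halves in the
    denominator reflect that each side transmits half its variance to the
    hybrid phenotype.
    """
    sigma2_HE = np.asarray(sigma2_HE, dtype=float)
    sigma2_HJ = np.asarray(sigma2_HJ, dtype=float)
    denom = 0.5 * sigma2_HE + 0.5 * sigma2_HJ + np.asarray(sigma2_P, float) + sigma2_R
    if np.any(denom <= 0):
        raise ZeroDivisionError("hybrid phenotypic variance is zero at some grid point")
    num = sigma2_HE if side == "E" else sigma2_HJ
    return num / denom


def additive_correlation(c, sigma2_T1, sigma2_T2) -> np.ndarray:
    """r(x) = c(x) / sqrt(sigma2_T1(x) sigma2_T2(x)).

    Grid points with a zero variance yield NaN (undefined there) rather
    than an error; values beyond +-1 by less than 1e-8 are clipped.
    """
    c = np.asarray(c, dtype=float)
    prod = np.asarray(sigma2_T1, float) * np.asarray(sigma2_T2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(prod > 0, c / np.sqrt(prod), np.nan)
    small = (np.abs(r) > 1) & (np.abs(r) <= 1 + _CLIP)
    r = np.where(small, np.sign(r), r)
    return r


# ---------------------------------------------------------------------------
# posterior pipeline


def _summaries(curves: np.ndarray, mode: str):
    """Pointwise MAP and 95% band across draws; curves is (n_draws, n_grid)."""
    if mode == "map":
        point = np.array([map_estimate(curves[:, g]) for g in range(curves.shape[1])])
    else:
        point = np.nanmean(curves, axis=0)
    lo, hi = zip(*(credible_interval(curves[:, g]) for g in range(curves.shape[1])))
    return point, np.array(lo), np.array(hi)


def covariance_function_set(
    fit: FitResult,
    n_grid: int = 101,
    x_grid=None,
    point: str = "map",
) -> pd.DataFrame:
    """Derived parameter curves with pointwise credible bands.

    For every retained draw the variance, covariance, heritability and
    correlation functions are evaluated on the grid; pointwise MAP (or
    posterior mean, ``point="mean"``) and 95% bands are then taken across
    draws.  The grid spans the covariate range observed by the fit.

    Returns a long table: x, parameter, side, trait, value, ci_low, ci_high.
    """
    spec = fit.spec
    scale = fit.scale
    if x_grid is None:
        x_grid = np.linspace(scale.min_x, scale.max_x, n_grid)
    x_grid = np.asarray(x_grid, dtype=float)
    order = spec.order
    T = spec.n_traits
    D = fit.n_draws
    G = x_grid.size

    hybrid = spec.taxon_mode == "hybrid"
    blocks = (
        {"HE": fit.draws["Sigma_HE"], "HJ": fit.draws["Sigma_HJ"]}
        if hybrid
        else {"A": fit.draws["Sigma_A"]}
    )
    has_pe = spec.include_permanent

    curves: dict = {}
    for side, Sig in blocks.items():
        for t in range(T):
            vname = f"sigma2_{side}:{spec.traits[t]}"
            curves[vname] = np.empty((D, G))
        if T == 2:
            curves[f"c_{side}"] = np.empty((D, G))
            curves[f"r_{side}"] = np.empty((D, G))
    for t in range(T):
        for side in blocks:
            curves[f"h2_{side}:{spec.traits[t]}"] = np.empty((D, G))
    if has_pe:
        for t in range(T):
            curves[f"sigma2_P:{spec.traits[t]}"] = np.empty((D, G))
        if T == 2:
            curves["c_P"] = np.empty((D, G))

    for dd in range(D):
        sigP = np.zeros((T, G))
        if has_pe:
            SP = fit.draws["Sigma_P"][dd]
            for t in range(T):
                sigP[t] = variance_function(trait_block(SP, order, t, t), x_grid, scale)
                curves[f"sigma2_P:{spec.traits[t]}"][dd] = sigP[t]
            if T == 2:
                curves["c_P"][dd] = covariance_function(
                    trait_block(SP, order, 0, 1), x_grid, scale
                )
        sig = {}
        for side, Sig in blocks.items():
            S = Sig[dd]
            for t in range(T):
                v = variance_function(trait_block(S, order, t, t), x_grid, scale)
                sig[(side, t)] = v
                curves[f"sigma2_{side}:{spec.traits[t]}"][dd] = v
            if T == 2:
                c = covariance_function(trait_block(S, order, 0, 1), x_grid, scale)
                curves[f"c_{side}"][dd] = c
                curves[f"r_{side}"][dd] = additive_correlation(
                    c, sig[(side, 0)], sig[(side, 1)]
                )
        s2R = fit.draws["sigma2"][dd]
        for t in range(T):
            if hybrid:
                for side in ("HE", "HJ"):
                    curves[f"h2_{side}:{spec.traits[t]}"][dd] = heritability_hybrid(
                        sig[("HE", t)],
                        sig[("HJ", t)],
                        sigP[t],
                        s2R[t],
                        side="E" if side == "HE" else "J",
                    )
            else:
                curves[f"h2_A:{spec.traits[t]}"][dd] = heritability(
                    sig[("A", t)], sigP[t], s2R[t]
                )

    rows = []
    for name, arr in curves.items():
        pt, lo, hi = _summaries(arr, point)
        param, _, trait = name.partition(":")
        base, _, side = param.partition("_")
        for g in range(G):
            rows.append(
                {
                    "x": x_grid[g],
                    "parameter": base,
                    "side": side,
                    "trait": trait,
                    "value": pt[g],
                    "ci_low": lo[g],
                    "ci_high": hi[g],
                }
            )
    return pd.DataFrame(rows)
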