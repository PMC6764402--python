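"""Equilibrium binding: from concentrations to the doped fraction phi.

The doped fraction used by the simulations is the equilibrium fraction
of alpha-synuclein monomers carrying a bound FKBP12.  For the
two-species system S + F <-> SF with dissociation constant Kd the
complex concentration follows the standard quadratic mass balance

    C = ((S + F + Kd) - sqrt((S + F + Kd)^2 - 4 S F)) / 2,   phi = C / S.

A competitive inhibitor I (ElteN378 occupying the FKBP12 pocket)
sequesters free FKBP12; the three-species equilibrium is solved by
bracketed bisection on free F, which reduces the effective FKBP12
concentration in a strictly dose-dependent way.

All concentrations are in micromolar.  The default kd_s = 1.2 uM sits
in the micromolar range and is exposed as a parameter, not a claim
about the real complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cg_model import doped_count

DEFAULT_KD_S = 1.2  # uM, FKBP12 / alpha-syn
DEFAULT_KD_I = 0.01  # uM, FKBP12 / tight inhibitor (FK506-like affinity)

_MASS_BALANCE_TOL = 1.0e-12  # uM
_MAX_ITER = 200


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations (uM) and dissociation constants (uM)."""

    s_total: float
    f_total: float
    i_total: float = 0.0
    kd_s: float = DEFAULT_KD_S
    kd_i: float = DEFAULT_KD_I

    def __post_init__(self) -> None:
        if min(self.s_total, self.f_total, self.i_total) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.kd_s <= 0:
            raise ValueError("kd_s must be positive")
        if self.i_total > 0 and self.kd_i <= 0:
            raise ValueError("kd_i must be positive when inhibitor is present")


@dataclass(frozen=True)
class BindingResult:
    """Bound fraction phi with solver diagnostics."""

    phi: float
    free_f: float
    free_s: float
    complex_sf: float
    complex_if: float = 0.0
    iterations: int = 0
    residual: float = 0.0


def nm(value: float) -> float:
    """Convert a nanomolar concentration to the micromolar unit used here."""
    return value * 1.0e-3


def bound_fraction(
    s_total: float, f_total: float, kd_s: float = DEFAULT_KD_S
) -> BindingResult:
    """Two-species bound fraction from the closed-form quadratic."""
    if s_total <= 0:
        raise ValueError("phi is undefined without alpha-synuclein (s_total = 0)")
    if kd_s <= 0:
        raise ValueError("kd_s must be positive")
    if f_total < 0:
        raise ValueError("f_total must be non-negative")
    b = s_total + f_total + kd_s
    disc = b * b - 4.0 * s_total * f_total
    c = 0.5 * (b - math.sqrt(max(disc, 0.0)))
    c = min(c, s_total, f_total)
    free_s = s_total - c
    free_f = f_total - c
    residual = abs(free_s * free_f - kd_s * c)
    return BindingResult(
        phi=c / s_total,
        free_f=free_f,
        free_s=free_s,
        complex_sf=c,
        iterations=0,
        residual=residual,
    )


def bound_fraction_bisection(
    s_total: float, f_total: float, kd_s: float = DEFAULT_KD_S,
    tol: float = _MASS_BALANCE_TOL,
) -> BindingResult:
    """Two-species bound fraction by bisection on the complex concentration.

    Independent of the closed form; used to cross-check it.
    """
    if s_total <= 0:
        raise ValueError("phi is undefined without alpha-synuclein (s_total = 0)")
    lo, hi = 0.0, min(s_total, f_total)

    def g(c: float) -> float:
        return (s_total - c) * (f_total - c) - kd_s * c

    it = 0
    while hi - lo > tol and it < _MAX_ITER:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        it += 1
    c = 0.5 * (lo + hi)
    return BindingResult(
        phi=c / s_total,
        free_f=f_total - c,
        free_s=s_total - c,
        complex_sf=c,
        iterations=it,
        residual=abs(g(c)),
    )


def competitive_bound_fraction(bs: BindingSystem) -> BindingResult:
    """Three-species competitive equilibrium, bisection on free FKBP12.

    Free F solves  F + S_tot F/(kd_s + F) + I_tot F/(kd_i + F) = F_tot,
    monotone in F, so [0, F_tot] brackets the root.  phi = F/(kd_s + F)
    is the fraction of alpha-syn bearing FKBP12.
    """
    if bs.s_total <= 0:
        raise ValueError("phi is undefined without alpha-synuclein (s_total = 0)")
    if bs.f_total == 0.0:
        return BindingResult(
            phi=0.0, free_f=0.0, free_s=bs.s_total, complex_sf=0.0,
        )

    def balance(f: float) -> float:
        tot = f + bs.s_total * f / (bs.kd_s + f)
        if bs.i_total > 0:
            tot += bs.i_total * f / (bs.kd_i + f)
        return tot - bs.f_total

    # bisect to machine precision: the balance slope can reach
    # s_total/kd_s, so a loose bracket would leave a visible residual
    lo, hi = 0.0, bs.f_total
    it = 0
    while hi - lo > 1.0e-16 * max(1.0, hi) and it < _MAX_ITER:
        mid = 0.5 * (lo + hi)
        if balance(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        it += 1
    f = 0.5 * (lo + hi)
    residual = abs(balance(f))
    if residual > 1.0e-8:
        raise RuntimeError(
            f"competitive equilibrium did not converge: residual {residual:.3e} uM"
        )
    c_sf = bs.s_total * f / (bs.kd_s + f)
    c_if = bs.i_total * f / (bs.kd_i + f) if bs.i_total > 0 else 0.0
    return BindingResult(
        phi=f / (bs.kd_s + f),
        free_f=f,
        free_s=bs.s_total - c_sf,
        complex_sf=c_sf,
        complex_if=c_if,
        iterations=it,
        residual=residual,
    )


def dose_response(
    bs: BindingSystem, i_grid: np.ndarray | list[float]
) -> list[tuple[float, float]]:
    """phi along an increasing inhibitor-concentration grid."""
    grid = np.asarray(i_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("inhibitor grid must be strictly increasing")
    out = []
    for i_tot in grid:
        r = competitive_bound_fraction(
            BindingSystem(bs.s_total, bs.f_total, float(i_tot), bs.kd_s, bs.kd_i)
        )
        out.append((float(i_tot), r.phi))
    return out


def phi_to_doping(phi: float, n_monomers: int) -> int:
    """Doped-monomer count for a simulation of ``n_monomers`` chains."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return doped_count(phi, n_monomers)
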