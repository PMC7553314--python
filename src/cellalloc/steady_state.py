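"""Balanced-growth solutions of the allocation model.

Under balanced growth all concentrations are constant and the volume grows
exponentially at rate ``α = k·e``.  Combining the steady-state equations
with the regulation ``f_R = δ·a`` yields a single master equation in
``f_R``.  Two variants are provided:

``solve_regulated``
    The small-precursor (``a ≪ 1``) master equation

    ``σ·f_R²/(f_R + K) = k·f_E·(1 + kon/(koff + k·f_E))``

    with ``f_E = 1 − f_R − f_Q − f_U − f_X``.  This is the closed-form
    workhorse behind the growth-law and size-law predictions.

``solve_regulated_exact``
    The finite-δ steady state without the ``a ≪ 1`` approximation,

    ``σ·f_R²/(f_R + K) = k·f_E·(1−a)·(k·f_E·(1−a) + kon + koff)/(k·f_E·(1−a) + koff)``

    with ``a = f_R/δ``.  This is the exact fixed point of the dynamic
    model and the oracle for the lineage simulators.

``solve_optimal`` replaces the regulation by growth-rate maximization over
``f_R``, the benchmark showing that supply-driven regulation is
near-optimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model_core import AllocationFractions, GrowthModulation, ModelParameters

__all__ = [
    "SteadyStateSolution",
    "InfeasibleCondition",
    "solve_regulated",
    "solve_regulated_exact",
    "solve_optimal",
    "exact_precursor_for_fractions",
    "rna_protein_conversion",
    "elongation_curve",
]

_EPS = 1e-9
_XTOL = 1e-14


class InfeasibleCondition(ValueError):
    """Raised when a growth condition admits no balanced-growth state."""


@dataclass(frozen=True)
class SteadyStateSolution:
    """A balanced-growth state.

    Concentrations are mass fractions: ``e = f_E(1−a)`` etc., they sum with
    ``a`` to one.  ``alpha = k·e`` is the exponential growth rate,
    ``ribo_efficiency = σ·f_R/(f_R+K)`` the per-ribosome synthesis rate and
    ``active_fraction = r_a/r`` the share of ribosomes not bound by
    chloramphenicol.
    """

    fractions: AllocationFractions
    a: float
    alpha: float
    active_fraction: float
    mod: GrowthModulation
    params: ModelParameters

    @property
    def f_R(self) -> float:
        return self.fractions.f_R

    @property
    def f_E(self) -> float:
        return self.fractions.f_E

    @property
    def e(self) -> float:
        return self.fractions.f_E * (1.0 - self.a)

    @property
    def r(self) -> float:
        return self.fractions.f_R * (1.0 - self.a)

    @property
    def r_a(self) -> float:
        return self.active_fraction * self.r

    @property
    def r_i(self) -> float:
        return self.r - self.r_a

    @property
    def q(self) -> float:
        return self.fractions.f_Q * (1.0 - self.a)

    @property
    def x(self) -> float:
        return self.fractions.f_X * (1.0 - self.a)

    @property
    def u(self) -> float:
        return self.fractions.f_U * (1.0 - self.a)

    @property
    def ribo_efficiency(self) -> float:
        p = self.params
        return p.sigma * self.f_R / (self.f_R + p.K)

    def concentrations(self) -> dict[str, float]:
        return {
            "a": self.a,
            "e": self.e,
            "r_a": self.r_a,
            "r_i": self.r_i,
            "q": self.q,
            "x": self.x,
            "u": self.u,
        }


def _capacity(params: ModelParameters, mod: GrowthModulation, f_X: float) -> float:
    cap = 1.0 - params.f_Q - mod.f_U - f_X
    if cap <= 0.0:
        raise InfeasibleCondition(
            "f_Q + f_U + f_X >= 1 leaves no capacity for E and R sectors"
        )
    return cap


def _find_root(residual, cap: float) -> float:
    lo, hi = _EPS, cap - _EPS
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise InfeasibleCondition(
            "no balanced-growth root for f_R in (0, 1 - f_Q - f_U - f_X)"
        )
    return brentq(residual, lo, hi, xtol=_XTOL, rtol=8.9e-16)


def _package(
    f_R: float,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float,
    f_Q_eff: float,
    a: float,
    active: float,
) -> SteadyStateSolution:
    cap = 1.0 - f_Q_eff - mod.f_U - f_X
    fractions = AllocationFractions(
        f_E=cap - f_R, f_R=f_R, f_Q=f_Q_eff, f_X=f_X, f_U=mod.f_U
    )
    alpha = mod.k * fractions.f_E * (1.0 - a)
    return SteadyStateSolution(
        fractions=fractions,
        a=a,
        alpha=alpha,
        active_fraction=active,
        mod=mod,
        params=params,
    )


def solve_regulated(
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> SteadyStateSolution:
    """Balanced growth of the regulated model, small-precursor master equation.

    The two sides of the master equation are strictly monotone in opposite
    directions, so the root in ``(0, 1−f_Q−f_U−f_X)`` is unique.  The
    reported precursor concentration is the regulation readback
    ``a = f_R/δ``; the active ribosome fraction is
    ``(koff + k·f_E)/(koff + k·f_E + kon)``.
    """
    f_Q_eff = params.f_Q if f_Q is None else f_Q
    cap = 1.0 - f_Q_eff - mod.f_U - f_X
    if cap <= 0.0:
        raise InfeasibleCondition("f_Q + f_U + f_X >= 1")
    sigma, K = params.sigma, params.K
    k, kon, koff = mod.k, mod.kon_cm, params.koff_cm

    def residual(f_R: float) -> float:
        f_E = cap - f_R
        lhs = sigma * f_R * f_R / (f_R + K)
        rhs = k * f_E * (1.0 + kon / (koff + k * f_E))
        return lhs - rhs

    f_R = _find_root(residual, cap)
    f_E = cap - f_R
    active = (koff + k * f_E) / (koff + k * f_E + kon)
    a = f_R / params.delta
    return _package(f_R, params, mod, f_X, f_Q_eff, a, active)


def solve_regulated_exact(
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> SteadyStateSolution:
    """Balanced growth of the regulated model without the ``a ≪ 1`` approximation.

    This is the exact fixed point of the concentration ODEs at finite δ and
    the reference for trajectory-based simulators.
    """
    f_Q_eff = params.f_Q if f_Q is None else f_Q
    cap = 1.0 - f_Q_eff - mod.f_U - f_X
    if cap <= 0.0:
        raise InfeasibleCondition("f_Q + f_U + f_X >= 1")
    sigma, K, delta = params.sigma, params.K, params.delta
    k, kon, koff = mod.k, mod.kon_cm, params.koff_cm

    def residual(f_R: float) -> float:
        f_E = cap - f_R
        a = f_R / delta
        flux = k * f_E * (1.0 - a)  # = alpha = k*e
        lhs = sigma * f_R * f_R / (f_R + K)
        rhs = flux * (flux + kon + koff) / (flux + koff)
        return lhs - rhs

    f_R = _find_root(residual, cap)
    f_E = cap - f_R
    a = f_R / delta
    alpha = k * f_E * (1.0 - a)
    active = (koff + alpha) / (koff + alpha + kon)
    return _package(f_R, params, mod, f_X, f_Q_eff, a, active)


def exact_precursor_for_fractions(
    f_R: float,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> float:
    """Exact steady-state precursor concentration for *fixed* fractions.

    Solves ``f_R·σ·a/(a+a_sat) = k·f_E·(1−a)·(k·f_E·(1−a)+kon+koff)/(k·f_E·(1−a)+koff)``
    for ``a`` in (0, 1).  The left side increases and the right side
    decreases in ``a``, so the root is unique.
    """
    f_Q_eff = params.f_Q if f_Q is None else f_Q
    cap = 1.0 - f_Q_eff - mod.f_U - f_X
    if not 0.0 < f_R < cap:
        raise ValueError("f_R must lie in (0, 1 - f_Q - f_U - f_X)")
    f_E = cap - f_R
    sigma, a_sat = params.sigma, params.a_sat
    k, kon, koff = mod.k, mod.kon_cm, params.koff_cm

    def residual(a: float) -> float:
        flux = k * f_E * (1.0 - a)
        lhs = f_R * sigma * a / (a + a_sat)
        rhs = flux * (flux + kon + koff) / (flux + koff)
        return lhs - rhs

    return brentq(residual, 1e-15, 1.0 - 1e-15, xtol=_XTOL, rtol=8.9e-16)


def solve_optimal(
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> SteadyStateSolution:
    """Allocation that maximizes growth rate instead of following ``f_R = δ·a``.

    Bounded scalar maximization of ``α(f_R) = k·f_E·(1 − a(f_R))`` where
    ``a(f_R)`` is the exact steady-state precursor level for fixed
    fractions.  The regulated solution can never beat this optimum.
    """
    f_Q_eff = params.f_Q if f_Q is None else f_Q
    cap = 1.0 - f_Q_eff - mod.f_U - f_X
    if cap <= 0.0:
        raise InfeasibleCondition("f_Q + f_U + f_X >= 1")

    def neg_alpha(f_R: float) -> float:
        a = exact_precursor_for_fractions(f_R, params, mod, f_X=f_X, f_Q=f_Q_eff)
        return -mod.k * (cap - f_R) * (1.0 - a)

    res = minimize_scalar(
        neg_alpha,
        bounds=(_EPS, cap - _EPS),
        method="bounded",
        options={"xatol": 1e-10},
    )
    f_R = float(res.x)
    f_E = cap - f_R
    a = exact_precursor_for_fractions(f_R, params, mod, f_X=f_X, f_Q=f_Q_eff)
    alpha = mod.k * f_E * (1.0 - a)
    active = (params.koff_cm + alpha) / (params.koff_cm + alpha + mod.kon_cm)
    return _package(f_R, params, mod, f_X, f_Q_eff, a, active)


def rna_protein_conversion(value: float, direction: str = "ratio_to_fraction") -> float:
    """Convert between RNA/protein ratio and extended-ribosome proteome fraction.

    The proteome fraction of (extended) ribosomes is 0.76 times the measured
    RNA/protein ratio.
    """
    if value < 0:
        raise ValueError("input must be non-negative")
    if direction == "ratio_to_fraction":
        return 0.76 * value
    if direction == "fraction_to_ratio":
        return value / 0.76
    raise ValueError("direction must be 'ratio_to_fraction' or 'fraction_to_ratio'")


def elongation_curve(
    params: ModelParameters,
    conditions: list[GrowthModulation],
    exact: bool = False,
):
    """Per-condition (f_R, ribosome efficiency, active fraction, growth rate).

    Because ``f_R = δ·a``, the per-ribosome synthesis rate is
    ``σ·f_R/(f_R + K)`` in every condition: nutrient and chloramphenicol
    modulations collapse onto a single Michaelis–Menten curve in ``f_R``.

    Returns a pandas DataFrame with one row per condition.
    """
    import pandas as pd

    solver = solve_regulated_exact if exact else solve_regulated
    rows = []
    for mod in conditions:
        ss = solver(params, mod)
        rows.append(
            {
                "label": mod.label,
                "k": mod.k,
                "kon_cm": mod.kon_cm,
                "f_U": mod.f_U,
                "f_R": ss.f_R,
                "f_E": ss.f_E,
                "a": ss.a,
                "alpha": ss.alpha,
                "ribo_efficiency": ss.ribo_efficiency,
                "active_fraction": ss.active_fraction,
                "rna_protein_ratio": rna_protein_conversion(
                    ss.f_R, "fraction_to_ratio"
                ),
            }
        )
    return pd.DataFrame(rows)
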