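"""Coarse-grained reaction network of bacterial cell physiology.

The cell is described by a pool of protein precursors ``A`` and five protein
sectors: metabolic enzymes ``E`` (import nutrients and convert them into
precursors), ribosomes ``R`` (active ``R_a`` and chloramphenicol-inactivated
``R_i``), housekeeping proteins ``Q``, division proteins ``X`` and, when
protein over-expression burden is modelled, useless proteins ``U``.  Mass
density homeostasis makes cell volume equal to total mass,
``V = A + E + R_a + R_i + Q + X + U``, so mass fractions and concentrations
are interchangeable.

Reactions (rates in absolute amounts per hour):

- nutrient import          ``∅ → A``            at ``k·E``
- synthesis of sector S    ``A → S``            at ``f_S·σ·R_a·a/(a + a_sat)``
- ribosome inactivation    ``R_a → R_i``        at ``kon_cm·R_a``
- ribosome re-activation   ``R_i → R_a``        at ``koff_cm·R_i``
- optional X turnover      ``X → ∅``            at ``gamma_X·X``

with ``a = A/V`` the precursor concentration.  Synthesis conserves mass, so
``dV/dt = k·E`` exactly when ``gamma_X = 0``.

Allocation fractions are set dynamically: ``f_Q`` and ``f_U`` are imposed,
``f_R = δ·a`` (supply-driven activation, clamped to the available capacity)
and ``f_E`` takes the remainder.  The division allocation ``f_X`` is supplied
by the caller (zero for pure growth physiology; a function of composition
when the structural division model is attached).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "GrowthModulation",
    "CellState",
    "AllocationFractions",
    "SPECIES",
    "allocation_fractions",
    "reaction_rates",
    "ode_rhs",
    "concentration_rhs",
]

#: Order of the seven state variables used throughout the package.
SPECIES = ("A", "E", "R_a", "R_i", "Q", "X", "U")


@dataclass(frozen=True)
class ModelParameters:
    """Condition-independent model constants.

    Parameters
    ----------
    sigma : float
        Maximal protein synthesis rate per extended ribosome (1/hr).
    K : float
        Ribosome regulation constant, ``K = delta * a_sat`` (dimensionless).
    delta : float
        Gain of the supply-driven regulation ``f_R = delta * a``.
    f_Q : float
        Housekeeping allocation fraction, in (0, 1).  When a dynamic
        division allocation is attached the effective housekeeping fraction
        is reduced so that ``f_Q + f_X`` stays at this value.
    koff_cm : float
        Chloramphenicol–ribosome unbinding rate (1/hr).
    X_div : float
        Division threshold: absolute amount of X triggering division.
    f_X_scale : float
        Prefactor of the division-protein regulation
        ``f_X = f_X_scale * e**beta_e * (r_a/r)**beta_ar``.
    beta_e, beta_ar : float
        Exponents of the division-protein regulation.
    gamma_X : float
        First-order X degradation rate (1/hr); 0 in the baseline model.
    S0 : float
        Replication-initiation unit size in μm³ (used only for C+D).
    size_scale : float
        μm³ per model mass unit (reporting only).
    """

    sigma: float = 6.46
    K: float = 0.0836
    delta: float = 5.0
    f_Q: float = 0.5
    koff_cm: float = 5.04
    X_div: float = 60.0
    f_X_scale: float = 0.09
    beta_e: float = 1.0
    beta_ar: float = -2.0 / 3.0
    gamma_X: float = 0.0
    S0: float = 0.28
    size_scale: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not 0.0 < self.f_Q < 1.0:
            raise ValueError("f_Q must be in (0, 1)")
        if self.koff_cm < 0:
            raise ValueError("koff_cm must be >= 0")
        if self.X_div <= 0:
            raise ValueError("X_div must be > 0")
        if self.f_X_scale <= 0:
            raise ValueError("f_X_scale must be > 0")
        if self.gamma_X < 0:
            raise ValueError("gamma_X must be >= 0")

    @property
    def a_sat(self) -> float:
        """Precursor half-saturation constant of ribosomes, ``K / delta``."""
        return self.K / self.delta

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GrowthModulation:
    """One growth condition.

    ``k`` is the medium nutrient quality (1/hr), ``kon_cm`` the
    chloramphenicol-imposed ribosome inactivation rate (1/hr) and ``f_U``
    the imposed useless-protein allocation fraction.
    """

    k: float
    kon_cm: float = 0.0
    f_U: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("nutrient quality k must be > 0")
        if self.kon_cm < 0:
            raise ValueError("kon_cm must be >= 0")
        if not 0.0 <= self.f_U < 1.0:
            raise ValueError("f_U must be in [0, 1)")


@dataclass
class CellState:
    """Absolute amounts of the seven coarse-grained components (mass units)."""

    A: float
    E: float
    R_a: float
    R_i: float
    Q: float
    X: float
    U: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.amounts()):
            raise ValueError("all amounts must be non-negative")
        if self.volume <= 0:
            raise ValueError("degenerate state: V must be > 0")

    def amounts(self) -> np.ndarray:
        return np.array(
            [self.A, self.E, self.R_a, self.R_i, self.Q, self.X, self.U],
            dtype=float,
        )

    @classmethod
    def from_amounts(cls, y, t: float = 0.0) -> "CellState":
        return cls(*(float(v) for v in y), t=t)

    @property
    def volume(self) -> float:
        return self.A + self.E + self.R_a + self.R_i + self.Q + self.X + self.U

    @property
    def R(self) -> float:
        return self.R_a + self.R_i

    @property
    def a(self) -> float:
        return self.A / self.volume


@dataclass(frozen=True)
class AllocationFractions:
    """Protein-synthesis allocation fractions; they sum to one."""

    f_E: float
    f_R: float
    f_Q: float
    f_X: float
    f_U: float

    def __post_init__(self) -> None:
        vals = (self.f_E, self.f_R, self.f_Q, self.f_X, self.f_U)
        if any(v < -1e-15 for v in vals):
            raise ValueError("allocation fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError("allocation fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_E, self.f_R, self.f_Q, self.f_X, self.f_U], dtype=float
        )


def allocation_fractions(
    a: float,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> AllocationFractions:
    """Allocation fractions at precursor concentration ``a``.

    ``f_R = delta*a`` clamped to the capacity left after the imposed
    fractions; ``f_E`` is the remainder.  ``f_Q`` defaults to
    ``params.f_Q`` but can be overridden (the dynamic division model
    reduces it so that ``f_Q + f_X`` is constant).
    """
    if not 0.0 <= a < 1.0:
        raise ValueError("precursor concentration a must be in [0, 1)")
    if f_X < 0:
        raise ValueError("f_X must be >= 0")
    fQ = params.f_Q if f_Q is None else f_Q
    imposed = fQ + mod.f_U + f_X
    if imposed >= 1.0:
        raise ValueError(
            "f_Q + f_U + f_X >= 1: no synthesis capacity left for E and R"
        )
    cap = 1.0 - imposed
    f_R = min(params.delta * a, cap)
    f_E = cap - f_R
    return AllocationFractions(f_E=f_E, f_R=f_R, f_Q=fQ, f_X=f_X, f_U=mod.f_U)


def reaction_rates(
    state: CellState,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> np.ndarray:
    """The eight (nine with X turnover) reaction rates at the given state.

    Order: import, synthesis of E, R_a, Q, X, U, inactivation R_a→R_i,
    re-activation R_i→R_a, degradation X→∅.
    """
    a = state.a
    frac = allocation_fractions(a, params, mod, f_X=f_X, f_Q=f_Q)
    syn = params.sigma * state.R_a * a / (a + params.a_sat)
    return np.array(
        [
            mod.k * state.E,
            frac.f_E * syn,
            frac.f_R * syn,
            frac.f_Q * syn,
            frac.f_X * syn,
            frac.f_U * syn,
            mod.kon_cm * state.R_a,
            params.koff_cm * state.R_i,
            params.gamma_X * state.X,
        ]
    )


# Stoichiometry: rows = reactions (as ordered in reaction_rates), columns =
# species (A, E, R_a, R_i, Q, X, U).
STOICHIOMETRY = np.array(
    [
        [+1, 0, 0, 0, 0, 0, 0],  # import
        [-1, +1, 0, 0, 0, 0, 0],  # A -> E
        [-1, 0, +1, 0, 0, 0, 0],  # A -> R_a
        [-1, 0, 0, 0, +1, 0, 0],  # A -> Q
        [-1, 0, 0, 0, 0, +1, 0],  # A -> X
        [-1, 0, 0, 0, 0, 0, +1],  # A -> U
        [0, 0, -1, +1, 0, 0, 0],  # inactivation
        [0, 0, +1, -1, 0, 0, 0],  # re-activation
        [0, 0, 0, 0, 0, -1, 0],  # X degradation
    ],
    dtype=np.int64,
)


def ode_rhs(
    y: np.ndarray,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> np.ndarray:
    """Time derivatives of the seven absolute amounts.

    With ``gamma_X = 0`` the derivatives sum to ``k·E`` (mass conservation:
    volume grows exactly at the nutrient import rate).
    """
    state = CellState.from_amounts(y)
    rates = reaction_rates(state, params, mod, f_X=f_X, f_Q=f_Q)
    return rates @ STOICHIOMETRY.astype(float)


def concentration_rhs(
    c: np.ndarray,
    params: ModelParameters,
    mod: GrowthModulation,
    f_X: float = 0.0,
    f_Q: float | None = None,
) -> np.ndarray:
    """Concentration-form ODEs: amount form per unit volume minus dilution.

    ``c`` holds (a, e, r_a, r_i, q, x, u), which sum to 1.  Dilution acts at
    rate ``k·e`` on every concentration.
    """
    c = np.asarray(c, dtype=float)
    # Any volume works: concentrations are scale-free. Use V = 1.
    dy = ode_rhs(c, params, mod, f_X=f_X, f_Q=f_Q)
    growth = mod.k * c[1] - params.gamma_X * c[5]
    return dy - growth * c
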