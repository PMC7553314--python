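"""Generators for condition grids and synthetic size-law tables.

These emulate the three classic growth-rate modulation experiments:

- *nutrient*: a series of media qualities ``k`` spanning growth rates from
  slow (~0.1/hr) to fast (~2.5/hr);
- *chloramphenicol*: increasing ribosome-inactivation rates ``kon_cm`` at a
  fixed nutrient quality;
- *useless*: increasing forced expression ``f_U`` at a fixed nutrient
  quality.

`make_sizelaw_table` produces per-condition composition/size tables that
obey the size law exactly (``V_div = X_div/f_X`` with
``f_X = f_X_scale·e^{beta_e}·(r_a/r)^{beta_ar}``) and optionally corrupts
the sizes with multiplicative log-normal noise, which keeps the OLS-in-logs
assumptions of the size-law regression exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import GrowthModulation, ModelParameters
from .steady_state import solve_regulated

__all__ = [
    "ConditionGrid",
    "reference_parameterization",
    "k_for_growth_rate",
    "make_modulation_grid",
    "make_sizelaw_table",
]


def reference_parameterization(**overrides) -> ModelParameters:
    """Model constants derived from published E. coli measurements.

    σ converts the maximal translation elongation rate (22 aa/s) into a
    per-extended-ribosome protein synthesis rate, using a ribosome length
    of 7336 aa and the extended-ribosome factor 1.67:
    ``σ = 22·3600/(7336·1.67) = 6.46/hr``.  K converts the RNA/protein
    half-saturation ratio 0.11 into a proteome fraction via the factor
    0.76: ``K = 0.0836``.  ``f_Q = 0.5`` and ``koff_cm = 5.04/hr``.
    """
    sigma = 22.0 * 3600.0 / (7336.0 * 1.67)
    K = 0.11 * 0.76
    base = dict(sigma=sigma, K=K, delta=5.0, f_Q=0.5, koff_cm=5.04)
    base.update(overrides)
    return ModelParameters(**base)


@dataclass(frozen=True)
class ConditionGrid:
    """A labelled list of growth conditions plus generation metadata."""

    kind: str
    conditions: tuple[GrowthModulation, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    def __iter__(self):
        return iter(self.conditions)

    def __len__(self) -> int:
        return len(self.conditions)


def k_for_growth_rate(
    alpha_target: float,
    params: ModelParameters,
    kon_cm: float = 0.0,
    f_U: float = 0.0,
    k_bounds: tuple[float, float] = (1e-3, 500.0),
) -> float:
    """Nutrient quality ``k`` whose balanced-growth rate equals ``alpha_target``.

    α is strictly increasing in ``k``, so bisection on the small-precursor
    solver is well posed.
    """

    def gap(k: float) -> float:
        mod = GrowthModulation(k=k, kon_cm=kon_cm, f_U=f_U)
        return solve_regulated(params, mod).alpha - alpha_target

    return brentq(gap, *k_bounds, xtol=1e-12, rtol=8.9e-16)


def make_modulation_grid(
    kind: str,
    n_conditions: int,
    params: ModelParameters,
    alpha_range: tuple[float, float] = (0.1, 2.4),
    k_fixed: float | None = None,
    kon_max: float = 8.0,
    f_U_max: float = 0.3,
) -> ConditionGrid:
    """A condition grid for one of the three growth-rate modulations.

    - ``nutrient``: ``k`` chosen so growth rates are geometrically spaced
      over ``alpha_range``;
    - ``chloramphenicol``: geometric ``kon_cm`` series (plus the drug-free
      point) at fixed ``k``;
    - ``useless``: linear ``f_U`` series from 0 to ``f_U_max`` at fixed ``k``.

    Every returned condition is solvable by the steady-state module.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    if kind == "nutrient":
        alphas = np.geomspace(alpha_range[0], alpha_range[1], n_conditions)
        conds = tuple(
            GrowthModulation(
                k=k_for_growth_rate(al, params), label=f"nutrient_{i:02d}"
            )
            for i, al in enumerate(alphas)
        )
        meta = {"alpha_targets": alphas.tolist()}
    elif kind == "chloramphenicol":
        k = 3.5088 if k_fixed is None else k_fixed
        kons = np.concatenate(
            [[0.0], np.geomspace(kon_max / 2 ** (n_conditions - 2), kon_max,
                                 n_conditions - 1)]
        )
        conds = tuple(
            GrowthModulation(k=k, kon_cm=kon, label=f"cm_{i:02d}")
            for i, kon in enumerate(kons)
        )
        meta = {"k": k, "kon_grid": kons.tolist()}
    elif kind == "useless":
        k = 3.5088 if k_fixed is None else k_fixed
        fus = np.linspace(0.0, f_U_max, n_conditions)
        conds = tuple(
            GrowthModulation(k=k, f_U=fu, label=f"useless_{i:02d}")
            for i, fu in enumerate(fus)
        )
        meta = {"k": k, "f_U_grid": fus.tolist()}
    else:
        raise ValueError(f"unknown grid kind {kind!r}")
    return ConditionGrid(kind=kind, conditions=conds, meta=meta)


def make_sizelaw_table(
    grid: ConditionGrid | list[GrowthModulation],
    params: ModelParameters,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-condition composition and division size obeying the size law.

    Division sizes follow ``V_div = X_div/f_X`` (the low-precursor
    structural model) times ``exp(ε)``, ``ε ~ N(0, noise_sd²)``.  With
    ``noise_sd = 0`` the size-law regression on (e, r_a/r) recovers the
    exponents ``(−beta_e, −beta_ar)`` exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for mod in grid:
        ss = solve_regulated(params, mod)
        f_X = (
            params.f_X_scale
            * ss.e ** params.beta_e
            * ss.active_fraction ** params.beta_ar
        )
        V = params.X_div / f_X
        if noise_sd > 0:
            V *= np.exp(rng.normal(0.0, noise_sd))
        rows.append(
            {
                "label": mod.label,
                "k": mod.k,
                "kon_cm": mod.kon_cm,
                "f_U": mod.f_U,
                "V_div": V,
                "e": ss.e,
                "r": ss.r,
                "r_a": ss.r_a,
                "active_fraction": ss.active_fraction,
                "alpha": ss.alpha,
            }
        )
    return pd.DataFrame(rows)
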