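"""Structural model of division size and the size-law regression.

Division is triggered when the absolute amount of division proteins X
reaches a condition-independent threshold ``X_div``.  At balanced growth
the division size is then fixed by the steady-state X concentration:

    ``V_div = X_div / x = X_div / (f_X (1 − a))  ≈  X_div / f_X``.

The allocation to X is regulated by the coarse-grained composition,

    ``f_X = f_X_scale · e^{beta_e} · (r_a/r)^{beta_ar}``,

with default exponents ``beta_e = 1`` and ``beta_ar = −2/3``, so that the
division size follows the size law ``V_div ∝ e⁻¹·(r_a/r)^{2/3}`` across
nutrient, chloramphenicol and useless-expression modulations.

The inverse problem — which coarse-grained quantities regulate X, and with
which exponents — is solved by ordinary least squares on logarithms:
``ln V_div`` against the logs of one or two candidate regressors among
``e``, ``r``, ``r_a`` and ``r_a/r``.  Fitted size-law exponents are the
negatives of the corresponding ``f_X`` exponents.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_core import ModelParameters
from .steady_state import SteadyStateSolution

__all__ = [
    "SizeLawFit",
    "SizePrediction",
    "REGRESSOR_NAMES",
    "division_allocation",
    "predict_division_size",
    "predict_c_plus_d",
    "fit_size_law",
    "enumerate_pairwise_fits",
]

#: Candidate coarse-grained regulators of division-protein expression.
REGRESSOR_NAMES = ("e", "r", "r_a", "active_fraction")


@dataclass(frozen=True)
class SizeLawFit:
    """OLS fit of ``ln V_div`` on log coarse-grained quantities."""

    quantity_names: tuple[str, ...]
    exponents: np.ndarray
    ci95: np.ndarray  # shape (n_regressors, 2)
    intercept: float
    r_squared: float
    n_points: int

    def summary_row(self) -> dict:
        row: dict = {
            "regressors": "+".join(self.quantity_names),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "intercept": self.intercept,
        }
        for name, b, (lo, hi) in zip(self.quantity_names, self.exponents, self.ci95):
            row[f"beta[{name}]"] = b
            row[f"ci95_low[{name}]"] = lo
            row[f"ci95_high[{name}]"] = hi
        return row


@dataclass(frozen=True)
class SizePrediction:
    """Division size and C+D duration predicted for one condition."""

    label: str
    f_X: float
    V_div: float  # mass units
    V_div_um3: float
    alpha: float
    c_plus_d: float


def division_allocation(ss: SteadyStateSolution, params: ModelParameters) -> float:
    """Division-protein allocation ``f_X = f_X_scale·e^{beta_e}·(r_a/r)^{beta_ar}``."""
    if ss.active_fraction <= 0:
        raise ValueError("active ribosome fraction must be > 0")
    return (
        params.f_X_scale
        * ss.e ** params.beta_e
        * ss.active_fraction ** params.beta_ar
    )


def predict_division_size(
    ss: SteadyStateSolution,
    params: ModelParameters,
    approx: bool = False,
) -> SizePrediction:
    """Division size from the structural model, ``V_div = X_div/(f_X·(1−a))``.

    With ``approx=True`` the low-precursor form ``X_div/f_X`` is used, which
    makes ``V_div`` exactly proportional to ``e^{−beta_e}·(r_a/r)^{−beta_ar}``.
    """
    f_X = division_allocation(ss, params)
    if approx:
        V_div = params.X_div / f_X
    else:
        V_div = params.X_div / (f_X * (1.0 - ss.a))
    V_um3 = V_div * params.size_scale
    cpd = predict_c_plus_d(V_um3, ss.alpha, params.S0)
    return SizePrediction(
        label=ss.mod.label,
        f_X=f_X,
        V_div=V_div,
        V_div_um3=V_um3,
        alpha=ss.alpha,
        c_plus_d=cpd,
    )


def predict_c_plus_d(V_div_um3: float, alpha: float, S0: float) -> float:
    """C+D period from the replication-initiation size: ``ln(V_div/S0)/α``.

    A division size below the initiation size ``S0`` yields a negative
    duration, returned as-is so callers can flag the non-physical regime.
    """
    if V_div_um3 <= 0:
        raise ValueError("V_div must be > 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return math.log(V_div_um3 / S0) / alpha


def steady_state_with_division(
    params: ModelParameters, mod, exact: bool = True
) -> dict:
    """Self-consistent balanced growth with the division sector attached.

    The housekeeping allocation is reduced so that ``f_Q + f_X`` equals the
    nominal ``f_Q``; the E/R capacity is then unchanged, so growth rate,
    precursor level and the e/r concentrations do not depend on ``f_X`` and
    the division allocation follows in closed form.  Returns the solution,
    the division allocation, the steady X concentration and ``V_div``.
    """
    from .steady_state import solve_regulated, solve_regulated_exact

    ss = (solve_regulated_exact if exact else solve_regulated)(params, mod)
    f_X = division_allocation(ss, params)
    if f_X >= params.f_Q:
        raise ValueError("division allocation exceeds the housekeeping budget")
    x = f_X * (1.0 - ss.a)
    return {
        "solution": ss,
        "f_X": f_X,
        "f_Q_eff": params.f_Q - f_X,
        "x": x,
        "q": (params.f_Q - f_X) * (1.0 - ss.a),
        "V_div": params.X_div / x,
    }


def _design_matrix(table: pd.DataFrame, regressors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in regressors:
        if name not in table.columns:
            raise KeyError(f"regressor {name!r} not in table")
        vals = np.asarray(table[name], dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"regressor {name!r} has non-positive values")
        cols.append(np.log(vals))
    return np.column_stack(cols)


def fit_size_law(
    table: pd.DataFrame,
    regressors: tuple[str, ...] | list[str] = ("e", "active_fraction"),
) -> SizeLawFit:
    """OLS of ``ln V_div`` on the natural logs of 1 or 2 regressors.

    ``table`` needs a positive ``V_div`` column plus the regressor columns
    (any of ``e``, ``r``, ``r_a``, ``active_fraction``).  95% confidence
    intervals come from the standard OLS covariance.  Raises if a regressor
    is (near-)constant or the pair is collinear in log space.
    """
    regressors = tuple(regressors)
    if not 1 <= len(regressors) <= 2:
        raise ValueError("choose 1 or 2 regressors")
    if len(table) < len(regressors) + 2:
        raise ValueError("need at least n_regressors + 2 conditions")
    y = np.log(np.asarray(table["V_div"], dtype=float))
    X = _design_matrix(table, regressors)
    for j, name in enumerate(regressors):
        if np.ptp(X[:, j]) < 1e-12:
            raise ValueError(f"regressor {name!r} is constant: unidentifiable")
    if X.shape[1] == 2:
        corr = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        if abs(corr) > 1.0 - 1e-10:
            raise ValueError("regressors are collinear in log space")
    model = sm.OLS(y, sm.add_constant(X))
    res = model.fit()
    ci = np.asarray(res.conf_int(alpha=0.05))
    return SizeLawFit(
        quantity_names=regressors,
        exponents=np.asarray(res.params[1:]),
        ci95=ci[1:],
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=len(y),
    )


def enumerate_pairwise_fits(table: pd.DataFrame) -> list[SizeLawFit]:
    """All single and pairwise size-law fits, ranked by R².

    Tests the 4 single regressors and the 6 pairs from
    ``(e, r, r_a, r_a/r)``; unidentifiable combinations (constant or
    collinear regressors on this table) are skipped.  Ties in R² are broken
    in favour of fewer regressors.
    """
    fits: list[SizeLawFit] = []
    combos = [(n,) for n in REGRESSOR_NAMES] + list(
        itertools.combinations(REGRESSOR_NAMES, 2)
    )
    for combo in combos:
        try:
            fits.append(fit_size_law(table, combo))
        except (ValueError, KeyError):
            continue
    fits.sort(key=lambda f: (-round(f.r_squared, 12), len(f.quantity_names)))
    return fits
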