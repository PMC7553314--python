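"""Exact stochastic simulation of the growth-and-division model.

Every reaction of the coarse-grained network is simulated as a discrete
event on integer molecule counts (Gillespie's direct method); after each
event all propensities are recomputed, since they depend on the precursor
concentration ``a = A/V`` (through ``f_R = δ·a``) and on the composition
(through the division allocation ``f_X``).  When the division-protein
count reaches ``X_div`` the cell divides: each molecule of each species is
kept in the tracked daughter with probability 1/2 (mother-machine
lineage).  The only noise sources are reaction stochasticity and this
binomial partitioning.

A model variant with first-order degradation of X (``X → ∅`` at
``gamma_X·X``) shifts size homeostasis from 'adder' towards 'sizer'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numba import njit

from .model_core import GrowthModulation, ModelParameters
from .steady_state import solve_regulated_exact

__all__ = [
    "BinnedStatistic",
    "gillespie_lineage",
    "adder_statistics",
    "growth_birth_correlation",
    "noise_summary",
]

_STATUS_OK = 0
_STATUS_EXTINCT = 1
_STATUS_MAX_EVENTS = 2


@njit(cache=True)
def _ssa_kernel(
    y0,
    k,
    kon,
    koff,
    sigma,
    a_sat,
    delta,
    fQ_nom,
    fU,
    fXscale,
    beta_e,
    beta_ar,
    gamma_X,
    X_div,
    n_cycles,
    seed,
    max_events,
):
    np.random.seed(seed)
    A, E, Ra, Ri, Q, X, U = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6]
    cap = 1.0 - fQ_nom - fU
    out_Vb = np.empty(n_cycles, np.float64)
    out_Vd = np.empty(n_cycles, np.float64)
    out_T = np.empty(n_cycles, np.float64)
    out_Xb = np.empty(n_cycles, np.int64)
    t = 0.0
    t_birth = 0.0
    V_birth = float(A + E + Ra + Ri + Q + X + U)
    X_birth = X
    cyc = 0
    events = 0
    status = _STATUS_OK
    while cyc < n_cycles:
        events += 1
        if events > max_events:
            status = _STATUS_MAX_EVENTS
            break
        V = float(A + E + Ra + Ri + Q + X + U)
        if V <= 0.0:
            status = _STATUS_EXTINCT
            break
        a = A / V
        R = Ra + Ri
        af = Ra / R if R > 0 else 1.0
        f_X = fXscale * (E / V) ** beta_e * af**beta_ar
        if f_X > fQ_nom:
            f_X = fQ_nom
        f_Q = fQ_nom - f_X
        f_R = delta * a
        if f_R > cap:
            f_R = cap
        f_E = cap - f_R
        syn = sigma * Ra * a / (a + a_sat) if A > 0 else 0.0
        p0 = k * E
        p1 = f_E * syn
        p2 = f_R * syn
        p3 = f_Q * syn
        p4 = f_X * syn
        p5 = fU * syn
        p6 = kon * Ra
        p7 = koff * Ri
        p8 = gamma_X * X
        total = p0 + p1 + p2 + p3 + p4 + p5 + p6 + p7 + p8
        if total <= 0.0:
            status = _STATUS_EXTINCT
            break
        t += np.random.exponential(1.0 / total)
        u = np.random.random() * total
        if u < p0:
            A += 1
        elif u < p0 + p1:
            A -= 1
            E += 1
        elif u < p0 + p1 + p2:
            A -= 1
            Ra += 1
        elif u < p0 + p1 + p2 + p3:
            A -= 1
            Q += 1
        elif u < p0 + p1 + p2 + p3 + p4:
            A -= 1
            X += 1
        elif u < p0 + p1 + p2 + p3 + p4 + p5:
            A -= 1
            U += 1
        elif u < p0 + p1 + p2 + p3 + p4 + p5 + p6:
            Ra -= 1
            Ri += 1
        elif u < p0 + p1 + p2 + p3 + p4 + p5 + p6 + p7:
            Ri -= 1
            Ra += 1
        else:
            X -= 1
        if X >= X_div:
            V_div = float(A + E + Ra + Ri + Q + X + U)
            out_Vb[cyc] = V_birth
            out_Vd[cyc] = V_div
            out_T[cyc] = t - t_birth
            out_Xb[cyc] = X_birth
            cyc += 1
            A = np.random.binomial(A, 0.5)
            E = np.random.binomial(E, 0.5)
            Ra = np.random.binomial(Ra, 0.5)
            Ri = np.random.binomial(Ri, 0.5)
            Q = np.random.binomial(Q, 0.5)
            X = np.random.binomial(X, 0.5)
            U = np.random.binomial(U, 0.5)
            t_birth = t
            V_birth = float(A + E + Ra + Ri + Q + X + U)
            X_birth = X
    final = np.array([A, E, Ra, Ri, Q, X, U], np.int64)
    return out_Vb[:cyc], out_Vd[:cyc], out_T[:cyc], out_Xb[:cyc], status, final


def _initial_counts(
    params: ModelParameters, mod: GrowthModulation
) -> np.ndarray:
    """Integer birth-sized state near the deterministic balanced-growth point."""
    ss = solve_regulated_exact(params, mod)
    f_X = (
        params.f_X_scale
        * ss.e ** params.beta_e
        * ss.active_fraction ** params.beta_ar
    )
    x = f_X * (1.0 - ss.a)
    V0 = 0.5 * params.X_div / x
    conc = np.array([ss.a, ss.e, ss.r_a, ss.r_i, ss.q, 0.0, ss.u])
    counts = np.maximum(np.rint(conc * V0), 0).astype(np.int64)
    counts[5] = int(params.X_div // 2)
    counts[1] = max(counts[1], 1)  # at least one metabolic enzyme
    counts[2] = max(counts[2], 1)  # and one active ribosome
    return counts


def gillespie_lineage(
    params: ModelParameters,
    mod: GrowthModulation,
    n_cycles: int = 1000,
    seed: int = 0,
    variant: str = "baseline",
    init: np.ndarray | None = None,
    burn_in: int = 50,
    max_events: int = 2_000_000_000,
) -> pd.DataFrame:
    """Simulate a mother-machine lineage for ``n_cycles`` division cycles.

    Returns one row per *post-burn-in* cycle with columns ``cycle,
    V_birth, V_div, added, T, alpha_cycle, X_birth, label``.  Identical
    (params, mod, seed) reproduce identical tables.  ``variant`` is
    ``"baseline"`` or ``"x_degradation"`` (first-order X turnover at
    ``gamma_X``, defaulting to 0.5/hr when the parameter is unset).
    """
    if variant not in ("baseline", "x_degradation"):
        raise ValueError("variant must be 'baseline' or 'x_degradation'")
    if n_cycles <= burn_in:
        raise ValueError("n_cycles must exceed burn_in")
    X_div = int(round(params.X_div))
    if X_div < 2:
        raise ValueError("X_div must be an integer >= 2")
    gamma_X = 0.0
    if variant == "x_degradation":
        gamma_X = params.gamma_X if params.gamma_X > 0 else 0.5
    y0 = _initial_counts(params, mod) if init is None else np.asarray(init, np.int64)
    Vb, Vd, T, Xb, status, _final = _ssa_kernel(
        y0,
        float(mod.k),
        float(mod.kon_cm),
        float(params.koff_cm),
        float(params.sigma),
        float(params.a_sat),
        float(params.delta),
        float(params.f_Q),
        float(mod.f_U),
        float(params.f_X_scale),
        float(params.beta_e),
        float(params.beta_ar),
        float(gamma_X),
        np.int64(X_div),
        np.int64(n_cycles),
        np.int64(seed % 2**31),
        np.int64(max_events),
    )
    if status == _STATUS_EXTINCT:
        raise RuntimeError("lineage went extinct (no reaction possible)")
    if status == _STATUS_MAX_EVENTS:
        raise RuntimeError("event budget exhausted before n_cycles divisions")
    df = pd.DataFrame(
        {
            "cycle": np.arange(len(Vb)),
            "V_birth": Vb,
            "V_div": Vd,
            "added": Vd - Vb,
            "T": T,
            "alpha_cycle": np.log(Vd / Vb) / T,
            "X_birth": Xb,
        }
    )
    df["label"] = mod.label
    return df.iloc[burn_in:].reset_index(drop=True)


@dataclass(frozen=True)
class BinnedStatistic:
    """Equal-count binned means of ``y`` against ``x`` plus a fitted slope."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray
    bin_counts: np.ndarray
    slope: float
    slope_ci95: tuple[float, float]
    intercept: float

    @property
    def slope_excludes_zero(self) -> bool:
        lo, hi = self.slope_ci95
        return lo > 0 or hi < 0


def _binned(x, y, n_bins, min_per_bin) -> BinnedStatistic:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < n_bins * min_per_bin:
        raise ValueError(
            f"need at least n_bins*min_per_bin = {n_bins * min_per_bin} records"
        )
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    centers, means, sems, counts = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < min_per_bin:
            continue
        centers.append(x[sel].mean())
        means.append(y[sel].mean())
        sems.append(y[sel].std(ddof=1) / np.sqrt(n))
        counts.append(n)
    centers = np.array(centers)
    means = np.array(means)
    res = sm.OLS(means, sm.add_constant(centers)).fit()
    ci = np.asarray(res.conf_int(alpha=0.05))
    return BinnedStatistic(
        bin_centers=centers,
        bin_means=means,
        bin_sems=np.array(sems),
        bin_counts=np.array(counts),
        slope=float(res.params[1]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept=float(res.params[0]),
    )


def adder_statistics(
    records: pd.DataFrame, n_bins: int = 8, min_per_bin: int = 30
) -> BinnedStatistic:
    """Added size vs birth size, binned; slope 0 = adder, negative = sizer.

    The slope is dimensionless (added volume per unit birth volume): a pure
    sizer gives −1, a pure timer +1.
    """
    return _binned(records["V_birth"], records["added"], n_bins, min_per_bin)


def growth_birth_correlation(
    records_by_condition: dict[str, pd.DataFrame],
    n_bins: int = 6,
    min_per_bin: int = 30,
) -> dict:
    """Birth size vs single-cycle growth rate, within and across conditions.

    Returns per-condition :class:`BinnedStatistic` objects (cycles binned
    by growth rate) plus the across-condition condition means, which trace
    the deterministic size-vs-growth-rate curve that the within-condition
    trends deviate from.
    """
    within = {
        label: _binned(df["alpha_cycle"], df["V_birth"], n_bins, min_per_bin)
        for label, df in records_by_condition.items()
    }
    across = pd.DataFrame(
        {
            "label": list(records_by_condition),
            "mean_alpha": [
                df["alpha_cycle"].mean() for df in records_by_condition.values()
            ],
            "mean_V_birth": [
                df["V_birth"].mean() for df in records_by_condition.values()
            ],
        }
    )
    return {"within": within, "across": across}


def noise_summary(
    records: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Coefficients of variation of birth size and single-cycle growth rate.

    Bootstrap 95% intervals use ``n_boot`` resamples of whole cycles.
    """
    rng = np.random.default_rng(seed)
    out = {}
    n = len(records)
    for key, col in (("V_birth", "V_birth"), ("alpha_cycle", "alpha_cycle")):
        vals = records[col].to_numpy(float)
        cv = vals.std(ddof=1) / vals.mean()
        boot = np.empty(n_boot)
        for i in range(n_boot):
            s = vals[rng.integers(0, n, n)]
            boot[i] = s.std(ddof=1) / s.mean()
        lo, hi = np.quantile(boot, [0.025, 0.975])
        out[f"cv_{key}"] = float(cv)
        out[f"cv_{key}_ci95"] = (float(lo), float(hi))
    return out
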