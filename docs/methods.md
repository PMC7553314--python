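# Methods

## Model

Seven state variables, all in mass units (one unit = one stochastic
molecule; ~0.15 fg of dry mass): precursors *A*, metabolic enzymes *E*,
active and inactive ribosomes *R_a*, *R_i*, housekeeping proteins *Q*,
division proteins *X*, useless proteins *U*. Volume equals total mass
(density homeostasis), so amount/volume ratios are both concentrations and
mass fractions. Reactions: nutrient import ∅→A at *kE*; synthesis A→S for
each sector S at *f_S*·σ·*R_a*·*a*/(*a*+*a*_sat) with *a = A/V*; ribosome
inactivation/re-activation R_a↔R_i at kon_cm·R_a and koff_cm·R_i; and, in
one variant, first-order turnover X→∅ at γ_X·X. Synthesis converts
precursor mass into protein mass, so dV/dt = *kE* exactly when γ_X = 0.

Allocation is dynamic: *f_Q* fixed, *f_U* imposed, *f_R* = δ·*a* (clamped
to the capacity 1−*f_Q*−*f_U*−*f_X*), *f_E* the remainder, and
*f_X* = fXscale·*e*^(β_e)·(*r_a*/*r*)^(β_ar) with defaults β_e = 1,
β_ar = −2/3. When the division sector is active, the housekeeping fraction
is reduced so *f_Q* + *f_X* keeps its nominal value; this leaves the E/R
capacity — and hence growth rate and composition — independent of *f_X*,
which only sets the size scale together with *X*_div.

## Parameters

| parameter | default | unit | origin |
|---|---|---|---|
| σ | 22·3600/(7336·1.67) = 6.46 | 1/hr | max elongation rate 22 aa/s, extended-ribosome length 7336·1.67 aa |
| K | 0.11·0.76 = 0.0836 | — | RNA/protein half-saturation ratio × conversion factor |
| δ | 5 | — | smallest gain for which the small-precursor approximation is adequate |
| f_Q | 0.5 | — | maximal observed ribosomal proteome fraction leaves half the proteome growth-independent |
| koff_cm | 5.04 | 1/hr | chloramphenicol–ribosome dissociation rate |
| X_div | 60 | molecules | calibrated, see below |
| fXscale | 0.09 | — | calibrated, see below |
| γ_X | 0 (0.5 in the degradation variant) | 1/hr | turnover comparable to dilution at slow growth |
| S0 | 0.28 | μm³ | replication-initiation unit size |
| size_scale | 1e-3 | μm³/unit | reporting constant, see below |

Condition parameters: nutrient quality *k* (1/hr), chloramphenicol
inactivation rate kon_cm (1/hr), burden fraction *f_U*. No mapping from
drug concentration (μM) to kon_cm is provided; kon_cm is the condition
parameter itself.

## Steady states

Balanced growth satisfies α = *k·e* and concentration = fraction × (1−*a*).
Two solvers:

- `solve_regulated` uses the small-precursor (*a*≪1) master equation
  σ·f_R²/(f_R+K) = k·f_E·(1 + kon/(koff + k·f_E)); the two sides are
  strictly monotone in opposite directions in f_R, so the bracketed Brent
  root is unique. The reported *a* is the regulation readback f_R/δ and
  the active fraction is (koff + k·f_E)/(koff + k·f_E + kon). This is the
  closed-form workhorse for growth-law and size-law scans.
- `solve_regulated_exact` keeps every (1−*a*) factor at finite δ; it is
  the true fixed point of the ODEs and the oracle for both lineage
  simulators. At δ = 5 and α ≈ 1/hr the two differ by ~1.7% in α — the
  size of the approximation error, which shrinks with δ (tested).

`solve_optimal` replaces the regulation by bounded scalar maximization of
α(f_R) = k·f_E·(1−a(f_R)), with a(f_R) the exact steady-state precursor
level for fixed fractions. Regulation is near-optimal at physiological
conditions (gap 3.3% at the α≈1/hr reference), but the measured worst-case
gap over the scan grid k∈[0.5,20] × f_U∈{0,.1,.2} × kon∈{0,2,5}/hr is
~14%, at the fastest-nutrient corners: the optimum there runs at precursor
fractions a ≈ 0.15–0.24 which the δ = 5 regulation (a = f_R/5) cannot
reach. The acceptance suite records this gap; near-optimality is a
statement about data-like conditions, not about extreme combined
modulations.

## Division size and the size-law regression

The structural model gives V_div = X_div/(f_X·(1−a)); the low-precursor
form X_div/f_X is exactly a power law in (e, r_a/r) and is the form the
synthetic size-law generator uses, so the noise-free regression round trip
is exact. The regression itself is unweighted OLS of ln V_div on the
natural logs of one or two regressors from {e, r, r_a, r_a/r}, with 95%
CIs from the OLS covariance (statsmodels); fitted size-law exponents are
the negatives of the f_X exponents. `enumerate_pairwise_fits` ranks the 4
single + 6 pairwise combinations by R², skipping combinations whose
regressors are constant or log-collinear on the given table (e.g. the
active fraction in drug-free grids, where it is identically 1). X_div is
treated as condition-invariant; the observationally equivalent reading in
which the threshold itself scales with (r_a/r)^(2/3) is not a separate
code path.

C+D is predicted as ln(V_div/S0)/α, which inverts the exponential
size–growth relation V_div = S0·exp(α(C+D)). Model mass units are
converted to μm³ only here, via size_scale = 1e-3 μm³/unit, chosen once so
the reference condition (α ≈ 1/hr) yields V_div ≈ 2.6 μm³. Division sizes
below S0 return a negative duration rather than clamping.

## Deterministic lineages

`simulate_lineage` integrates the amount-form ODEs with LSODA
(rtol 1e-9, atol 1e-12) and a terminal event on X−X_div (upward crossing);
at each division all amounts are exactly halved (mother machine). Because
halving preserves concentrations, the composition dynamics are autonomous
and converge to the exact steady state; the simulated α, concentrations
and division size agree with the analytic solution to ~1e-8, well inside
the 1e-4 oracle tolerance used in tests. The default initial state splits
the volume evenly over E, R_a and Q with 1% precursors; convergence makes
the choice immaterial (tested via ±20% perturbations, which decay within
10 cycles).

## Stochastic lineages

`gillespie_lineage` is an exact direct-method SSA on integer counts
(numba-compiled). All propensities are recomputed after every event since
f_R and f_X depend on the instantaneous composition; when R = 0 the active
fraction is defined as 1 (transient only, avoids 0/0). Division fires at
the first event reaching X ≥ X_div (X synthesis adds single molecules, so
the threshold is hit exactly); each molecule of each species is kept with
probability 1/2 (per-species binomial sampling). The first 50 cycles are
discarded as burn-in. The only noise sources are reaction timing and
partitioning.

Calibration (done once): with fXscale = 0.09 the reference cell is ~2500
units at division; X_div = 60 then gives CV(V_birth) ≈ 0.13 at α ≈ 1/hr,
in the range reported for *E. coli* (partition noise of the threshold
molecule scales as 1/√X_div, so X_div controls the noise level while
X_div/fXscale sets the size scale). CV of the single-cycle growth rate at
these defaults is ~0.03, on the low side of experimental values — the
model has no extrinsic noise channels.

Statistics: `adder_statistics` bins cycles by birth size (8 equal-count
bins, ≥30 cycles/bin) and fits the bin means by OLS; slope 0 is a perfect
adder, −1 a sizer. The baseline model gives a weak sizer-ward slope
(~−0.05, from the residual correlation between birth size and X count at
birth); the γ_X = 0.5/hr degradation variant gives a significantly
negative slope (~−0.3). `growth_birth_correlation` bins cycles by
single-cycle growth rate within each condition and contrasts those trends
with the across-condition means, which follow the deterministic
size-vs-growth curves (rising for nutrient series, falling for burden
series). `noise_summary` reports CVs with seeded bootstrap intervals.

## Synthetic condition grids

Nutrient grids place growth rates geometrically over [0.1, 2.4]/hr by
inverting α(k) with Brent's method (2.4 rather than a rounder upper edge
because the supremum of α over k at the reference parameterization is
≈2.49/hr, and ≈2.43 within the k ≤ 500 search bracket). Chloramphenicol
grids are geometric kon_cm series plus the drug-free point at fixed k;
burden grids are linear f_U series. Size-law tables corrupt ln V_div with
N(0, sd²) noise, so the OLS-in-logs error model is exact by construction —
real size data have no reason to follow it, which is what the Monte-Carlo
CI coverage checks do and do not establish.

## Problem sizes and limitations

Tests and the acceptance script use 30-condition steady-state suites,
5-condition ODE oracles, 200 noisy regression replicates (n = 40), 3×360
cycles at X_div = 5000 for the mean-field check and 2000–4000 cycles for
single-cell statistics; the whole suite runs in about a minute on one CPU.

Not modelled: mRNA/transcription (synthesis is single-step), nutrient
dynamics, population trees (both daughters), extrinsic parameter noise,
tau-leaping approximations, and any refitting to experimental proteomics
or size datasets — the exponents (1, −2/3) are model inputs here, and the
regression machinery demonstrates recovery on synthetic data only. The
degradation variant's first-order kinetics in X is an assumption; a
zeroth-order variant would differ at low copy number.
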