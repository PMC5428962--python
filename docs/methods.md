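# Methods

## Model

QUEFTS relates crop yield to above-ground nutrient uptake through two
empirical boundary lines per nutrient: at maximum accumulation a kg of
nutrient x supports at most `a_x` kg of seed, at maximum dilution `d_x` kg.
For uptake `U_x` and zero-yield offset `r_x` (default 0) the yield range is

    YA_x = clip(a_x (U_x − r_x), 0, Ymax)
    YD_x = clip(d_x (U_x − r_x), 0, Ymax)

with `Ymax` the climate/genotype yield potential. Nutrient interactions
enter through ordered pair estimates: with j the limited nutrient and i the
diluting partner,

    EY(i,j) = YA_j + (YD_i − YA_j) · ρ (2 − ρ),
    ρ = x / L,  x = (U_j − r_j) − YA_j / d_j,  L = YD_i / a_j − YA_j / d_j,

a parabola rising from j's accumulation yield to i's dilution yield, its
vertex at `U_j − r_j = YD_i / a_j` (beyond which EY stays at `YD_i`); when
`YA_j ≥ YD_i` the pair is fully limited by i and `EY = YD_i`. Each estimate
is clamped to `[0, min(YD_i, Ymax)]`; the predicted yield is the mean of
the six ordered estimates, finally capped at `Ymax` and at every `YD_x`
(no nutrient can carry the crop past its own dilution line). This produces
the familiar linear–parabolic–plateau response.

Capping order matters. `YA`/`YD` are capped at `Ymax` *before* the pair
interpolation; this choice makes the linear phase end at about 61 % of the
potential (first when `YD_P` reaches `Ymax`), consistent with the
published "60–70 %" description. Capping only the final average instead
stretches the linear phase to ~95 % of the potential and was rejected.

## Reverse (requirement) solver

"Balanced" uptake is operationalized as a single balanced position
`t ∈ [0, 1]` shared by the three nutrients:

    u_x(t) = r_x + Y · ((1 − t) / d_x + t / a_x)

so every nutrient sits at the same relative position between its
dilution-minimal (`Y/d`) and accumulation-maximal (`Y/a`) uptake per unit
yield. The forward yield is strictly increasing in `t`, and `t = 1` attains
any target up to `Ymax` exactly, so Brent root-finding on
`combined_yield(u(t)) = Y` over `[0, 1]` is globally convergent and
deterministic (tolerance 1e−6 relative on yield, verified by a forward
round trip at 0.1 %). No multivariate iteration is needed. In the linear
phase `t` is constant, hence constant per-tonne requirements and internal
efficiencies, and the linear-phase requirement is independent of `Ymax`
(exactly, by homogeneity). At `Y = Ymax` the root is `t = 1`: the solver
returns the plateau-onset uptake `Y/a_x`, the smallest uptake whose
predicted yield reaches the potential.

A reference Excel-based solver for this problem class equalizes nutrient
limitation numerically; its exact objective is not recoverable from the
published material. Under the printed Set-I envelope our solver reproduces
the published linear-phase values within 1 % for N and P (54.84 vs 55.4,
7.91 vs 7.9 kg t⁻¹) and 3 % for K (19.47 vs 20.1), the 5.0 t/ha row within
1 % (57.7 vs 58.3), and the full shape of the requirement table. Two
published values are *not* reproduced by construction:

- the 6.0 t/ha row (81.0 kg N t⁻¹): with the target equal to the
  potential, the capped forward model approaches `Ymax` asymptotically in
  uptake, so any convergent solve returns the plateau onset
  (74.1 kg N t⁻¹). The published row corresponds to an uptake whose
  forward yield is ≈99.3 % of the potential — an artifact of iterative
  stopping on the flat asymptote that we do not emulate;
- strict (±0.5 %) constancy of per-tonne P and K through 3.6 t/ha: the
  first `Ymax` cap (on `YD_P`) bites at ≈3.23 t/ha, so P drifts +1.3 % and
  K +1.0 % by 3.6 t/ha. At the published table's print precision (0.1
  kg t⁻¹) such drift is partially invisible.

## Envelope calibration

`a_x` and `d_x` are the lower/upper percentiles of the per-nutrient IE
sample after symmetric tail exclusion — 2.5/97.5 % (Set I), 5/95 %
(Set II), 7.5/92.5 % (Set III) — computed with linear interpolation
between order statistics at rank `p·(n−1)`. The convention is fixed and
documented because alternative percentile definitions move the third
significant digit at n ≈ 2200. Calibration runs on the HI-filtered dataset
(HI ≥ 0.4; records lacking HI are excluded by default and counted in the
log). At least 20 IE values per nutrient are required; degenerate
distributions (a ≥ d) are rejected. Widening the exclusion can only narrow
the envelope — a property test guards the Set I → III monotonicity.

## Seed removal

Nutrient export in harvested seed is obtained by a second balanced solve
under a *seed-based* envelope (calibrated on seed-yield/seed-uptake IEs by
the same percentile method) at the same target yield; the seed share is
its percentage of the above-ground requirement. No seed-based envelope is
published for this calibration, so seed columns require user-supplied
coefficients; an identity envelope yields a 100 % share and a seed
requirement exceeding the above-ground one is rejected as a mass-balance
violation.

## Validation statistics

RMSE = sqrt(mean((s_i − m_i)²)) in kg ha⁻¹ and normalized RMSE =
100·RMSE/mean(measured) in percent, over paired simulated/measured
uptakes. The published field-validation RMSEs rest on unpublished plot
measurements and are intentionally out of reach; the module is exercised
on toy pairs with hand-computed expectations and on synthetic pairs with
analytically known noise. A plain per-nutrient mean-bias summary is
provided without inferential claims (significance testing is out of
scope).

## Synthetic trial generator

Each record draws: seed yield from a truncated normal
(2472 ± 683 kg ha⁻¹ on [300, Ymax]); HI from a truncated normal
(0.46 ± 0.06 on (0.2, 0.7)); per-nutrient IE from a beta(2,2) rescaled so
that the configured envelope is the **central 95 % band** of the IE
distribution (the envelope is *defined* as the 2.5/97.5 percentile pair,
and observed IE extremes lie well outside it, so the support must exceed
the band); uptake = yield/IE, perturbed by mean-one lognormal noise
(default CV 8 %); a seed/straw split by truncated-normal nutrient harvest
indices (means 0.84/0.67/0.58 for N/P/K); and tissue concentrations
derived consistently with the dry weights, so recomputing uptake from the
stored record reproduces the noisy uptake exactly. One integer seed
governs everything; each record uses a spawned substream, so extending
`n_obs` never reshuffles earlier records.

What the generator does *not* emulate: correlations between yield and IE,
between nutrients, or across sites/years; treatment structure (omission
plots); soil or climate covariates; truncation of concentrations at
physiological limits. Passing recovery tests therefore demonstrates
correctness of the calibration machinery under the stated sampling model,
not robustness to real-data structure.

## Numerical choices and problem sizes

- Percentile/quartile convention: linear interpolation at rank `p·(n−1)`
  everywhere (summaries and calibration).
- Balanced solve: Brent on `[0, 1]`, xtol 1e−13; forward round-trip
  verified at 0.1 % or the solve raises.
- Degenerate inputs: zero target → zero uptake row; zero uptake → IE
  undefined (raised); zero yield → IE 0 with RIE flagged NaN; empty
  summaries and inverted configuration bounds are rejected.
- Requirement tables use the printed-table grid (0; 0.8–3.6 by 0.4;
  3.9–4.8 by 0.3; 5.0–6.0 by 0.2 t ha⁻¹, scaled to `Ymax`); the linear
  limit is located on an internal 400-point probe, defined as the largest
  target whose per-tonne N requirement is within 0.5 % of the small-target
  constant. Full precision is kept internally; rounding to 0.1 kg t⁻¹
  happens only in the presentation layer.
- Test problem sizes: envelope-recovery runs use n = 5000 records
  (noise-free) and n = 2000 (unit level); validation-pair calibration uses
  200–300 sites; the forward/reverse consistency sweep uses 50 targets.
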