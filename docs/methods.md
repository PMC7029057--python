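# Methods

## Model overview

`leafopt` treats a mature leaf as a steady-state economic agent with two
slow controls: its area `LA` and its (life-span average) stomatal resistance
`r_es`. Both controls raise carbon income and both spend the same scarce
resource — xylem water potential. The model maximizes whole-leaf net carbon
gain subject to a cap `ΔΨ_Lmax` on the total potential loss along one flow
path from the petiole to a terminal minor vein. The cap, not water volume,
is the budget: even where soil water is unlimited, the potential at which
cavitation impairs the leaf (`Ψ_C`, well approximated by the P50 of a
vulnerability curve) bounds how hard the leaf may pull. With `Ψ_P` the
petiole potential, `ΔΨ_Lmax = Ψ_P − Ψ_C`.

Assumptions: steady state at fixed 25 °C environment; the linear
assimilation model (a deliberately simple stand-in for Farquhar kinetics
that keeps the optimum in closed reach — it slightly overestimates GPP but
preserves the monotonicities that drive the optimum); Hagen–Poiseuille flow
in xylem conduits; a dendritic, space-filling venation hierarchy; no
boundary-layer resistance (`r_es` is the whole vapor path); no light,
temperature, or instantaneous stomatal dynamics.

## Venation reconstruction

The venation model is the package's load-bearing reconstruction, so its
derivation is spelled out.

Orders run 0 (major vein, length `l0 = √(LA/k_SP)`, the leaf length) to `T`
(terminal minor veins, fixed length `l_T`). Per order, vein lengths shrink
by `γ = k_SP/2` — a broader leaf's veins shorten more slowly — so
`T = log_γ(l_T/l0)`, treated as a continuous real. Conduit radii shrink
downstream by `β` per order; conservation of a vein's total conduit
cross-section then fixes the conduit-count branching ratio at `m = 1/β²`
(counts multiply by m downstream: the major vein has fewer, wider conduits,
`M0 = M_T·β^{2T}`, `r0 = r_T/β^T`, with `M0·r0² = M_T·r_T²` exact). Veins
branch with ratio `n`; space filling in two dimensions (each order-k vein
serves a territory scaling with `l_k²`) gives `n = 1/γ²`.

Water enters the xylem only at the terminal veins. Walking upstream from a
terminal vein, the flux carried per unit conduit cross-section therefore
grows by `n` at every branching, while the per-conduit-area Poiseuille
resistance of order k is `(8μ/ρ_w)·l_k/r_k²` and grows by `β²/γ` per order
toward the terminal end. Referencing the whole path to the terminal flux
density `J_x` gives a geometric series with per-order ratio `q = n·β²/γ`:

    r_Xtotal = (8μ/ρ_w)·(l_T/r_T²)·Σ_{j=0..T} q^j
             = (8μ/ρ_w)·(l_T/r_T²)·[1 − q^{T+1}]/[1 − q],

with the `(T+1)`-segment limit at `q → 1`. The units are Pa per unit
mass-flux density; the `1/ρ_w` factor converts the mass flux to the mean
conduit velocity, so `J_x·r_Xtotal` is in Pa with `J_x` in kg m⁻² s⁻¹. The
explicit per-order sum is implemented separately and used as the oracle in
tests (they agree to 1e-10 at integer T).

Without the branching factor `n` (i.e. a literal single-conduit path with
ratio `β²/γ < 1` at the defaults), the series saturates after a few orders
and the maximum attainable `Ψ_loss` at the default parameters is below one
pascal — the kPa budgets the model is exercised at could never bind and no
trait covariance would emerge. With `n = 1/γ²` the potential drop lands in
the kPa range and the constrained optimum at a 3 kPa budget falls at
15.6 cm², essentially the ~16 cm² mean leaf area the default parameter set
is built around. This consistency is the package's main internal check that
the accumulated-flux reading is the right one.

## Transpiration path

The constraint-side flux is stomatally controlled:
`E = cons2·(e_sat − e_a)/r_es` (vapor density difference over the stomatal
resistance). The interior liquid path — diffusion across half the inter-vein
spacing `k_Z·Z/2` through mesophyll with diffusivity `D_m` and saturated
tissue concentration `w0`, surface equilibrium `w_1 = w0·e_l/e_sat` — is
implemented as a two-resistor series diagnostic (`mesophyll_state`),
reporting the interior vapor pressure `e_l` and surface concentration `w_1`.
It is deliberately kept out of the constraint flux: at the default
mesophyll parameters that leg is equivalent to ≈5,600 s/m of stomatal
resistance, which is more than an order of magnitude above the GPP
half-saturation scale (≈312 s/m); placed in series it would pin the optimal
stomatal resistance at zero for every budget and erase the stomatal
trade-off the model exists to study. Under stomatal control every positive
budget is feasible (`Ψ_loss → ∞` as `r_es → 0`), so the closed-form
constraint inversion

    r_es(LA; ΔΨ) = cons2·(e_sat − e_a)·A·r_Xtotal(LA)/ΔΨ,
    A = (l_T·k_Z·Z/2)/(M_T·π·r_T²),

is always strictly positive. Thickness `Z` enters the constraint through the
served-strip area `A ∝ Z`: a thicker leaf (sparser minor veins) pushes more
water through each terminal conduit at the same conductance, pays more
potential, and optimally sits at higher `r_es` and smaller `LA`.

## Parameters

Defaults (SI, 25 °C), single source of truth in `leafopt.params`:

| symbol | meaning | default | units |
|---|---|---|---|
| a1 | maximum carboxylation capacity | 60e-6 | mol m⁻² s⁻¹ |
| a2 | biochemical constant Kc(1+Coa/Ko) | 510e-6 | mol/mol |
| Ca | ambient CO₂ mole fraction | 4e-4 | mol/mol |
| S | leaf-to-air CO₂ ratio | 0.6 | – |
| R | carbon cost per leaf volume | 0.9e-6 | mol m⁻³ s⁻¹ |
| k_SP | width-to-length ratio W/L | 0.28 | – |
| Z | leaf thickness | 300e-6 | m |
| k_Z | vein-spacing-to-thickness ratio | 1 | – |
| l_T | terminal vein length | 150e-6 | m |
| r_T | terminal conduit radius | 3e-6 | m |
| M_T | conduits per terminal vein | 1 | – |
| β | conduit radius ratio per order | 0.30 | – |
| Ψ_C | critical xylem potential | −5e6 | Pa |
| e_sat, e_a | saturated/ambient vapor pressure | 3169, 1584.5 | Pa |
| cons1 | molar mass of water | 0.01801528 | kg/mol |
| cons2 | 1/(R_w·T) | 7.27e-6 | s²/m² |
| cons3 | mass→molar resistance conversion | 0.025 | m³/mol |
| μ, ρ_w | water viscosity, density | 8.90e-4, 1000 | SI |
| D_m, w0 | mesophyll diffusivity, saturation | 8.5e-10 m²/s, 40 mol/m³ (diagnostic path) |
| ΔΨ_Lmax | potential budget | 3e3 | Pa |

`M_T = 1` is implied by the single-conduit cross-section in the terminal
funneling factor; `β = 0.30` is a mid-range taper (the source literature for
the parameter set does not pin it, so all β-dependent magnitudes are
reproducible only up to this choice — the sensitivity is smooth: larger β
raises `q` and steepens `r_Xtotal(LA)`, shrinking optimal leaves at fixed
budget). `D_e` (vapor diffusivity in air, 24e-6 m²/s) is stored for
completeness and unused. `l_T` is half the default thickness but kept as an
independent parameter: thickness sweeps vary `Z` alone.

## Output scale

SI magnitudes of NPP_leaf at these parameters are ~1e-9 mol/s, whereas the
published presentation of this model family reports the same sweeps on an
axis where the 3 kPa shape-effect delta reads 0.47. The axis normalization
is not derivable from the parameter table, so the package carries one output
scale constant, `PAPER_NPP_SCALE = 2.868e8`, calibrated once against that
single anchor and shared by every scaled output. Ratios, orderings, and all
comparative statics are independent of it; the 4 kPa delta is a genuine
prediction (0.657 on that scale, vs 0.65 reported — agreement to 1%).

## Numerics

* Reduced 1-D solve: the active constraint eliminates `r_es` analytically;
  the reduced derivative of NPP over log LA is closed-form; a 256-point
  bracket scan on LA ∈ [1e-6, 1] m² locates sign changes and Brent's method
  polishes each to xtol 1e-13. A maximum at a bracket edge is returned with
  `converged=False`, never silently. Typical residuals: constraint ~1e-16
  relative, equal-marginal condition ~1e-15 relative.
* All partial derivatives used in the first-order report are analytic;
  central differences are test-side cross-checks only.
* The grid oracle evaluates NPP on a log-spaced (LA, r_es) mesh, masks
  infeasible points, and returns the argmax; its undershoot is first-order
  in the grid step (the feasibility cut lands up to one step inside the
  boundary), which is the error bound the tests use.
* Isolines: marching squares (`skimage.measure.find_contours`) on a
  log-spaced 200×200 grid, then one Newton step per vertex in LA using the
  analytic field derivative; Ψ_loss vertices reproduce their level to 1e-6
  relative. Degenerate guards: the Newton step is skipped if it would leave
  the cell neighbourhood or the derivative underflows.
* Series edge cases: `q → 1` switches to the `(T+1)` limit inside
  |q−1| ≤ 1e-12; the series is evaluated via `expm1` in log space, finite
  over at least LA ∈ [1e-4, 1e-2] m² for k_SP ∈ [0.1, 0.5].
* T is continuous; the integer-T per-order sum exists purely as an oracle.
* CSV output uses `%.17g` (exact double round-trip) and embeds the full
  generating parameter set as a JSON comment header.

The model is fully deterministic; random draws appear only in tests (seeded
`numpy.random.default_rng` / derandomized hypothesis profiles) to sample
parameter space.

## Limitations

* The venation series ratio and every β-dependent magnitude rest on the
  accumulated-flux reconstruction argued above; the qualitative predictions
  (all orderings and monotonicities) are robust to the choice of `n`, but
  absolute Ψ_loss magnitudes are not.
* The optimal stomatal resistances at the defaults (~2e4 s/m) and GPP
  values (~0.5 μmol m⁻² s⁻¹) are internally consistent but low compared
  with field-measured leaves; the parameter set inherits laboratory-derived
  mesophyll-scale constants, and the absolute operating point should be
  read as a model scale, not a field prediction.
* Single leaf, fixed environment: no canopy light, no leaf energy balance,
  no instantaneous stomatal response, no loopy/reticulate venation, no
  pit-level anatomy (all folded into `r_T`), no optimization over shape,
  thickness or taper — those are swept exogenously.
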