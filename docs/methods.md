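# Methods

## Model

A single cylindrical lignocellulose fibre of radius `R_i` sits in a closed
annulus of acid hydrolysate reaching to `R_o = R_i (1 + hydrolysate_factor)`;
with the default factor 2.32 the annulus cross-section is ~10× the fibre's,
matching the liquid-to-solid loading of a packed pretreatment cell. Only
radial transport is considered (fibres are long and thin), the domain is
isothermal and isobaric, and the acid is not a transported species: pores
are assumed instantly acid-filled, so the catalysing concentration is the
bulk value scaled by local porosity, ψ = ε_v C_H⁺ (ε_v = 1 in the
hydrolysate). One mole of hydronium per mole of sulfuric acid is assumed
(0.5 wt% ≈ 51 mol m⁻³).

Hemicellulose is idealised as linear xylan chains of DP 1..N (N = 100,
chosen within the plausible DP range of bagasse xylan). Chains of DP ≤ m
(m = 15) are soluble; longer chains are solid and immobile. The state is
the volume-averaged mass concentration of every chain length plus furfural.
Initially the reactive xylan is monodisperse at DP N with concentration
`(1 − α) ε_N⁰ ρ_s` on fibre nodes, everything else zero.

Scission follows discrete population-balance (binary breakage) kinetics with
the mass-based random-scission kernel

    Ω(i, j−i) = i / (j (j−1)),

the unique weight for which the gain term `2 k ψ Σ Ω φ_j` exactly
balances the loss `−k ψ φ_j` (every bond equally likely; fragments carry the
parent's mass). Solid chains scise at `k_a`, aqueous chains at `k_b`, and
xylose degrades to furfural at `k_d`. Furfural inherits xylose's mass 1:1,
so the model system conserves mass exactly; molar-mass corrections (water of
hydrolysis, the 132/96 furfural factor) belong to the *experimental* yield
conversions in `experiment_io`, not to the model equations.

A temperature-dependent fraction α(T) of the xylan is treated as entirely
unreactive on the hydrolysis timescale ("hard to hydrolyse", the standard
biphasic observation for lignocellulose). It enters only the porosity
closure and the yield normalisation; it is not a tracked species.

Porosity follows algebraically from volume bookkeeping,
`ε_v = 1 − (F̂ + Σ_{i>m} φ_i/ρ_s + α ε_N⁰)`, rising from 0.254 (untreated
fibre) towards `1 − F̂ − α ε_N⁰` as solid dissolves. Dissolution therefore
feeds back on both the effective acid concentration and the effective
diffusivity `D_eff = ε_v³ D_∞(i)`, with `D_∞` Stokes-Einstein on the
hydrodynamic radius `R_h(i) = 0.676 l √i` and furfural given the fixed
literature value 1.12e-9 m² s⁻¹.

Yields are reported in % of the initial xylan mass (including the
unreactive part): aqueous species are integrated over the hydrolysate
cross-section, the solid remnant over the fibre, both with the cylindrical
measure r dr.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `F_hat` | fixed lignocellulose volume fraction | 0.581 | — |
| `eps_N0` | initial xylan volume fraction | 0.165 | — |
| `rho_s` | solid xylan density | 1500 | kg m⁻³ |
| `N`, `m` | chain cap, solubility cutoff | 100, 15 | DP |
| `l` | monomer segment length | 0.65e-9 | m |
| `R_i` | fibre radius | 3.75e-4 | m |
| `hydrolysate_factor` | (R_o − R_i)/R_i | 2.32 | — |
| `C_H` | bulk acid concentration | 51 | mol m⁻³ |
| `k_a, k_b, k_d` | scission/degradation rates | fitted | m³ mol⁻¹ s⁻¹ |
| `alpha` | unreactive fraction | fitted / α(T) | — |
| `n_fibre, n_hydro` | nodes per region | 100, 250 | — |

Two constants with no firm literature value are explicit, documented
configuration rather than silent assumptions: `rho_s` (1500 kg m⁻³, typical
for cell-wall polysaccharides; reported yields are invariant to it — only
the porosity feedback depends on it) and the solution viscosity
(Vogel-type liquid-water correlation `2.414e-5 · 10^{247.8/(T−140)}` Pa s,
treating 0.5 wt% acid as water; pluggable via the `viscosity` argument).

Temperatures are Kelvin internally (°C + 273.15 at I/O); times are seconds
internally, minutes at every I/O boundary.

## Numerics

Vertex-centred finite volumes on uniform nodes per region; the interface
vertex at `R_i` is shared. Its control volume straddles both regions, so a
per-node fibre-material fraction (1 in the interior, the fibre sub-volume
share at the interface) scales the fixed volume fractions and the initial
solid concentration there; the discrete initial xylan mass then equals
`ε_N⁰ ρ_s R_i²/2` exactly and yield normalisation is grid-consistent. Face
diffusivities are harmonic means, preserving flux continuity across the ε_v³
jump at the interface; fluxes vanish at r = 0 and r = R_o.

Porosity is substituted algebraically, leaving a pure (stiff) ODE system.
The default integrator is LSODA with a banded Jacobian: under a node-major
ordering of the unknowns the Jacobian has bandwidth ≲ 2(N+1), independent of
grid size (≈200 MB and ~15 s for the full 14,100-unknown problem; BDF with a
sparse Jacobian pattern is available as an option). Concentrations are
scaled by `ε_N⁰ ρ_s` so the tolerances (rtol 1e-7, atol 1e-10) act on an
O(1) state. Small negative integrator overshoots are clipped when
evaluating rates and logged if they exceed 1e-8 of the concentration scale.
Doubling both grids moves every yield by < 0.05 percentage points at the
default resolution.

Model yields are interpolated to observation times with cubic splines.
Calibration is bounded least squares (trust-region-reflective, equal
weights, relative finite-difference increment 0.01) run as an outer loop of
single Gauss-Newton-style steps so the classical stopping rule can be
applied literally: at most 30 iterations, early stop when the relative Φ
improvement over 4 consecutive iterations falls below 0.005. Default bounds
keep rates in [0, 1] m³ mol⁻¹ s⁻¹ and α in [0, 0.9] ("prevent non-physical
values"); an optional seeded Latin-hypercube multi-start guards against
local minima. The Arrhenius laws (`ln k` vs `1/T`) and the exponential
α-law (`ln α` vs `T`, the spreadsheet exponential-trendline convention) are
closed-form OLS; on exact-law input they recover the coefficients to
round-off, and on the three calibrated parameter sets they reproduce the
reference constants (e.g. E_a(k_d) = 1.54675e5 J mol⁻¹, α(T) = 4.1820e9
e^(−6.0514e-2 T)) to better than 0.1%.

Two behaviours of the equations are worth noting because they differ from
first intuition. First, k_a is strongly non-Arrhenius across the three
calibration temperatures (its 140 °C value is ~30× the 125 °C value), so
the k_a regression line tracks the per-temperature fits only to within a
factor of ~2.5; k_b and k_d are within 15%, α(T) within 20%. Second,
diffusion acts on the volume-averaged concentration φ, so a closed system
equilibrates to uniform φ across the whole cross-section: with k_d = 0 and
α = 0 the terminal xylose yield is the hydrolysate's share of the
cross-section measure (~91% at the default geometry), not 100%.

## Synthetic data and what passing tests show

No machine-readable experimental curves ship with the package, so the
calibration pipeline is exercised on synthetic data: forward-simulated
yields at sparse sampling times with multiplicative (5%) plus additive
(0.2 pp) Gaussian noise, clipped at zero, seeded, with the generating truth
in a sidecar JSON. The defaults emulate sparse HPLC sampling over the
110 °C horizon (5–360 min, with early points because the solid-chain decay
is fast); they are a synthetic choice and cannot be validated against a
published error model. Recovery studies run on a reduced chain system
(N = 12, m = 4, coarse 6+4 grid) with 110 °C-like rates and k_d = 4e-8
m³ mol⁻¹ s⁻¹ — between the 110 and 125 °C fitted values — so furfural peaks
near 2.5% and all four parameters are identifiable; with k_d an order of
magnitude lower, furfural sits below the noise floor and k_d is not
recoverable, which is a property of the experiment design, not of the
optimiser. Passing recovery tests therefore show the estimator is unbiased
and reasonably tight *under this noise model and sampling design*; real
chromatography data adds systematic errors (calibration drift, heat-up
transients, species misassignment) that the generator deliberately does not
emulate.

The scission kinetics are validated in the well-mixed limit against two
independent oracles: a longhand per-species ODE integration, and an
event-driven particle simulation in which every chain breaks at a constant
rate with the cut bond uniform — the exact number-process counterpart of the
mass-based kernel. The PDE solver matches the longhand oracle within 1% on
a fibre shrunk far below its diffusion length, and the ODE matches the
particle simulation within 3 Monte-Carlo standard errors.

## Limitations

* Cellulose and lignin are inert volume; acetyl groups, acetic acid,
  branched xylan and furfural's further degradation are not modelled.
* The α(T) exponential diverges at low temperature; prediction is refused
  below 383.15 K (110 °C).
* High-temperature validation data in the literature are distorted by
  apparatus heat-up time (non-zero yields at t = 0); no deconvolution is
  attempted beyond an optional time offset when generating synthetic data.
* The hydrolysate annulus and fibre radius are fixed: no fibre shrinkage,
  swelling or reactor-scale gradients.
* Φ values from fits to figure-derived data are not reproducible here; only
  their orderings (4-parameter beats 3-parameter; freeing diffusivities does
  not substitute for α) are meaningful, and those are asserted on synthetic
  analogues.
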