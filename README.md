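# fibrolysis

Population-balance modelling of the dilute-acid hydrolysis of hemicellulose
(xylan) in lignocellulosic fibres, for researchers studying acid pretreatment
of feedstocks such as sugarcane bagasse.

Dilute-acid pretreatment removes hemicellulose from lignocellulose so that
enzymes can reach the cellulose. `fibrolysis` models a single idealised
cylindrical fibre immersed in an annulus of acid hydrolysate and predicts the
yield-versus-time curves of xylose, short xylo-oligomers (DP 2-6) and
furfural, resolving *every* chain length, the radial transport of soluble
species, and the opening of the fibre's pore structure as solid xylan
dissolves.

## The model

Chains of degree of polymerisation (DP) `i` are tracked as volume-averaged
mass concentrations φᵢ(r, t). Chains with DP ≤ m are soluble and diffuse;
longer chains are solid xylan confined to the fibre. Random scission moves
mass down the chain-length spectrum:

    ∂φᵢ/∂t = −k ψ φᵢ + 2 k ψ Σ_{j>i} Ω(i, j−i) φⱼ + (1/r) ∂/∂r ( r D_eff ∂φᵢ/∂r )

with the mass-based random-scission kernel Ω(i, j−i) = i / (j (j−1)), which
conserves mass exactly (Σ_{i<j} 2Ω = 1). Solid chains break at rate k_a,
aqueous chains at k_b, and xylose degrades to furfural at k_d
(m³ mol⁻¹ s⁻¹), all catalysed by the effective acid concentration
ψ = ε_v C_H⁺, where the porosity ε_v follows from volume conservation

    ε_v = 1 − (F̂ + Σ_{i>m} φᵢ/ρ_s + α ε_N⁰)

as solid xylan dissolves. A fraction α(T) of the xylan is "hard to
hydrolyse" and treated as unreactive. Effective diffusivities are
Stokes-Einstein with a tortuosity factor ε_v³. The two-region cylindrical
domain (fibre 0 ≤ r ≤ R_i, hydrolysate R_i < r ≤ R_o) is closed (no-flux at
r = 0 and r = R_o), discretised with a vertex-centred finite-volume scheme
and integrated as a stiff ODE system.

Calibration fits (k_a, k_b, k_d, α) to measured yield curves by bounded
least squares; Arrhenius regressions of the fitted rates and an exponential
fit α(T) = A e^(−bT) then let the model *predict* yields at temperatures it
was never fitted to.

## Worked example

Simulate six hours of hydrolysis at 110 °C with the calibrated rate
parameters and print the final yields:

```python
import numpy as np
from fibrolysis import (
    Conditions, KineticParams, MaterialGeometry, simulate, yields,
)

geom = MaterialGeometry()            # bagasse defaults, N = 100, m = 15
t_end = 360 * 60.0
cond = Conditions(T=383.15, C_H=51.0, t_end=t_end,
                  output_times=np.linspace(0.0, t_end, 61))
params = KineticParams(k_a=2.0630e-4, k_b=1.5434e-5, k_d=7.9618e-9,
                       alpha=0.32016)

traj = simulate(geom, cond, params)
series = yields(traj, geom, params)
for label in ("X1", "X2", "X3", "furfural"):
    print(f"{label:9s} {series.yields[label][-1]:8.3f} % at 360 min")
```

Output (a couple of minutes on one CPU):

```
X1         61.322 % at 360 min
X2          0.049 % at 360 min
X3          0.002 % at 360 min
furfural    0.345 % at 360 min
```

By 360 min nearly all of the reactive xylan (67.98% of the total, since
α ≈ 0.32 is unreactive) has dissolved and been cut down to xylose, most of
which has diffused into the hydrolysate: the xylose yield plateaus at ~61%,
in line with the ~63% measured at these conditions. Oligomers have passed
through their transient maxima and are nearly extinct; only a trace of
furfural has formed because xylose degradation is slow at 110 °C.

The same workflow is available from the shell:

```
fibrolysis simulate --k-a 2.0630e-4 --k-b 1.5434e-5 --k-d 7.9618e-9 \
    --alpha 0.32016 --out results/110C
fibrolysis synth    --k-a 2e-4 --k-b 1.5e-5 --k-d 4e-8 --alpha 0.32 \
    --rel-sd 0.05 --seed 1 --out results/synthetic.csv
fibrolysis fit      --experiment results/synthetic.csv --out results/fit
fibrolysis laws     --table results/rates_by_temperature.csv --out results/laws.json
fibrolysis predict  --laws results/laws.json --temp-c 155 --out results/155C
```

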