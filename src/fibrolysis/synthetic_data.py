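"""Pseudo-experimental data generation and small brute-force oracles.

The experimental yield curves this model is calibrated against exist only as
published figures, so recovery studies and end-to-end tests run on synthetic
data: forward-simulated yield profiles at sparse sampling times with
multiplicative plus additive Gaussian noise.  A sidecar JSON records the
generating parameters so fits can be scored against ground truth.

Two independent oracles validate the scission kinetics in the well-mixed
(0-D) limit for small maximum chain length:

* a longhand ODE integration of the chain equations, written as explicit
  per-species loops (deliberately sharing no code with the vectorised
  solver), and
* an event-driven stochastic simulation of random scission over a large
  population of chains, whose number-based dynamics (every chain breaks at
  the same rate, the cut bond chosen uniformly) are the exact particle
  counterpart of the mass-based kernel i / (j (j-1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import model_at_times
from .experiment_io import write_experiment
from .model_core import (
    Conditions,
    KineticParams,
    MaterialGeometry,
)

__all__ = [
    "NoiseModel",
    "generate_experiment",
    "scission_ode",
    "scission_ssa",
    "scission_oracle",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for synthetic yields.

    Observed yield = y * (1 + e_rel) + e_abs with independent Gaussians
    e_rel ~ N(0, rel_sd^2) and e_abs ~ N(0, abs_sd^2) (% yield), clipped at
    zero.  Defaults approximate the scatter of sparse HPLC yield series;
    they are a synthetic choice, not a measured error model.
    """

    rel_sd: float = 0.05
    abs_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sd < 0 or self.abs_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def generate_experiment(
    params: KineticParams,
    cond: Conditions,
    geom: MaterialGeometry,
    sample_times_min: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    *,
    species: Optional[Sequence[str]] = None,
    out_csv=None,
    sidecar_json=None,
    **solver_options,
) -> List[Tuple[str, float, float]]:
    """Forward-simulate and sample noisy yield observations.

    Returns (species, time_min, yield_pct) triples; optionally writes the
    tidy experiment CSV and a sidecar JSON holding the generating truth.
    Byte-identical outputs for identical inputs and seed.
    """
    times = np.asarray(sample_times_min, dtype=float)
    if species is None:
        species = ["furfural"] + [f"X{i}" for i in range(1, min(6, geom.m) + 1)]
    series = model_at_times(params, cond, geom, times, **solver_options)
    rng = np.random.default_rng(noise.seed)
    observations: List[Tuple[str, float, float]] = []
    for label in species:
        clean = series.yields[label]
        e_rel = rng.normal(0.0, noise.rel_sd, size=clean.shape) if noise.rel_sd else 0.0
        e_abs = rng.normal(0.0, noise.abs_sd, size=clean.shape) if noise.abs_sd else 0.0
        noisy = np.clip(clean * (1.0 + e_rel) + e_abs, 0.0, None)
        observations.extend(
            (label, float(t), float(y)) for t, y in zip(times, noisy)
        )
    if out_csv is not None:
        write_experiment(observations, out_csv)
    if sidecar_json is not None:
        truth = {
            "params": {
                "k_a": params.k_a,
                "k_b": params.k_b,
                "k_d": params.k_d,
                "alpha": params.alpha,
            },
            "temperature_K": cond.T,
            "acid_mol_m3": cond.C_H,
            "noise": {
                "rel_sd": noise.rel_sd,
                "abs_sd": noise.abs_sd,
                "seed": noise.seed,
            },
            "species": list(species),
            "sample_times_min": [float(t) for t in times],
        }
        with open(sidecar_json, "w") as fh:
            json.dump(truth, fh, indent=2)
    return observations


# ---------------------------------------------------------------------------
# well-mixed oracles
# ---------------------------------------------------------------------------


def scission_ode(
    N_small: int,
    m_small: int,
    params: KineticParams,
    psi: float,
    t_grid: Sequence[float],
    phi0: Optional[Sequence[float]] = None,
    porosity_closure: Optional[dict] = None,
) -> Dict[str, np.ndarray]:
    """Longhand 0-D integration of the chain scission/degradation equations.

    State: furfural plus chains of DP 1..N_small (mass concentrations, by
    default normalised so the initial reactive plus unreactive mass is 1).
    ``psi`` is the fixed effective acid concentration; if
    ``porosity_closure`` = ``{"F_hat", "eps_N0", "rho_s", "C_H"}`` is given,
    psi is instead recomputed every step from the porosity of the remaining
    solid chains (DP > m_small), mirroring the fibre feedback.

    Returns ``{"t", "furfural", "chains"}`` with ``chains[i-1]`` the DP-i
    trajectory.  Written with explicit loops as an independent oracle for
    the vectorised solver.
    """
    if N_small < 2:
        raise ValueError("need N_small >= 2")
    if not 1 <= m_small <= N_small:
        raise ValueError("need 1 <= m_small <= N_small")
    N, m = N_small, m_small
    if phi0 is None:
        phi0 = np.zeros(N)
        phi0[N - 1] = 1.0 - params.alpha
    phi0 = np.asarray(phi0, dtype=float)
    y0 = np.concatenate([[0.0], phi0])  # furfural first

    def omega(frag, parent):
        # random-scission kernel weight for a fragment of DP `frag` from a
        # parent of DP `parent`
        return frag / (parent * (parent - 1.0))

    def rhs(t, y):
        furf, chains = y[0], y[1:]
        if porosity_closure is not None:
            # chains are on the normalised mass scale, so the solid volume
            # fraction is (remaining solid mass fraction) * eps_N0
            pc = porosity_closure
            solid_frac = sum(chains[j - 1] for j in range(m + 1, N + 1)) * pc["eps_N0"]
            eps_v = 1.0 - (pc["F_hat"] + params.alpha * pc["eps_N0"] + solid_frac)
            psi_t = eps_v * pc["C_H"]
        else:
            psi_t = psi
        dy = np.zeros_like(y)
        dy[0] = params.k_d * psi_t * chains[0]
        for i in range(1, N + 1):
            rate = 0.0
            if i == 1:
                rate -= params.k_d * psi_t * chains[0]
            elif i <= m:
                rate -= params.k_b * psi_t * chains[i - 1]
            else:
                rate -= params.k_a * psi_t * chains[i - 1]
            for j in range(i + 1, N + 1):
                k_j = params.k_b if j <= m else params.k_a
                rate += 2.0 * k_j * psi_t * omega(i, j) * chains[j - 1]
            dy[i] = rate
        return dy

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method="Radau",
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return {"t": sol.t, "furfural": sol.y[0], "chains": sol.y[1:]}


def scission_ssa(
    N_small: int,
    m_small: int,
    params: KineticParams,
    psi: float,
    t_grid: Sequence[float],
    n_chains: int = 100_000,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Event-driven stochastic simulation of random scission.

    ``n_chains`` chains of DP ``N_small`` evolve independently: every chain
    of DP j >= 2 breaks at rate k psi (k_a above the solubility cutoff, k_b
    at or below), the broken bond chosen uniformly among its j - 1 bonds;
    monomers degrade to furfural at rate k_d psi.  Returns mass
    concentrations on the same normalisation as :func:`scission_ode`
    (initial reactive mass = 1 - alpha; the unreactive fraction is never
    simulated).
    """
    if N_small < 2:
        raise ValueError("need N_small >= 2")
    if N_small > 6:
        raise ValueError("stochastic oracle supports N_small <= 6")
    N, m = N_small, m_small
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)

    n = np.zeros(N + 1, dtype=np.int64)  # n[j] = chains of DP j
    n[N] = n_chains
    n_furf = 0
    t = float(t_grid[0])
    out_chains = np.zeros((N, t_grid.size))
    out_furf = np.zeros(t_grid.size)
    next_out = 0

    def record_until(time):
        nonlocal next_out
        while next_out < t_grid.size and t_grid[next_out] <= time:
            for j in range(1, N + 1):
                out_chains[j - 1, next_out] = j * n[j]
            out_furf[next_out] = n_furf
            next_out += 1

    record_until(t)
    while next_out < t_grid.size:
        a_sol = params.k_a * psi * int(n[m + 1 : N + 1].sum()) if m < N else 0.0
        a_aq = params.k_b * psi * int(n[2 : min(m, N) + 1].sum())
        a_deg = params.k_d * psi * int(n[1])
        a_tot = a_sol + a_aq + a_deg
        if a_tot <= 0.0:
            break
        t += rng.exponential(1.0 / a_tot)
        record_until(t)
        u = rng.random() * a_tot
        if u < a_deg:
            n[1] -= 1
            n_furf += 1
            continue
        u -= a_deg
        if u < a_aq:
            lengths = list(range(2, min(m, N) + 1))
            rate = params.k_b
        else:
            u -= a_aq
            lengths = list(range(m + 1, N + 1))
            rate = params.k_a
        j = lengths[-1]
        for cand in lengths:
            u -= rate * psi * n[cand]
            if u < 0.0:
                j = cand
                break
        cut = 1 + rng.integers(j - 1)  # fragment lengths cut, j - cut
        n[j] -= 1
        n[cut] += 1
        n[j - cut] += 1
    record_until(np.inf)

    scale = (1.0 - params.alpha) / (N * n_chains)
    return {
        "t": t_grid,
        "furfural": out_furf * scale,
        "chains": out_chains * scale,
    }


def scission_oracle(
    N_small: int,
    m_small: int,
    params: KineticParams,
    psi: float,
    t_grid: Sequence[float],
    n_chains: int = 100_000,
    seed: int = 0,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Both independent well-mixed solutions (longhand ODE, stochastic SSA)
    for a small chain system; ``N_small`` must be <= 6."""
    if N_small > 6:
        raise ValueError("oracle supports N_small <= 6")
    ode = scission_ode(N_small, m_small, params, psi, t_grid)
    ssa = scission_ssa(
        N_small, m_small, params, psi, t_grid, n_chains=n_chains, seed=seed
    )
    return ode, ssa
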