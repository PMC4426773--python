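"""Calibration of rate constants and the hard-to-hydrolyse fraction.

The kinetic parameters (k_a, k_b, k_d, optionally alpha, optionally the bulk
diffusivities) are estimated by bounded least squares against experimental
yield-versus-time observations, all species weighted equally.  The optimiser
is a trust-region-reflective Gauss-Newton (scipy ``least_squares``), driven
through an outer loop so the classic parameter-estimation stopping rule can
be applied literally: stop after ``max_iter`` outer iterations or when the
relative improvement of the objective Phi over the last ``n_phi_stop``
iterations falls below ``phi_red_stop``.  Finite-difference sensitivities use
a relative increment of 0.01 with a per-parameter absolute floor.

Temperature laws are fitted in closed form: Arrhenius constants by ordinary
least squares of ln k against 1/T, and the exponential alpha(T) law by least
squares of ln alpha against T (the spreadsheet "exponential trendline"
convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constants import GAS_CONSTANT, SECONDS_PER_MINUTE
from .model_core import (
    AlphaLaw,
    ArrheniusFit,
    Conditions,
    KineticParams,
    MaterialGeometry,
    YieldSeries,
    alpha_of_T,
    arrhenius_rate,
)
from .transport_solver import simulate, yields

__all__ = [
    "FitResult",
    "Observation",
    "model_at_times",
    "objective",
    "fit",
    "arrhenius_regression",
    "alpha_regression",
    "predict_at_temperature",
    "FREE_PARAMETERS",
    "DEFAULT_BOUNDS",
]

#: Parameters that may be freed in a fit.  ``d_scale`` multiplies the
#: Stokes-Einstein chain diffusivities (fitting the bulk chain diffusivity);
#: ``D_F_inf`` is the furfural bulk diffusivity itself.
FREE_PARAMETERS = ("k_a", "k_b", "k_d", "alpha", "d_scale", "D_F_inf")

#: Default box bounds preventing non-physical values.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k_a": (0.0, 1.0),
    "k_b": (0.0, 1.0),
    "k_d": (0.0, 1.0),
    "alpha": (0.0, 0.9),
    "d_scale": (1e-3, 1e3),
    "D_F_inf": (1e-12, 1e-7),
}

#: Observation triple: (species label, time in minutes, yield in %).
Observation = Tuple[str, float, float]


@dataclass
class FitResult:
    """Outcome of a calibration run.

    ``Phi`` is the sum of squared residuals (yield-%^2) and always equals
    ``residuals @ residuals`` for the returned parameters.
    """

    params: KineticParams
    d_scale: float
    D_F_inf: float
    Phi: float
    residuals: np.ndarray
    observations: list
    n_iter: int
    converged: bool
    message: str
    phi_history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": {
                "k_a": self.params.k_a,
                "k_b": self.params.k_b,
                "k_d": self.params.k_d,
                "alpha": self.params.alpha,
            },
            "d_scale": self.d_scale,
            "D_F_inf": self.D_F_inf,
            "Phi": self.Phi,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "message": self.message,
            "phi_history": list(self.phi_history),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# forward model evaluation
# ---------------------------------------------------------------------------


def model_at_times(
    params: KineticParams,
    cond: Conditions,
    geom: MaterialGeometry,
    times_min: Sequence[float],
    *,
    d_scale: float = 1.0,
    include_solid: bool = False,
    **solver_options,
) -> YieldSeries:
    """Simulate and interpolate model yields to the requested times (minutes).

    The simulation is evaluated on ``cond.output_times`` and each species
    curve is interpolated with a cubic spline.  Times outside the simulated
    horizon raise ``ValueError`` (no extrapolation).
    """
    times_min = np.asarray(times_min, dtype=float)
    times_s = times_min * SECONDS_PER_MINUTE
    if np.any(times_s < -1e-9) or np.any(times_s > cond.t_end * (1 + 1e-12)):
        raise ValueError("requested times fall outside the simulated horizon")
    traj = simulate(geom, cond, params, d_scale=d_scale, **solver_options)
    series = yields(traj, geom, params, include_solid=include_solid)
    grid_min = series.times_min
    out = {}
    for label, values in series.yields.items():
        spline = CubicSpline(grid_min, values)
        out[label] = spline(times_min)
    return YieldSeries(times_min, out)


def objective(
    params: KineticParams,
    experiments: Iterable[Observation],
    cond: Conditions,
    geom: MaterialGeometry,
    *,
    d_scale: float = 1.0,
    **solver_options,
) -> np.ndarray:
    """Equal-weight residual vector (model - observed), one entry per
    observation.  Phi is the sum of its squared entries."""
    obs = list(experiments)
    known = {"furfural"} | {f"X{i}" for i in range(1, geom.m + 1)}
    for species, _, _ in obs:
        if species not in known:
            raise ValueError(f"unknown species label {species!r}")
    all_times = sorted({t for _, t, _ in obs})
    series = model_at_times(
        params, cond, geom, all_times, d_scale=d_scale, **solver_options
    )
    index = {t: k for k, t in enumerate(series.times_min)}
    return np.array(
        [series.yields[s][index[t]] - y for s, t, y in obs], dtype=float
    )


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------


def _pack(start: Dict[str, float], free: Sequence[str]) -> np.ndarray:
    return np.array([start[name] for name in free], dtype=float)


def _assemble(
    x: np.ndarray, free: Sequence[str], fixed: Dict[str, float]
) -> Tuple[KineticParams, float, float]:
    values = dict(fixed)
    values.update(dict(zip(free, x)))
    params = KineticParams(
        k_a=values["k_a"],
        k_b=values["k_b"],
        k_d=values["k_d"],
        alpha=values["alpha"],
    )
    return params, values["d_scale"], values["D_F_inf"]


def fit(
    experiments: Iterable[Observation],
    cond: Conditions,
    geom: MaterialGeometry,
    free: Sequence[str] = ("k_a", "k_b", "k_d", "alpha"),
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    start: Optional[Dict[str, float]] = None,
    *,
    fixed: Optional[Dict[str, float]] = None,
    max_iter: int = 30,
    phi_red_stop: float = 0.005,
    n_phi_stop: int = 4,
    diff_step: float = 0.01,
    n_starts: int = 1,
    seed: int = 0,
    **solver_options,
) -> FitResult:
    """Bounded least-squares calibration of the kinetic parameters.

    Parameters
    ----------
    experiments : iterable of (species, time_min, yield_pct)
        Observations; all weighted equally.
    free : sequence of str
        Subset of :data:`FREE_PARAMETERS` to vary.  The three standard
        regimes are ``("k_a","k_b","k_d")`` with alpha fixed at 0,
        ``("k_a","k_b","k_d","alpha")``, and
        ``("k_a","k_b","k_d","d_scale","D_F_inf")``.
    bounds, start, fixed : dict
        Per-parameter overrides; defaults are :data:`DEFAULT_BOUNDS`,
        mid-magnitude starting guesses and alpha = 0 / d_scale = 1 /
        literature furfural diffusivity for whatever is not freed.
    max_iter, phi_red_stop, n_phi_stop
        Stopping rule: at most ``max_iter`` Gauss-Newton iterations, early
        stop when the relative Phi improvement over the last ``n_phi_stop``
        iterations drops below ``phi_red_stop``.
    diff_step : float
        Relative finite-difference increment for the sensitivities.
    n_starts : int
        Optional Latin-hypercube multi-start count (> 1 guards against
        local minima); the best Phi wins.  Seeded by ``seed``.

    Returns
    -------
    FitResult
        Best parameters found; ``converged`` is False when the iteration
        budget was exhausted while Phi was still improving.
    """
    obs = list(experiments)
    if not obs:
        raise ValueError("no observations supplied")
    for name in free:
        if name not in FREE_PARAMETERS:
            raise ValueError(f"unknown free parameter {name!r}")

    all_bounds = dict(DEFAULT_BOUNDS)
    if bounds:
        all_bounds.update(bounds)
    base_fixed = {
        "k_a": 1e-4,
        "k_b": 1e-5,
        "k_d": 1e-8,
        "alpha": 0.0,
        "d_scale": 1.0,
        "D_F_inf": geom.D_F_inf,
    }
    if fixed:
        base_fixed.update(fixed)
    default_start = dict(base_fixed)
    default_start["alpha"] = 0.1 if "alpha" in free else base_fixed["alpha"]
    if start:
        default_start.update(start)

    lo = np.array([all_bounds[name][0] for name in free])
    hi = np.array([all_bounds[name][1] for name in free])
    x0 = np.clip(_pack(default_start, free), lo, hi)

    def residual(x):
        params, d_scale, D_F = _assemble(x, free, base_fixed)
        geom_x = geom if D_F == geom.D_F_inf else replace(geom, D_F_inf=D_F)
        return objective(
            params, obs, cond, geom_x, d_scale=d_scale, **solver_options
        )

    starts = [x0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        extra = qmc.scale(sampler.random(n_starts - 1), lo, hi)
        starts.extend(list(extra))

    best = None
    for x_start in starts:
        result = _fit_single(
            residual,
            x_start,
            lo,
            hi,
            max_iter=max_iter,
            phi_red_stop=phi_red_stop,
            n_phi_stop=n_phi_stop,
            diff_step=diff_step,
        )
        if best is None or result[1] < best[1]:
            best = result

    x_best, phi, res_vec, n_iter, converged, message, history = best
    params, d_scale, D_F = _assemble(x_best, free, base_fixed)
    return FitResult(
        params=params,
        d_scale=d_scale,
        D_F_inf=D_F,
        Phi=phi,
        residuals=res_vec,
        observations=obs,
        n_iter=n_iter,
        converged=converged,
        message=message,
        phi_history=history,
    )


def _fit_single(
    residual,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    *,
    max_iter: int,
    phi_red_stop: float,
    n_phi_stop: int,
    diff_step: float,
):
    """One optimisation run: outer Gauss-Newton iterations with the
    Phi-improvement stopping rule."""
    x = x0.copy()
    res_vec = residual(x)
    phi = float(res_vec @ res_vec)
    history = [phi]
    converged = False
    message = "iteration budget exhausted"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ls = least_squares(
            residual,
            x,
            bounds=(lo, hi),
            method="trf",
            diff_step=diff_step,
            x_scale=np.maximum(np.abs(x), 1e-12),
            max_nfev=len(x) + 2,
            ftol=1e-12,
            xtol=1e-14,
            gtol=1e-14,
        )
        new_phi = float(2.0 * ls.cost)
        if new_phi < phi:
            x, phi, res_vec = ls.x, new_phi, ls.fun
        history.append(phi)
        if phi <= 1e-12 * max(1.0, history[0]):
            converged = True
            message = "Phi reduced to numerical zero"
            break
        if len(history) > n_phi_stop:
            ref = history[-1 - n_phi_stop]
            if ref > 0 and (ref - history[-1]) / ref < phi_red_stop:
                converged = True
                message = (
                    f"relative Phi improvement below {phi_red_stop} over "
                    f"{n_phi_stop} iterations"
                )
                break
    return x, phi, res_vec, n_iter, converged, message, history


# ---------------------------------------------------------------------------
# temperature laws
# ---------------------------------------------------------------------------


def arrhenius_regression(T_list: Sequence[float], k_list: Sequence[float]) -> ArrheniusFit:
    """Closed-form Arrhenius fit: OLS of ln k on 1/T.

    Returns the pre-exponential factor ``k0 = exp(intercept)`` and
    activation energy ``Ea = -slope * R``.
    """
    T = np.asarray(T_list, dtype=float)
    k = np.asarray(k_list, dtype=float)
    if T.size < 2 or T.size != k.size:
        raise ValueError("need matching T and k arrays with >= 2 entries")
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and rate constants must be positive")
    slope, intercept = np.polyfit(1.0 / T, np.log(k), 1)
    return ArrheniusFit(k0=float(np.exp(intercept)), Ea=float(-slope * GAS_CONSTANT))


def alpha_regression(T_list: Sequence[float], alpha_list: Sequence[float]) -> AlphaLaw:
    """Closed-form exponential fit alpha(T) = A exp(-b T): OLS of ln alpha on T."""
    T = np.asarray(T_list, dtype=float)
    a = np.asarray(alpha_list, dtype=float)
    if T.size < 2 or T.size != a.size:
        raise ValueError("need matching T and alpha arrays with >= 2 entries")
    if np.any(a <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and alpha values must be positive")
    slope, intercept = np.polyfit(T, np.log(a), 1)
    return AlphaLaw(A=float(np.exp(intercept)), b=float(-slope))


def params_from_laws(
    arrhenius_fits: Dict[str, ArrheniusFit],
    alpha_law: AlphaLaw,
    T: float,
) -> KineticParams:
    """Assemble KineticParams at temperature T from the fitted laws."""
    return KineticParams(
        k_a=arrhenius_rate(arrhenius_fits["k_a"], T),
        k_b=arrhenius_rate(arrhenius_fits["k_b"], T),
        k_d=arrhenius_rate(arrhenius_fits["k_d"], T),
        alpha=alpha_of_T(alpha_law, T),
    )


def predict_at_temperature(
    arrhenius_fits: Dict[str, ArrheniusFit],
    alpha_law: AlphaLaw,
    T: float,
    cond: Conditions,
    geom: MaterialGeometry,
    *,
    T_min_valid: float = 383.15,
    include_solid: bool = False,
    **solver_options,
) -> Tuple[KineticParams, YieldSeries]:
    """Pure prediction at an uncalibrated temperature: parameters come from
    the temperature laws, then one forward simulation -- no fitting.

    ``T_min_valid`` guards the validity window of the exponential alpha law,
    which diverges at low temperature.
    """
    if T < T_min_valid:
        raise ValueError(
            f"T = {T:.2f} K is below the validity window of the alpha(T) "
            f"law (>= {T_min_valid:.2f} K); the exponential form is not "
            "meaningful at lower temperatures"
        )
    params = params_from_laws(arrhenius_fits, alpha_law, T)
    cond_T = replace(cond, T=T)
    traj = simulate(geom, cond_T, params, **solver_options)
    return params, yields(traj, geom, params, include_solid=include_solid)
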