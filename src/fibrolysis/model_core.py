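"""Domain types and pointwise material laws for fibre-scale xylan hydrolysis.

The model tracks mass concentrations of xylan chains of every degree of
polymerisation (DP) 1..N inside an idealised cylindrical lignocellulose fibre
and in the surrounding hydrolysate.  Chains longer than the solubility cutoff
``m`` are solid and confined to the fibre; chains of DP <= m plus furfural are
aqueous and diffuse.  Scission is catalysed by the effective acid
concentration, which is the bulk acid concentration scaled by the local pore
volume fraction (porosity).  This module holds the building blocks evaluated
pointwise: the random-scission breakage kernel, Arrhenius rates, the
hard-to-hydrolyse fraction alpha(T), Stokes-Einstein diffusivities with a
porosity-cubed tortuosity factor, and the porosity closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .constants import (
    BOLTZMANN,
    D_FURFURAL_INF,
    GAS_CONSTANT,
    HYDRODYNAMIC_PREFACTOR,
)

__all__ = [
    "MaterialGeometry",
    "Conditions",
    "KineticParams",
    "ArrheniusFit",
    "AlphaLaw",
    "StateField",
    "YieldSeries",
    "breakage_kernel",
    "arrhenius_rate",
    "alpha_of_T",
    "effective_acid",
    "water_viscosity",
    "bulk_diffusivity",
    "diffusivity",
    "porosity",
    "initial_state",
    "FURFURAL",
]

#: Sentinel chain-length tag selecting furfural in diffusivity lookups.
FURFURAL = "furfural"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialGeometry:
    """Composition, chain-length limits and radial geometry of one fibre.

    Defaults are the standard sugarcane-bagasse parameter set used throughout
    this package.

    Parameters
    ----------
    F_hat : float
        Fixed (non-reacting) lignocellulose volume fraction of the fibre.
    eps_N0 : float
        Initial total hemicellulose (xylan) volume fraction.
    rho_s : float
        Density of solid xylan (kg m^-3).  Yields are invariant to this
        value; it only enters the porosity feedback.
    N : int
        Maximum chain length (DP) tracked.
    m : int
        Solubility cutoff: chains of DP <= m are aqueous.
    l : float
        Monomer segment length (m), used for hydrodynamic radii.
    R_i : float
        Fibre radius (m).
    hydrolysate_factor : float
        Radial extent of the hydrolysate annulus relative to the fibre
        radius, (R_o - R_i) / R_i.
    n_fibre, n_hydro : int
        Number of uniformly spaced nodes in each region.
    D_F_inf : float
        Bulk diffusivity of furfural (m^2 s^-1).
    """

    F_hat: float = 0.581
    eps_N0: float = 0.165
    rho_s: float = 1500.0
    N: int = 100
    m: int = 15
    l: float = 0.65e-9
    R_i: float = 3.75e-4
    hydrolysate_factor: float = 2.32
    n_fibre: int = 100
    n_hydro: int = 250
    D_F_inf: float = D_FURFURAL_INF

    def __post_init__(self) -> None:
        if not 0.0 < self.F_hat + self.eps_N0 < 1.0:
            raise ValueError("F_hat + eps_N0 must lie in (0, 1)")
        if not 1 < self.m < self.N:
            raise ValueError("need 1 < m < N")
        if self.R_i <= 0 or self.hydrolysate_factor <= 0:
            raise ValueError("R_i and hydrolysate_factor must be positive")
        if self.rho_s <= 0 or self.l <= 0 or self.D_F_inf <= 0:
            raise ValueError("rho_s, l and D_F_inf must be positive")
        if self.n_fibre < 3 or self.n_hydro < 3:
            raise ValueError("each region needs at least 3 nodes")

    @property
    def R_o(self) -> float:
        """Outer radius of the hydrolysate annulus (m)."""
        return self.R_i * (1.0 + self.hydrolysate_factor)

    @property
    def initial_porosity(self) -> float:
        """Fibre porosity before any xylan has dissolved (independent of alpha)."""
        return 1.0 - (self.F_hat + self.eps_N0)


@dataclass(frozen=True)
class Conditions:
    """Operating conditions of one hydrolysis run.

    Attributes
    ----------
    T : float
        Temperature (K); the domain is isothermal.
    C_H : float
        Bulk hydronium concentration (mol m^-3).
    t_end : float
        Simulation horizon (s).
    output_times : ndarray
        Strictly increasing times (s) within [0, t_end] at which the state
        is reported.
    """

    T: float
    C_H: float = 51.0
    t_end: float = 360.0 * 60.0
    output_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.C_H < 0:
            raise ValueError("acid concentration must be non-negative")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        times = self.output_times
        if times is None:
            times = np.linspace(0.0, self.t_end, 121)
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("output_times must be a 1-D array of >= 2 times")
        if np.any(np.diff(times) <= 0):
            raise ValueError("output_times must be strictly increasing")
        if times[0] < 0 or times[-1] > self.t_end + 1e-9:
            raise ValueError("output_times must lie within [0, t_end]")
        object.__setattr__(self, "output_times", times)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and hard-to-hydrolyse fraction at one temperature.

    ``k_a``/``k_b`` are the scission rates of solid/aqueous chains and
    ``k_d`` the xylose-to-furfural degradation rate, all in m^3 mol^-1 s^-1.
    ``alpha`` is the unreactive (hard-to-hydrolyse) mass fraction of the
    initial xylan.
    """

    k_a: float
    k_b: float
    k_d: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_a, self.k_b, self.k_d) < 0:
            raise ValueError("rate constants must be non-negative")
        # alpha = 1 (fully unreactive) is allowed as a degenerate limit
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius law k(T) = k0 * exp(-Ea / (R T))."""

    k0: float
    Ea: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("pre-exponential factor must be positive")
        if self.Ea < 0:
            raise ValueError("activation energy must be non-negative")


@dataclass(frozen=True)
class AlphaLaw:
    """Exponential temperature law alpha(T) = A * exp(-b T), T in Kelvin."""

    A: float
    b: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.b <= 0:
            raise ValueError("A and b must be positive")


@dataclass
class StateField:
    """Concentration state on the radial grid.

    ``furfural`` has shape (n_total,), ``aqueous`` has shape (m, n_total)
    with row i-1 holding chains of DP i, and ``solid`` has shape
    (N - m, n_fibre) with row q holding DP m+1+q.  All entries are
    volume-averaged mass concentrations (kg m^-3).  Porosity is not stored:
    it follows algebraically from the solid concentrations via
    :func:`porosity`.
    """

    furfural: np.ndarray
    aqueous: np.ndarray
    solid: np.ndarray

    @property
    def n_total(self) -> int:
        return self.furfural.shape[0]

    @property
    def n_fibre(self) -> int:
        return self.solid.shape[1]

    @property
    def m(self) -> int:
        return self.aqueous.shape[0]

    @property
    def N(self) -> int:
        return self.m + self.solid.shape[0]

    def copy(self) -> "StateField":
        return StateField(
            self.furfural.copy(), self.aqueous.copy(), self.solid.copy()
        )

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.furfural, self.aqueous.ravel(), self.solid.ravel()]
        )

    @classmethod
    def from_vector(
        cls, y: np.ndarray, m: int, N: int, n_total: int, n_fibre: int
    ) -> "StateField":
        n_diff = (m + 1) * n_total
        furfural = y[:n_total]
        aqueous = y[n_total:n_diff].reshape(m, n_total)
        solid = y[n_diff:].reshape(N - m, n_fibre)
        return cls(furfural, aqueous, solid)


@dataclass
class YieldSeries:
    """Yield-versus-time curves, in % of the initial xylan mass.

    ``times_min`` is in minutes (the reporting unit); ``yields`` maps a
    species label (``"furfural"``, ``"X1"`` .. ``"X<m>"``, optionally
    ``"solid"``) to an array of yields aligned with ``times_min``.
    """

    times_min: np.ndarray
    yields: dict

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.yields = {k: np.asarray(v, dtype=float) for k, v in self.yields.items()}
        for label, values in self.yields.items():
            if values.shape != self.times_min.shape:
                raise ValueError(f"yield series {label!r} misaligned with times")

    def species(self) -> list:
        return list(self.yields)

    def to_frame(self):
        """Tidy DataFrame with columns time_min, species, yield_pct."""
        import pandas as pd

        rows = []
        for label, values in self.yields.items():
            for t, y in zip(self.times_min, values):
                rows.append((t, label, y))
        return pd.DataFrame(rows, columns=["time_min", "species", "yield_pct"])


# ---------------------------------------------------------------------------
# pointwise laws
# ---------------------------------------------------------------------------


def breakage_kernel(i, j):
    """Random-scission breakage kernel Omega(i, j - i) on mass concentrations.

    Weight with which scission of a parent chain of DP ``j`` produces a
    fragment of DP ``i``::

        Omega(i, j - i) = i / (j * (j - 1))

    This is the unique mass-based random-scission closure for which the gain
    term ``2 k psi sum_j Omega phi_j`` exactly balances the loss term
    ``-k psi phi_j``: for every j >= 2, ``sum_{i<j} 2 Omega(i, j-i) == 1``.

    Accepts scalars or broadcastable integer arrays; every pair must satisfy
    ``1 <= i < j``.
    """
    i_arr = np.asarray(i)
    j_arr = np.asarray(j)
    if np.any(i_arr < 1) or np.any(i_arr >= j_arr):
        raise ValueError("breakage kernel requires 1 <= i < j")
    out = i_arr / (j_arr * (j_arr - 1.0))
    return out.item() if np.isscalar(i) and np.isscalar(j) else out


def arrhenius_rate(fit: ArrheniusFit, T: float):
    """Evaluate k(T) = k0 exp(-Ea / (R T)); T in Kelvin."""
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ValueError("temperature must be positive (K)")
    out = fit.k0 * np.exp(-fit.Ea / (GAS_CONSTANT * T_arr))
    return out.item() if np.isscalar(T) else out


def alpha_of_T(law: AlphaLaw, T: float) -> float:
    """Hard-to-hydrolyse fraction alpha(T) = A exp(-b T).

    Raises
    ------
    ValueError
        If T <= 0, or if the law evaluates to >= 1, which signals a
        temperature below the regression's validity window (the exponential
        form grows without bound as T decreases and is not meaningful there).
    """
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    value = law.A * np.exp(-law.b * T)
    if value >= 1.0:
        raise ValueError(
            f"alpha(T) = {value:.3g} >= 1 at T = {T:.2f} K: temperature is "
            "below the validity window of the exponential alpha law"
        )
    return float(max(value, 0.0))


def effective_acid(eps_v, C_H):
    """Effective (pore-scaled) acid concentration psi = eps_v * C_H.

    Hydrolysate nodes have ``eps_v = 1`` so psi equals the bulk value there.
    """
    eps_arr = np.asarray(eps_v, dtype=float)
    if np.any(eps_arr < 0) or np.any(eps_arr > 1):
        raise ValueError("porosity must lie in [0, 1]")
    out = eps_arr * C_H
    return out.item() if np.isscalar(eps_v) else out


def water_viscosity(T: float):
    """Dynamic viscosity of liquid water (kg m^-1 s^-1), Vogel-type correlation.

    eta(T) = 2.414e-5 * 10^(247.8 / (T - 140)).  The 0.5 wt% acid solution is
    treated as water.  Any callable with this signature can be substituted
    wherever a ``viscosity`` argument is accepted.
    """
    return 2.414e-5 * 10.0 ** (247.8 / (np.asarray(T, dtype=float) - 140.0))


def hydrodynamic_radius(i, l: float):
    """Hydrodynamic radius R_h(i) = 0.676 l sqrt(i) of a DP-i chain (m)."""
    return HYDRODYNAMIC_PREFACTOR * l * np.sqrt(np.asarray(i, dtype=float))


def bulk_diffusivity(
    i,
    T: float,
    *,
    l: float = 0.65e-9,
    D_F_inf: float = D_FURFURAL_INF,
    viscosity: Callable = water_viscosity,
):
    """Bulk (free-solution) diffusivity D_inf (m^2 s^-1).

    Chains use the Stokes-Einstein relation ``k_B T / (6 pi eta R_h(i))``;
    furfural (``i == FURFURAL``) uses the fixed literature value ``D_F_inf``.
    """
    if isinstance(i, str):
        if i != FURFURAL:
            raise ValueError(f"unknown species tag {i!r}")
        return D_F_inf
    i_arr = np.asarray(i)
    if np.any(i_arr < 1):
        raise ValueError("chain length must be >= 1")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    out = BOLTZMANN * T / (6.0 * np.pi * viscosity(T) * hydrodynamic_radius(i_arr, l))
    return out.item() if np.isscalar(i) else out


def diffusivity(
    i,
    T: float,
    eps_v,
    *,
    l: float = 0.65e-9,
    D_F_inf: float = D_FURFURAL_INF,
    viscosity: Callable = water_viscosity,
):
    """Effective diffusivity D_eff = eps_v^3 * D_inf(i) (m^2 s^-1).

    The cubic porosity factor models the tortuosity of the fibre interior;
    in the hydrolysate eps_v = 1 and D_eff reduces to the bulk value.
    """
    eps_arr = np.asarray(eps_v, dtype=float)
    if np.any(eps_arr < 0) or np.any(eps_arr > 1):
        raise ValueError("porosity must lie in [0, 1]")
    d_inf = bulk_diffusivity(i, T, l=l, D_F_inf=D_F_inf, viscosity=viscosity)
    out = eps_arr**3 * d_inf
    if np.isscalar(eps_v) and (isinstance(i, str) or np.isscalar(i)):
        return float(out)
    return out


def porosity(solid_phi, geom: MaterialGeometry, alpha: float, fibre_fraction=1.0):
    """Pore volume fraction of fibre material from the solid-chain state.

    Volume bookkeeping: the void fraction is what remains after the fixed
    lignocellulose fraction ``F_hat``, the unreactive xylan fraction
    ``eps_alpha = alpha * eps_N0`` and the remaining reactive solid chains
    (volume fraction ``phi_i / rho_s`` each) are subtracted::

        eps_v = 1 - (F_hat + sum_i phi_i / rho_s + eps_alpha)

    ``solid_phi`` may be (n_species,) for one node or (n_species, n_nodes).
    ``fibre_fraction`` scales the fixed fractions for control volumes that
    are only partially fibre material (the shared interface vertex); interior
    nodes use 1.
    """
    solid_phi = np.asarray(solid_phi, dtype=float)
    if np.any(solid_phi < -1e-12 * geom.eps_N0 * geom.rho_s):
        raise ValueError("solid concentrations must be non-negative")
    total = np.clip(solid_phi, 0.0, None).sum(axis=0)
    eps_v = 1.0 - (
        np.asarray(fibre_fraction) * (geom.F_hat + alpha * geom.eps_N0)
        + total / geom.rho_s
    )
    if np.any(eps_v <= 0.0):
        raise ValueError("porosity closure produced eps_v <= 0 (invalid state)")
    return float(eps_v) if np.ndim(eps_v) == 0 else eps_v


def initial_state(
    geom: MaterialGeometry,
    cond: Conditions,
    params: KineticParams,
    fibre_fraction=None,
) -> StateField:
    """Initially monodisperse state: all reactive xylan as chains of DP N.

    The reactive solid concentration on fibre nodes is
    ``(1 - alpha) * eps_N0 * rho_s``; every other species is zero everywhere.
    ``fibre_fraction`` (length n_fibre) scales the interface vertex so the
    discrete initial mass matches the continuum fibre exactly; ``None`` means
    uniform.
    """
    n_total = geom.n_fibre + geom.n_hydro
    furfural = np.zeros(n_total)
    aqueous = np.zeros((geom.m, n_total))
    solid = np.zeros((geom.N - geom.m, geom.n_fibre))
    phi_N0 = (1.0 - params.alpha) * geom.eps_N0 * geom.rho_s
    if fibre_fraction is None:
        solid[-1, :] = phi_N0
    else:
        solid[-1, :] = phi_N0 * np.asarray(fibre_fraction, dtype=float)
    return StateField(furfural, aqueous, solid)
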