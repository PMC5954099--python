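"""Flat-plate soft-layer electrokinetics for polymer-grafted cells.

The cell surface is modelled as a charged, hydrodynamically penetrable layer
(the glycocalyx) of thickness ``beta`` anchored to an impermeable membrane at
``z = 0``.  Within the layer, polymer segments of Stokes radius ``a`` at
number density ``n(z)`` exert a Brinkman volume drag ``f(z) = 6*pi*eta*a*n(z)``
on the electroosmotic flow, and a fixed charge density ``rho_fix(z)``
(the sialic-acid charge of the native glycocalyx) sources the electrostatic
potential.  Grafted polymer adds friction over a prescribed depth interval —
either throughout the layer ("uniform" scenario) or restricted to its outer
region ("outer" scenario) — without adding charge (polyglycerol is a neutral
polyol).

Because both the Debye length (~0.8 nm in physiological saline) and the layer
thickness (7.8 nm for the red-cell glycocalyx) are orders of magnitude smaller
than the cell radius, curvature is neglected and the problem is solved on a
one-dimensional half-line normal to the membrane:

* potential:   ``psi'' = kappa^2 psi - rho_fix(z)/(eps)``,
  with ``psi'(0) = -sigma_mem/eps`` and ``psi(L) = 0``;
* flow:        ``eta u'' - f(z) u = -rho_e(z)`` at unit applied field,
  with ``rho_e = -eps kappa^2 psi``, ``u(0) = 0`` and ``u'(L) = 0``.

Sign convention (cell frame): the far-field electroosmotic velocity is
``-mu E``, so the electrophoretic mobility is ``mu = -u(L)`` and a negatively
charged layer yields ``mu < 0``.  Both two-point boundary-value problems are
linear and are solved by second-order finite differences with a banded direct
solve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import constants
from scipy.linalg import solve_banded
from scipy.optimize import least_squares

from .errors import InvalidParameterError, SolverError, UnderDeterminedError

EPS0 = constants.epsilon_0

#: External mobility unit used in CSV files: um s^-1 per V cm^-1 == 1e-8 m^2/(V s).
MOBILITY_EXTERNAL_UNIT = 1e-8

#: Default lower bound of the outer grafting interval (m).
OUTER_Z_LO_DEFAULT = 2.7e-9

#: Red-cell membrane surface area used to convert molecules/cell to a surface
#: density (m^2).
RBC_AREA_DEFAULT = 1.4e-10

SCENARIOS = ("uniform", "outer")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Electrolyte:
    """A symmetric 1:1 electrolyte bathing the cell.

    Defaults correspond to 0.145 mol/L saline at 25 C, the suspension medium
    used for red-cell electrophoresis.
    """

    ionic_strength: float = 0.145       # mol/L
    temperature: float = 298.15         # K
    viscosity: float = 8.9e-4           # Pa s
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        for name in ("ionic_strength", "temperature", "viscosity",
                     "relative_permittivity"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"Electrolyte.{name} must be strictly positive")

    @property
    def permittivity(self) -> float:
        """Absolute permittivity eps_r * eps_0 (F/m)."""
        return self.relative_permittivity * EPS0

    @property
    def kappa(self) -> float:
        """Debye screening parameter (1/m), recomputed on access."""
        return debye_parameter(self)


@dataclass(frozen=True)
class GlycocalyxModel:
    """The native charged, penetrable surface layer.

    ``segment_surface_density`` counts native glycocalyx elements per m^2 of
    membrane; they are spread uniformly through the layer thickness.  The
    total fixed charge ``total_surface_charge`` (C/m^2, negative for sialic
    acid) is likewise distributed uniformly over ``[0, beta]``.
    """

    thickness_beta: float = 7.8e-9          # m
    segment_radius_a: float = 0.6e-9        # m, Stokes radius of a native segment
    segment_surface_density: float = 1.4e17  # segments / m^2
    total_surface_charge: float = -0.0138   # C / m^2
    membrane_surface_charge: float = 0.0    # C / m^2

    def __post_init__(self) -> None:
        if not self.thickness_beta > 0:
            raise InvalidParameterError("thickness_beta must be > 0")
        if not self.segment_radius_a > 0:
            raise InvalidParameterError("segment_radius_a must be > 0")
        if self.segment_surface_density < 0:
            raise InvalidParameterError("segment_surface_density must be >= 0")


@dataclass(frozen=True)
class GraftDistribution:
    """Grafted polymer molecules and the depth interval they occupy.

    ``z_lo``/``z_hi`` are measured from the membrane; segments are spread
    uniformly over ``[z_lo, z_hi]``.  Grafts carry no charge.
    """

    molecules_per_cell: float
    z_lo: float                               # m
    z_hi: float                               # m
    graft_segment_radius: float               # m
    cell_area: float = RBC_AREA_DEFAULT       # m^2
    segments_per_molecule: float = 1.0

    def __post_init__(self) -> None:
        if self.molecules_per_cell < 0:
            raise InvalidParameterError("molecules_per_cell must be >= 0")
        if not (0.0 <= self.z_lo < self.z_hi):
            raise InvalidParameterError("require 0 <= z_lo < z_hi")
        if not self.graft_segment_radius > 0:
            raise InvalidParameterError("graft_segment_radius must be > 0")
        if not self.cell_area > 0:
            raise InvalidParameterError("cell_area must be > 0")

    @property
    def surface_density(self) -> float:
        """Grafted molecules per m^2 of membrane (derived, never stored)."""
        return self.molecules_per_cell / self.cell_area


@dataclass(frozen=True)
class LayerProfile:
    """Discretized friction and fixed-charge profiles on a uniform grid.

    Node values are cell averages (node ``k`` owns ``[z_k - dz/2, z_k + dz/2]``
    clipped to the domain), so the trapezoid rule integrates them exactly.
    """

    grid: np.ndarray                 # m, ascending from 0
    friction: np.ndarray             # kg/(m^3 s) per node
    fixed_charge: np.ndarray         # C/m^3 per node
    thickness_beta: float            # m, for bookkeeping/validation
    membrane_surface_charge: float = 0.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or grid[0] != 0.0:
            raise InvalidParameterError("grid must be 1-D and start at 0")
        if np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("grid must be strictly ascending")
        if np.any(np.asarray(self.friction) < 0):
            raise InvalidParameterError("friction must be non-negative")

    @property
    def dz(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def length(self) -> float:
        return float(self.grid[-1])

    def total_fixed_charge(self) -> float:
        """Integral of the fixed charge density over the domain (C/m^2)."""
        return float(np.trapezoid(self.fixed_charge, self.grid))


@dataclass(frozen=True)
class MobilitySolution:
    """Solution bundle of one mobility solve."""

    mobility: float                  # m^2/(V s)
    grid: np.ndarray                 # m
    potential_profile: np.ndarray    # V
    velocity_profile: np.ndarray     # m^2/(V s) at unit field, cell frame
    converged: bool
    residual_norm: float

    @property
    def mobility_external(self) -> float:
        """Mobility in um s^-1 / (V cm^-1)."""
        return self.mobility / MOBILITY_EXTERNAL_UNIT


# --------------------------------------------------------------------------
# elementary relations
# --------------------------------------------------------------------------

def debye_parameter(electrolyte: Electrolyte) -> float:
    """Debye screening parameter kappa (1/m) for a 1:1 electrolyte.

    kappa = sqrt(2 e^2 N_A I*1000 / (eps k_B T)) with I in mol/L.
    """
    if not electrolyte.ionic_strength > 0 or not electrolyte.temperature > 0:
        raise InvalidParameterError(
            "ionic strength and temperature must be strictly positive")
    num = (2.0 * constants.e ** 2 * constants.N_A
           * electrolyte.ionic_strength * 1000.0)
    den = (electrolyte.permittivity * constants.k * electrolyte.temperature)
    return math.sqrt(num / den)


def hpg_stokes_radius(molar_mass: float, prefactor: float = 4.6e-11) -> float:
    """Effective Stokes radius (m) of a hyperbranched polyglycerol graft.

    Compact branched polymers follow an R_h = c * M^0.4 scaling; the default
    prefactor places a 20 kDa graft near 2.4 nm.
    """
    if molar_mass <= 0:
        raise InvalidParameterError("molar_mass must be > 0")
    return prefactor * molar_mass ** 0.4


def _box_average(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Cell-averaged indicator of the interval [lo, hi] on a uniform grid.

    Returns, per node, the overlap of the node's cell with [lo, hi] divided
    by the cell width, so sums against cell widths integrate exactly.
    """
    dz = grid[1] - grid[0]
    cell_lo = np.maximum(grid - dz / 2.0, grid[0])
    cell_hi = np.minimum(grid + dz / 2.0, grid[-1])
    overlap = np.clip(np.minimum(cell_hi, hi) - np.maximum(cell_lo, lo),
                      0.0, None)
    return overlap / (cell_hi - cell_lo)


# --------------------------------------------------------------------------
# profile construction
# --------------------------------------------------------------------------

def build_profile(
    glx: GlycocalyxModel,
    graft: GraftDistribution | None = None,
    electrolyte: Electrolyte | None = None,
    L: float | None = None,
    n_nodes: int = 2000,
) -> LayerProfile:
    """Discretize a glycocalyx (plus optional graft) into layer profiles.

    Friction is ``6 pi eta a n(z)`` summed over native segments (uniform over
    ``[0, beta]``) and graft segments (uniform over ``[z_lo, z_hi]``); fixed
    charge is uniform over ``[0, beta]`` and integrates to
    ``total_surface_charge``.  Beyond ``beta`` both vanish.

    ``L`` defaults to ``beta + 10/kappa`` so the diffuse layer decays fully
    inside the domain.
    """
    electrolyte = electrolyte or Electrolyte()
    beta = glx.thickness_beta
    if L is None:
        L = beta + 10.0 / electrolyte.kappa
    if not L > beta:
        raise InvalidParameterError("domain length L must exceed thickness_beta")
    if n_nodes < 200:
        raise InvalidParameterError("n_nodes must be >= 200")
    if graft is not None and graft.z_hi > beta + 1e-15:
        raise InvalidParameterError(
            "graft interval must lie inside [0, thickness_beta]")

    grid = np.linspace(0.0, L, n_nodes)
    eta = electrolyte.viscosity

    native_density = glx.segment_surface_density / beta     # segments / m^3
    friction = (6.0 * math.pi * eta * glx.segment_radius_a * native_density
                * _box_average(grid, 0.0, beta))
    if graft is not None and graft.molecules_per_cell > 0:
        graft_density = (graft.surface_density * graft.segments_per_molecule
                         / (graft.z_hi - graft.z_lo))
        friction = friction + (
            6.0 * math.pi * eta * graft.graft_segment_radius * graft_density
            * _box_average(grid, graft.z_lo, graft.z_hi))

    fixed_charge = (glx.total_surface_charge / beta
                    * _box_average(grid, 0.0, beta))

    return LayerProfile(
        grid=grid,
        friction=friction,
        fixed_charge=fixed_charge,
        thickness_beta=beta,
        membrane_surface_charge=glx.membrane_surface_charge,
    )


# --------------------------------------------------------------------------
# boundary-value solvers
# --------------------------------------------------------------------------

def _solve_tridiag(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray,
                   rhs: np.ndarray) -> np.ndarray:
    n = diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, rhs)


def _residual_norm(lower, diag, upper, rhs, x) -> float:
    ax = diag * x
    ax[1:] += lower[1:] * x[:-1]
    ax[:-1] += upper[:-1] * x[1:]
    scale = max(float(np.max(np.abs(rhs))), 1e-300)
    return float(np.max(np.abs(ax - rhs)) / scale)


def solve_potential(
    profile: LayerProfile,
    electrolyte: Electrolyte,
    tol: float = 1e-8,
) -> np.ndarray:
    """Solve the linearized Poisson-Boltzmann problem for psi(z) (V).

    ``psi'' = kappa^2 psi - rho_fix/eps`` with ``psi'(0) = -sigma_mem/eps``
    and ``psi(L) = 0``.
    """
    psi, res = _solve_potential_with_residual(profile, electrolyte)
    if not np.all(np.isfinite(psi)) or res > tol:
        raise SolverError("potential solve failed", residual_norm=res)
    return psi


def _solve_potential_with_residual(profile, electrolyte):
    grid = profile.grid
    n = grid.size
    dz = profile.dz
    kappa = electrolyte.kappa
    eps = electrolyte.permittivity

    lower = np.full(n, 1.0 / dz ** 2)
    diag = np.full(n, -2.0 / dz ** 2 - kappa ** 2)
    upper = np.full(n, 1.0 / dz ** 2)
    rhs = -profile.fixed_charge / eps

    # Neumann at z=0 via ghost node: psi'(0) = -sigma_mem/eps
    g = -profile.membrane_surface_charge / eps
    upper[0] = 2.0 / dz ** 2
    rhs[0] = rhs[0] + 2.0 * g / dz
    # Dirichlet at z=L
    lower[-1] = 0.0
    diag[-1] = 1.0
    rhs[-1] = 0.0

    psi = _solve_tridiag(lower, diag, upper, rhs)
    res = _residual_norm(lower, diag, upper, rhs, psi)
    return psi, res


def solve_mobility(
    profile: LayerProfile,
    electrolyte: Electrolyte,
    tol: float = 1e-8,
) -> MobilitySolution:
    """Solve the Brinkman flow problem and return the mobility solution.

    ``eta u'' - f(z) u = -rho_e(z)`` at unit applied field with
    ``rho_e = -eps kappa^2 psi``, ``u(0) = 0`` and ``u'(L) = 0``;
    ``mu = -u(L)`` in the cell frame.
    """
    kappa = electrolyte.kappa
    if profile.length < profile.thickness_beta + 8.0 / kappa:
        raise InvalidParameterError(
            "domain too short: require L >= thickness_beta + 8/kappa")

    psi = solve_potential(profile, electrolyte, tol=tol)

    grid = profile.grid
    n = grid.size
    dz = profile.dz
    eta = electrolyte.viscosity
    eps = electrolyte.permittivity
    rho_e = -eps * kappa ** 2 * psi

    lower = np.full(n, eta / dz ** 2)
    diag = -2.0 * eta / dz ** 2 - profile.friction
    upper = np.full(n, eta / dz ** 2)
    rhs = -rho_e

    # Dirichlet u(0) = 0
    diag[0] = 1.0
    upper[0] = 0.0
    rhs[0] = 0.0
    # Neumann u'(L) = 0 via ghost node
    lower[-1] = 2.0 * eta / dz ** 2
    rhs[-1] = -rho_e[-1]

    u = _solve_tridiag(lower, diag, upper, rhs)
    res = _residual_norm(lower, diag, upper, rhs, u)
    converged = bool(np.all(np.isfinite(u)) and res <= tol)
    if not converged:
        raise SolverError("mobility solve failed", residual_norm=res)

    return MobilitySolution(
        mobility=float(-u[-1]),
        grid=grid,
        potential_profile=psi,
        velocity_profile=u,
        converged=converged,
        residual_norm=res,
    )


# --------------------------------------------------------------------------
# scenario curves and fitting
# --------------------------------------------------------------------------

def scenario_interval(scenario: str, beta: float,
                      outer_z_lo: float = OUTER_Z_LO_DEFAULT) -> tuple[float, float]:
    """Depth interval occupied by grafts under a named scenario."""
    if scenario == "uniform":
        return 0.0, beta
    if scenario == "outer":
        if not 0.0 < outer_z_lo < beta:
            raise InvalidParameterError("outer_z_lo must lie inside (0, beta)")
        return outer_z_lo, beta
    raise InvalidParameterError(f"unknown scenario {scenario!r}")


def mobility_curve(
    glx: GlycocalyxModel,
    electrolyte: Electrolyte,
    molecules_grid: Sequence[float],
    scenario: str,
    graft_segment_radius: float | None = None,
    outer_z_lo: float = OUTER_Z_LO_DEFAULT,
    cell_area: float = RBC_AREA_DEFAULT,
    segments_per_molecule: float = 1.0,
    n_nodes: int = 2000,
) -> pd.DataFrame:
    """Predicted mobility versus grafted molecules per cell for one scenario.

    Returns a DataFrame with columns ``molecules_per_cell`` and ``mobility``
    (SI units).
    """
    molecules = np.asarray(molecules_grid, dtype=float)
    if np.any(molecules < 0):
        raise InvalidParameterError("molecules_grid must be non-negative")
    if np.any(np.diff(molecules) < 0):
        raise InvalidParameterError("molecules_grid must be sorted ascending")
    if graft_segment_radius is None:
        graft_segment_radius = hpg_stokes_radius(20000.0)

    z_lo, z_hi = scenario_interval(scenario, glx.thickness_beta, outer_z_lo)
    mobilities = np.empty_like(molecules)
    for i, m in enumerate(molecules):
        graft = None
        if m > 0:
            graft = GraftDistribution(
                molecules_per_cell=m, z_lo=z_lo, z_hi=z_hi,
                graft_segment_radius=graft_segment_radius,
                cell_area=cell_area,
                segments_per_molecule=segments_per_molecule)
        profile = build_profile(glx, graft, electrolyte, n_nodes=n_nodes)
        mobilities[i] = solve_mobility(profile, electrolyte).mobility
    return pd.DataFrame(
        {"molecules_per_cell": molecules, "mobility": mobilities})


_FIT_PARAM_SPECS: Mapping[str, tuple[float, float]] = {
    # name -> (log10 lower bound, log10 upper bound) on the magnitude
    "graft_segment_radius": (-10.7, -7.7),
    "segment_surface_density": (13.0, 18.0),
    "total_surface_charge": (-3.5, -0.8),   # magnitude in C/m^2; sign fixed <0
}


@dataclass(frozen=True)
class ScenarioFit:
    scenario: str
    params: dict
    sse: float


@dataclass(frozen=True)
class FitScenarioResult:
    """Outcome of fitting the mobility data under each grafting scenario."""

    best_scenario: str               # "uniform" | "outer" | "indistinguishable"
    fits: dict                       # scenario -> ScenarioFit
    indistinguishable: bool

    @property
    def sse_per_scenario(self) -> dict:
        return {s: f.sse for s, f in self.fits.items()}


def _apply_params(glx: GlycocalyxModel, values: Mapping[str, float]) -> GlycocalyxModel:
    glx_updates = {}
    for name in ("segment_surface_density",):
        if name in values:
            glx_updates[name] = values[name]
    if "total_surface_charge" in values:
        glx_updates["total_surface_charge"] = -abs(values["total_surface_charge"])
    return replace(glx, **glx_updates) if glx_updates else glx


def fit_scenario(
    measurements: pd.DataFrame,
    glx: GlycocalyxModel,
    electrolyte: Electrolyte,
    free_params: Sequence[str] = ("segment_surface_density",),
    outer_z_lo: float = OUTER_Z_LO_DEFAULT,
    cell_area: float = RBC_AREA_DEFAULT,
    n_nodes: int = 800,
    n_starts: int = 3,
    tie_rel_tol: float = 0.01,
) -> FitScenarioResult:
    """Weighted least-squares fit of the mobility data under both scenarios.

    ``measurements`` needs columns ``molecules_per_cell``, ``mobility`` and
    ``sd`` (SI units, sd > 0).  Each free parameter is optimized in log space
    from a deterministic multi-start grid, independently per scenario; the
    scenario with the lower weighted SSE wins unless the two SSEs agree within
    ``tie_rel_tol`` (relative), in which case the result is declared
    ``"indistinguishable"``.
    """
    free_params = tuple(free_params)
    for p in free_params:
        if p not in _FIT_PARAM_SPECS:
            raise InvalidParameterError(f"unknown free parameter {p!r}")
    n_pts = len(measurements)
    if n_pts < len(free_params):
        raise UnderDeterminedError(
            f"{n_pts} points cannot determine {len(free_params)} parameters")
    if n_pts == len(free_params):
        warnings.warn("fit is exactly determined: exact interpolation, "
                      "no residual degrees of freedom", UserWarning,
                      stacklevel=2)
    mol = np.asarray(measurements["molecules_per_cell"], dtype=float)
    mob = np.asarray(measurements["mobility"], dtype=float)
    sd = np.asarray(measurements["sd"], dtype=float)
    if np.any(sd <= 0):
        raise InvalidParameterError("measurement sd must be > 0")

    defaults = {
        "graft_segment_radius": hpg_stokes_radius(20000.0),
        "segment_surface_density": glx.segment_surface_density,
        "total_surface_charge": abs(glx.total_surface_charge),
    }

    def model_mobilities(scenario: str, values: Mapping[str, float]) -> np.ndarray:
        glx_eff = _apply_params(glx, values)
        radius = values.get("graft_segment_radius",
                            defaults["graft_segment_radius"])
        curve = mobility_curve(
            glx_eff, electrolyte, mol, scenario,
            graft_segment_radius=radius, outer_z_lo=outer_z_lo,
            cell_area=cell_area, n_nodes=n_nodes)
        return curve["mobility"].to_numpy()

    fits: dict[str, ScenarioFit] = {}
    for scenario in SCENARIOS:
        if not free_params:
            resid = (model_mobilities(scenario, {}) - mob) / sd
            fits[scenario] = ScenarioFit(scenario, {}, float(resid @ resid))
            continue

        lo = np.array([_FIT_PARAM_SPECS[p][0] for p in free_params])
        hi = np.array([_FIT_PARAM_SPECS[p][1] for p in free_params])
        x_default = np.array([
            np.clip(math.log10(defaults[p]), _FIT_PARAM_SPECS[p][0],
                    _FIT_PARAM_SPECS[p][1])
            for p in free_params])

        def residuals(x, scenario=scenario):
            values = {p: 10.0 ** xi for p, xi in zip(free_params, x)}
            return (model_mobilities(scenario, values) - mob) / sd

        offsets = np.linspace(-0.5, 0.5, n_starts) if n_starts > 1 else [0.0]
        best = None
        for off in offsets:
            x0 = np.clip(x_default + off, lo, hi)
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-10, ftol=1e-12)
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[0]:
                best = (sse, sol.x)
        sse, x_best = best
        params = {p: 10.0 ** xi for p, xi in zip(free_params, x_best)}
        if "total_surface_charge" in params:
            params["total_surface_charge"] = -params["total_surface_charge"]
        fits[scenario] = ScenarioFit(scenario, params, sse)

    sse_u, sse_o = fits["uniform"].sse, fits["outer"].sse
    denom = max(min(sse_u, sse_o), 1e-300)
    indistinguishable = abs(sse_u - sse_o) / denom < tie_rel_tol
    if indistinguishable:
        best_scenario = "indistinguishable"
    else:
        best_scenario = "uniform" if sse_u < sse_o else "outer"
    return FitScenarioResult(best_scenario=best_scenario, fits=fits,
                             indistinguishable=indistinguishable)
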