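"""Closed-form electrokinetics for a single piecewise-constant layer.

Analytic reference solution for the special case the finite-difference
solver is validated against: one surface layer ``0 <= z <= beta`` with
constant fixed charge density ``rho0`` and constant Brinkman friction
``f0 > 0``, charge- and friction-free electrolyte ``beta < z <= L``, a
Neumann membrane-charge condition at ``z = 0`` and ``psi(L) = 0``.

Both governing equations are linear with constant coefficients per region,
so the solution is a combination of hyperbolic modes matched at ``z = beta``;
the small matching systems are solved directly.  This module shares no code
with the finite-difference path in :mod:`glyx.electrokinetics`.

Requires ``kappa^2 != f0/eta`` (non-resonant forcing) and moderate
``sqrt(f0/eta)*beta`` so the hyperbolic terms do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .electrokinetics import Electrolyte
from .errors import InvalidParameterError


@dataclass(frozen=True)
class TwoRegionLayer:
    """Piecewise-constant layer description for the closed-form solution."""

    beta: float                    # m, layer thickness
    rho0: float                    # C/m^3, fixed charge density inside layer
    f0: float                      # kg/(m^3 s), friction inside layer
    L: float                       # m, domain length
    sigma_membrane: float = 0.0    # C/m^2

    def __post_init__(self) -> None:
        if not 0 < self.beta < self.L:
            raise InvalidParameterError("require 0 < beta < L")
        if self.f0 <= 0:
            raise InvalidParameterError("closed form requires f0 > 0")


def _potential_coefficients(layer: TwoRegionLayer, electrolyte: Electrolyte):
    kappa = electrolyte.kappa
    eps = electrolyte.permittivity
    beta, L = layer.beta, layer.L
    ell = L - beta

    D = layer.rho0 / (eps * kappa ** 2)
    B = -layer.sigma_membrane / (eps * kappa)
    chb, shb = math.cosh(kappa * beta), math.sinh(kappa * beta)
    th = math.tanh(kappa * ell)
    A = -(D + B * (shb + th * chb)) / (chb + th * shb)
    Q = A * shb + B * chb
    P = -Q * th
    return A, B, D, P, Q


def potential_profile(layer: TwoRegionLayer, electrolyte: Electrolyte,
                      z: np.ndarray) -> np.ndarray:
    """psi(z) in volts on arbitrary query points ``z``."""
    kappa = electrolyte.kappa
    A, B, D, P, Q = _potential_coefficients(layer, electrolyte)
    z = np.asarray(z, dtype=float)
    inside = z <= layer.beta
    psi = np.empty_like(z)
    psi[inside] = (A * np.cosh(kappa * z[inside])
                   + B * np.sinh(kappa * z[inside]) + D)
    zo = z[~inside] - layer.beta
    psi[~inside] = P * np.cosh(kappa * zo) + Q * np.sinh(kappa * zo)
    return psi


def mobility(layer: TwoRegionLayer, electrolyte: Electrolyte) -> float:
    """Electrophoretic mobility mu = -u(L) (m^2 / V s), closed form."""
    kappa = electrolyte.kappa
    eps = electrolyte.permittivity
    eta = electrolyte.viscosity
    beta, L = layer.beta, layer.L
    ell = L - beta

    lam = math.sqrt(layer.f0 / eta)
    if abs(kappa ** 2 - lam ** 2) < 1e-6 * kappa ** 2:
        raise InvalidParameterError(
            "closed form is singular at kappa^2 == f0/eta")

    A, B, D, P, Q = _potential_coefficients(layer, electrolyte)

    # inside: u'' - lam^2 u = (eps kappa^2 / eta) psi1(z)
    scale = eps * kappa ** 2 / eta
    alpha_A = scale * A / (kappa ** 2 - lam ** 2)
    alpha_B = scale * B / (kappa ** 2 - lam ** 2)
    alpha_D = -scale * D / lam ** 2

    chb, shb = math.cosh(kappa * beta), math.sinh(kappa * beta)
    chl, shl = math.cosh(lam * beta), math.sinh(lam * beta)
    chL, shL = math.cosh(kappa * ell), math.sinh(kappa * ell)

    psi2_L_prime = kappa * (P * shL + Q * chL)
    psi2_beta = P
    psi2_beta_prime = kappa * Q

    # u(0) = 0
    C1 = -(alpha_A + alpha_D)
    # outside: u2 = E1 + E2 (z - beta) + (eps/eta) psi2 ;  u2'(L) = 0
    E2 = -(eps / eta) * psi2_L_prime
    # u1'(beta) = u2'(beta)
    C2 = (E2 + (eps / eta) * psi2_beta_prime
          - kappa * (alpha_A * shb + alpha_B * chb)
          - lam * C1 * shl) / (lam * chl)
    # u1(beta) = u2(beta)
    E1 = (C1 * chl + C2 * shl + alpha_A * chb + alpha_B * shb + alpha_D
          - (eps / eta) * psi2_beta)

    u_L = E1 + E2 * ell   # psi2(L) = 0 by construction
    return float(-u_L)


def smoluchowski_mobility(zeta: float, electrolyte: Electrolyte) -> float:
    """Smoluchowski limit mu = eps * zeta / eta for a bare charged plate."""
    return electrolyte.permittivity * zeta / electrolyte.viscosity
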