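"""Force-field and integrator parameters for the soft-potential DPD model.

All quantities are in reduced DPD units: the non-bonded interaction cutoff
``r_c`` defines the length scale, the thermostat temperature ``kT`` the energy
scale, and bead mass is 1. The amplitude of the random force is never stored;
it follows from the fluctuation--dissipation relation
``sigma = sqrt(2 * gamma * kT)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = ["DPDParams", "chi_from_repulsion", "GROOT_WARREN_CHI_COEFF"]

#: Linear coefficient of the excess-repulsion -> Flory-Huggins mapping at
#: reduced bead density rho = 3 (Groot & Warren): chi = 0.286 * (a_ij - a_ii).
GROOT_WARREN_CHI_COEFF = 0.286


@dataclass(frozen=True)
class DPDParams:
    """Parameters of the DPD force field and integrator.

    Attributes
    ----------
    a_pp, a_ps, a_ss
        Conservative repulsion amplitudes for polymer-polymer,
        polymer-solvent and solvent-solvent pairs. The defaults
        (``a_pp = a_ss = 25``, ``a_ps = 55``) give a strongly poor solvent
        (Flory-Huggins chi = 8.58 at density 3), under which a single chain
        collapses into a globule.
    r_c
        Non-bonded interaction cutoff; sets the unit of length.
    bond_k, bond_l0
        Harmonic-bond stiffness and unperturbed length, shared by backbone
        and restraint bonds. ``bond_l0`` below ~0.3 destroys chain
        phantomness (strands can no longer cross), so reconstruction
        configurations guard against it.
    gamma, kT
        Dissipative friction and thermostat temperature.
    dt
        Integration step. The soft potentials tolerate a large step; 0.04 is
        the working default.
    rho
        Reduced bead number density used to size simulation boxes.
    lambda_vv
        Velocity-prediction factor of the modified velocity-Verlet
        integrator.
    bond_max_stretch
        Extension beyond which the bond force stops growing (truncated
        harmonic). Near equilibrium bonds never reach it; it only tames
        the initially overstretched restraint bonds of a reconstruction.
    theta
        Distribution of the pairwise random variate: "uniform" (on
        [-sqrt(3), sqrt(3)], unit variance, fast) or "gaussian".
    """

    a_pp: float = 25.0
    a_ps: float = 55.0
    a_ss: float = 25.0
    r_c: float = 1.0
    bond_k: float = 40.0
    bond_l0: float = 0.5
    gamma: float = 4.5
    kT: float = 1.0
    dt: float = 0.04
    rho: float = 3.0
    lambda_vv: float = 0.65
    bond_max_stretch: float = 2.0
    theta: str = field(default="uniform")

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.bond_k <= 0:
            raise ValueError("bond_k must be positive")
        if not (0.0 <= self.bond_l0 <= 2.0 * self.r_c):
            raise ValueError("bond_l0 must lie in [0, 2*r_c]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.gamma < 0 or self.kT < 0:
            raise ValueError("gamma and kT must be non-negative")
        if self.bond_max_stretch <= 0:
            raise ValueError("bond_max_stretch must be positive")
        if self.theta not in ("uniform", "gaussian"):
            raise ValueError("theta must be 'uniform' or 'gaussian'")

    @property
    def sigma(self) -> float:
        """Random-force amplitude from fluctuation--dissipation."""
        return math.sqrt(2.0 * self.gamma * self.kT)

    def good_solvent(self) -> "DPDParams":
        """Return a copy with athermal polymer-solvent interactions."""
        return replace(self, a_ps=self.a_pp)

    def replace(self, **kwargs) -> "DPDParams":
        return replace(self, **kwargs)


def chi_from_repulsion(a_cross: float, a_same: float, rho: float = 3.0) -> float:
    """Flory-Huggins parameter implied by an excess DPD repulsion.

    Uses the Groot-Warren linear mapping ``chi = 0.286 * (a_cross - a_same)``
    calibrated at reduced density ``rho = 3``; other densities would need
    their own mapping coefficient and are rejected.

    A negative excess repulsion (``a_cross < a_same``) corresponds to a good
    solvent; the value is still returned, with a warning.
    """
    if rho != 3.0:
        raise ValueError(
            "the chi mapping coefficient is calibrated at rho = 3 only"
        )
    if a_cross < a_same:
        warnings.warn(
            "a_cross < a_same: good-solvent regime, chi is negative",
            stacklevel=2,
        )
    return GROOT_WARREN_CHI_COEFF * (a_cross - a_same)
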