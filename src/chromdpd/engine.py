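"""Public interface to the DPD simulator: system state, topology, forces,
integration and thermometry."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .params import DPDParams

__all__ = [
    "SimState",
    "Topology",
    "UnstableIntegrationError",
    "pairwise_forces",
    "bond_forces",
    "integrate",
    "measure_temperature",
    "maxwell_boltzmann_velocities",
]

POLYMER = 0
SOLVENT = 1


class UnstableIntegrationError(RuntimeError):
    """A bead moved further than half the box edge in a single step."""


def _check_finite(coords: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise ValueError(f"non-finite {what} at bead index {idx}")


@dataclass
class Topology:
    """Connectivity and species of a simulated system.

    ``backbone_bonds`` are the consecutive (i, i+1) bonds of each chain;
    ``restraint_bonds`` are extra (i, j) bonds derived from a contact map.
    Both are treated identically by the force field. ``species`` labels
    each bead POLYMER (0) or SOLVENT (1).
    """

    n_beads: int
    backbone_bonds: np.ndarray
    restraint_bonds: np.ndarray
    species: np.ndarray

    def __init__(
        self,
        n_beads: int,
        backbone_bonds: Iterable[Sequence[int]] = (),
        restraint_bonds: Iterable[Sequence[int]] = (),
        species: np.ndarray | None = None,
    ):
        self.n_beads = int(n_beads)
        self.backbone_bonds = self._canonical(backbone_bonds)
        self.restraint_bonds = self._canonical(restraint_bonds)
        if species is None:
            species = np.zeros(self.n_beads, dtype=np.int8)
        self.species = np.asarray(species, dtype=np.int8)
        if self.species.shape != (self.n_beads,):
            raise ValueError("species must have one entry per bead")
        self._validate()

    def _canonical(self, bonds) -> np.ndarray:
        arr = np.asarray(list(bonds) if not isinstance(bonds, np.ndarray) else bonds,
                         dtype=np.int64)
        if arr.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        arr = arr.reshape(-1, 2)
        if (arr[:, 0] == arr[:, 1]).any():
            raise ValueError("bond between identical bead indices")
        arr = np.sort(arr, axis=1)
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        return arr[order]

    def _validate(self) -> None:
        for name, arr in (("backbone", self.backbone_bonds),
                          ("restraint", self.restraint_bonds)):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_beads):
                raise ValueError(f"{name} bond index out of range")
            if len(np.unique(arr, axis=0)) != len(arr):
                raise ValueError(f"duplicate {name} bonds")
        if self.backbone_bonds.size and self.restraint_bonds.size:
            bb = {tuple(b) for b in self.backbone_bonds}
            for b in self.restraint_bonds:
                if tuple(b) in bb:
                    raise ValueError(
                        f"restraint bond {tuple(b)} duplicates a backbone bond"
                    )

    @property
    def bonds(self) -> np.ndarray:
        """All bonds (backbone + restraints) as one (M, 2) array."""
        if self.restraint_bonds.size == 0:
            return self.backbone_bonds
        if self.backbone_bonds.size == 0:
            return self.restraint_bonds
        return np.vstack([self.backbone_bonds, self.restraint_bonds])


@dataclass
class SimState:
    """Positions, velocities and the periodic cubic box of a system.

    Positions are stored unwrapped; periodicity is applied through the
    minimum-image convention during force evaluation.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: float
    rng_seed: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions")
        if self.box <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(), self.velocities.copy(), self.box,
            self.rng_seed,
        )


def _a_matrix(params: DPDParams) -> np.ndarray:
    return np.array(
        [[params.a_pp, params.a_ps], [params.a_ps, params.a_ss]],
        dtype=np.float64,
    )


def pairwise_forces(
    state: SimState,
    topo: Topology,
    params: DPDParams,
    step: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Non-bonded DPD forces (conservative + dissipative + random).

    The random contribution is drawn from the counter-based stream keyed on
    (seed, step, i, j); pass ``params.replace(kT=0, gamma=0)`` to evaluate
    the conservative part alone.
    """
    _check_finite(state.positions, "coordinate")
    f = np.zeros_like(state.positions)
    _kernels.nonbonded_forces(
        state.positions, state.velocities, topo.species, _a_matrix(params),
        params.r_c, params.gamma, params.sigma, params.dt, state.box,
        seed, step, params.theta == "gaussian", f,
    )
    return f


def bond_forces(state: SimState, topo: Topology, params: DPDParams) -> np.ndarray:
    """Harmonic forces of backbone and restraint bonds."""
    _check_finite(state.positions, "coordinate")
    f = np.zeros_like(state.positions)
    bonds = topo.bonds
    if bonds.size:
        _kernels.bond_forces(
            state.positions, bonds, params.bond_k, params.bond_l0,
            params.bond_max_stretch, f,
        )
    return f


def integrate(
    state: SimState,
    topo: Topology,
    params: DPDParams,
    n_steps: int,
    seed: int,
    step_offset: int = 0,
) -> SimState:
    """Advance the system by ``n_steps`` modified velocity-Verlet steps.

    Deterministic given (state, seed, step_offset). Raises
    :class:`UnstableIntegrationError` when a bead moves more than half the
    box edge in one step.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    new = state.copy()
    new.rng_seed = seed
    if n_steps == 0:
        return new
    _check_finite(new.positions, "coordinate")
    status, done, _t = _kernels.run(
        new.positions, new.velocities, topo.species, _a_matrix(params),
        params.r_c, params.gamma, params.sigma, params.lambda_vv, params.dt,
        state.box, topo.bonds, params.bond_k, params.bond_l0,
        params.bond_max_stretch,
        n_steps, seed, step_offset, params.theta == "gaussian",
    )
    if status != 0:
        raise UnstableIntegrationError(
            f"unstable integration: displacement > box/2 at step "
            f"{step_offset + done}"
        )
    return new


def measure_temperature(state: SimState) -> float:
    """Kinetic temperature: twice the mean kinetic energy per degree of
    freedom, with 3N - 3 degrees of freedom (total momentum conserved)."""
    n = state.n_beads
    if n < 2:
        raise ValueError("temperature needs at least 2 beads")
    ke2 = float(np.sum(state.velocities**2))
    return ke2 / (3.0 * n - 3.0)


def maxwell_boltzmann_velocities(
    n: int, kT: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian velocities at temperature kT with zero total momentum."""
    v = rng.normal(scale=np.sqrt(kT), size=(n, 3))
    v -= v.mean(axis=0)
    return v
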