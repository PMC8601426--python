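"""Gold-standard and initial polymer conformations.

Generators for the reference structures a reconstruction is benchmarked
against: the equilibrium globule (a chain collapsed in poor solvent), the
analytical Moore curve (a closed space-filling curve on the lattice),
equilibrated polymer solutions in good solvent, and the random-walk starting
conformations that reconstructions are seeded from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels, engine
from .engine import POLYMER, SOLVENT, SimState, Topology
from .params import DPDParams

__all__ = [
    "Conformation",
    "random_walk",
    "generate_globule",
    "generate_solution",
    "moore_curve",
    "radius_of_gyration",
]


@dataclass
class Conformation:
    """Bead coordinates of one or more polymer chains.

    ``chains`` holds half-open (start, stop) bead-index ranges; consecutive
    beads within a chain are bonded. ``box`` is the cubic edge length of the
    box the conformation was generated in (0 means unbounded/analytical).
    ``genomic_bins`` optionally annotates each bead with a
    (chromosome, start, end) genomic bin.
    """

    coords: np.ndarray
    chains: list[tuple[int, int]]
    box: float = 0.0
    genomic_bins: Optional[list[tuple[str, int, int]]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        self.chains = [(int(a), int(b)) for a, b in self.chains]
        covered = sorted(self.chains)
        pos = 0
        for a, b in covered:
            if a != pos or b <= a:
                raise ValueError("chains must be disjoint, ordered and cover all beads")
            pos = b
        if pos != self.n_beads:
            raise ValueError("chains must cover all beads")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def backbone_bonds(self) -> np.ndarray:
        out = []
        for a, b in self.chains:
            for i in range(a, b - 1):
                out.append((i, i + 1))
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    def bond_lengths(self) -> np.ndarray:
        bonds = self.backbone_bonds()
        d = self.coords[bonds[:, 0]] - self.coords[bonds[:, 1]]
        return np.linalg.norm(d, axis=1)

    def rg(self) -> float:
        return radius_of_gyration(self.coords)


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of beads from their center of mass."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# random walk


def random_walk(
    n_beads: int,
    concentration: float,
    step_len: float = 0.5,
    seed: int = 0,
    rho: float = 3.0,
) -> Conformation:
    """Random walk with fixed step length in a periodic cubic box.

    The box edge follows from the requested polymer volume fraction:
    ``edge = (n_beads / (concentration * rho)) ** (1/3)``, i.e. the ratio of
    chain beads to all beads in the box equals ``concentration`` at bead
    density ``rho``. Steps that would leave the box are rejected and
    redrawn, so the chain is contiguous in real space, every coordinate
    lies inside the box, and every consecutive pair sits at exactly
    ``step_len``.
    """
    if not 0 < concentration <= 1:
        raise ValueError("concentration must be in (0, 1]")
    edge = (n_beads / (concentration * rho)) ** (1.0 / 3.0)
    if edge < step_len:
        raise ValueError(
            f"box edge {edge:.3g} smaller than step length {step_len:.3g}; "
            "reduce the concentration"
        )
    rng = np.random.default_rng(seed)
    coords = np.empty((n_beads, 3))
    coords[0] = rng.uniform(0, edge, size=3)
    for i in range(1, n_beads):
        while True:
            step = rng.normal(size=3)
            norm = np.linalg.norm(step)
            if norm == 0:
                continue
            nxt = coords[i - 1] + step / norm * step_len
            if (nxt >= 0).all() and (nxt <= edge).all():
                coords[i] = nxt
                break
    return Conformation(coords, [(0, n_beads)], box=edge,
                        meta={"kind": "walk", "seed": seed})


# ---------------------------------------------------------------------------
# DPD-equilibrated gold standards


def _build_solvated_state(
    polymer_coords: np.ndarray,
    box: float,
    params: DPDParams,
    rng: np.random.Generator,
) -> tuple[SimState, Topology, int]:
    """Fill the box with solvent beads up to density rho and thermalize."""
    n_poly = polymer_coords.shape[0]
    n_total = max(n_poly, int(round(params.rho * box**3)))
    n_solv = n_total - n_poly
    pos = np.vstack([polymer_coords, rng.uniform(0, box, size=(n_solv, 3))])
    vel = engine.maxwell_boltzmann_velocities(n_total, params.kT, rng)
    species = np.full(n_total, SOLVENT, dtype=np.int8)
    species[:n_poly] = POLYMER
    backbone = [(i, i + 1) for i in range(n_poly - 1)]
    topo = Topology(n_total, backbone_bonds=backbone, species=species)
    return SimState(pos, vel, box), topo, n_solv


def _equilibrate(
    state: SimState,
    topo: Topology,
    params: DPDParams,
    n_steps: int,
    seed: int,
    check_every: int = 1000,
    rel_tol: float = 0.01,
    observable=None,
) -> tuple[SimState, bool, int, list[float]]:
    """Run in chunks until ``observable`` plateaus or the budget is spent.

    The plateau criterion: over the trailing 20% of elapsed steps, the
    observable's relative spread around its final value stays below
    ``rel_tol``. Default observable: radius of gyration of the polymer.
    """
    n_poly = int((topo.species == POLYMER).sum())
    if observable is None:
        def observable(st):
            return radius_of_gyration(st.positions[:n_poly])

    history: list[float] = []
    done = 0
    converged = False
    min_checks = 10  # never declare a plateau from a handful of samples
    while done < n_steps:
        chunk = min(check_every, n_steps - done)
        state = engine.integrate(state, topo, params, chunk, seed,
                                 step_offset=done)
        done += chunk
        history.append(observable(state))
        window = max(5, int(0.2 * len(history)))
        if len(history) >= max(min_checks, window):
            tail = np.array(history[-window:])
            ref = abs(tail[-1]) if tail[-1] != 0 else 1.0
            if np.ptp(tail) / ref < rel_tol:
                converged = True
                break
    return state, converged, done, history


def _largest_cluster_fraction(coords: np.ndarray, linkage: float) -> float:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(linkage, output_type="ndarray")
    n = coords.shape[0]
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    _, counts = np.unique(roots, return_counts=True)
    return counts.max() / n


def generate_globule(
    n_beads: int,
    params: DPDParams | None = None,
    concentration: float = 0.1,
    n_steps: int | None = None,
    seed: int = 0,
    check_every: int = 1000,
) -> Conformation:
    """Collapse a random walk into an equilibrium globule in poor solvent.

    The default parameters (a_ps = 55 vs a_pp = 25, chi = 8.58) put the
    chain deep in the poor-solvent regime where it forms a single dense
    droplet. The initial chain is a reflected random walk confined to a
    compact region at the box center (slightly larger than the equilibrium
    droplet), so equilibration consists of local rearrangements rather than
    a slow collapse from a box-spanning coil; the equilibrium state is the
    same either way. The run stops early when the radius of gyration
    plateaus (relative spread < 1% over the trailing 20% of steps); the
    step budget defaults to 2e5 * n_beads / 4096, scaled linearly with
    chain length.
    """
    params = params or DPDParams()
    if params.a_ps <= params.a_pp:
        raise ValueError("poor solvent requires a_ps > a_pp")
    if n_steps is None:
        n_steps = max(2000, int(2e5 * n_beads / 4096))
    walk = random_walk(n_beads, concentration, params.bond_l0, seed,
                       rho=params.rho)
    # compact start: fold the walk into a central cube of ~1.7x the
    # equilibrium droplet volume, keeping bond lengths (reflection isometry)
    droplet_edge = min((1.7 * n_beads / params.rho) ** (1.0 / 3.0), walk.box)
    folded = np.abs(walk.coords) % (2.0 * droplet_edge)
    compact = np.where(folded > droplet_edge, 2.0 * droplet_edge - folded,
                       folded)
    compact += 0.5 * (walk.box - droplet_edge)
    walk.coords[:] = compact
    rng = np.random.default_rng(seed + 1)
    state, topo, _ = _build_solvated_state(walk.coords, walk.box, params, rng)
    if n_steps == 0:
        return Conformation(walk.coords, [(0, n_beads)], box=walk.box,
                            meta={"kind": "globule", "converged": False,
                                  "n_steps": 0, "seed": seed})
    state, plateaued, done, rg_hist = _equilibrate(
        state, topo, params, n_steps, seed,
        check_every=min(check_every, max(n_steps // 20, 100)))
    coords = state.positions[:n_beads] - state.positions[:n_beads].mean(axis=0)
    frac = _largest_cluster_fraction(coords, params.r_c)
    converged = plateaued and frac >= 0.99
    return Conformation(
        coords, [(0, n_beads)], box=walk.box,
        meta={"kind": "globule", "converged": converged,
              "cluster_fraction": frac, "n_steps": done,
              "rg_history": rg_hist, "seed": seed},
    )


def generate_solution(
    n_beads: int,
    concentration: float,
    params: DPDParams | None = None,
    n_steps: int | None = None,
    seed: int = 0,
    check_every: int = 1000,
) -> Conformation:
    """Equilibrated coil at a given polymer volume fraction (good solvent).

    The polymer-solvent repulsion is set equal to the polymer-polymer one
    (athermal solvent), so the chain stays a coil confined only by the
    periodic box. The polymer-bead fraction of all beads equals
    ``concentration`` exactly; ``concentration = 1`` is a melt with no
    solvent.
    """
    if not 0 < concentration <= 1:
        raise ValueError("concentration must be in (0, 1]")
    params = (params or DPDParams()).good_solvent()
    if n_steps is None:
        n_steps = max(2000, int(2e5 * n_beads / 4096))
    walk = random_walk(n_beads, concentration, params.bond_l0, seed,
                       rho=params.rho)
    rng = np.random.default_rng(seed + 1)
    state, topo, _ = _build_solvated_state(walk.coords, walk.box, params, rng)
    state, plateaued, done, rg_hist = _equilibrate(
        state, topo, params, n_steps, seed,
        check_every=min(check_every, max(n_steps // 20, 100)), rel_tol=0.05)
    coords = state.positions[:n_beads] - state.positions[:n_beads].mean(axis=0)
    return Conformation(
        coords, [(0, n_beads)], box=walk.box,
        meta={"kind": "solution", "concentration": concentration,
              "converged": plateaued, "n_steps": done,
              "rg_history": rg_hist, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Moore curve


def _hilbert_points(order: int) -> np.ndarray:
    """3D Hilbert curve coordinates for indices 0 .. 8**order - 1.

    Iterative transpose algorithm (Skilling): interleave the index bits
    into three coordinate words, Gray-decode, then undo the per-level
    rotations.
    """
    n = 3
    npts = 8**order
    idx = np.arange(npts, dtype=np.uint64)
    # bit-transpose the index into 3 coordinate words
    x = np.zeros((n, npts), dtype=np.uint64)
    for b in range(order * n):
        bit = (idx >> np.uint64(order * n - 1 - b)) & np.uint64(1)
        axis = b % n
        x[axis] = (x[axis] << np.uint64(1)) | bit
    # Gray decode
    t = x[n - 1] >> np.uint64(1)
    for i in range(n - 1, 0, -1):
        x[i] ^= x[i - 1]
    x[0] ^= t
    # undo excess work
    Q = 2
    while Q != (1 << order):
        P = np.uint64(Q - 1)
        Qu = np.uint64(Q)
        for i in range(n - 1, -1, -1):
            hasbit = (x[i] & Qu) != 0
            x[0] = np.where(hasbit, x[0] ^ P, x[0])
            tt = np.where(hasbit, np.uint64(0), (x[0] ^ x[i]) & P)
            x[0] ^= tt
            x[i] ^= tt
        Q <<= 1
    return x.T.astype(np.int64)


_OCTANT_CYCLE = np.array(
    [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0),
     (1, 1, 0), (1, 1, 1), (1, 0, 1), (1, 0, 0)],
    dtype=np.int64,
)


def _isometries(m: int):
    """All 48 cube isometries on {0..m-1}^3 as (perm, signs) pairs."""
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            yield perm, signs


def _apply_isometry(pts: np.ndarray, perm, signs, m: int) -> np.ndarray:
    out = pts[:, list(perm)].copy()
    for k in range(3):
        if signs[k] < 0:
            out[:, k] = (m - 1) - out[:, k]
    return out


def _stitch_octants(start: np.ndarray, end: np.ndarray, m: int):
    """Choose one isometry per octant so the 8 sub-curves close a loop.

    ``start`` and ``end`` are the base sub-curve endpoints inside a cube of
    edge ``m``. Backtracking over the 48 isometries per octant; the first
    complete assignment is returned (deterministic order).
    """
    isos = list(_isometries(m))
    ep = []  # per isometry: transformed (start, end) in octant-local coords
    for perm, signs in isos:
        s = _apply_isometry(start[None, :], perm, signs, m)[0]
        e = _apply_isometry(end[None, :], perm, signs, m)[0]
        ep.append((s, e))
    offs = _OCTANT_CYCLE * m

    chosen: list[int] = []

    def adjacent(p, q) -> bool:
        return int(np.abs(p - q).sum()) == 1

    def rec(t: int) -> bool:
        if t == 8:
            e = ep[chosen[7]][1] + offs[7]
            s0 = ep[chosen[0]][0] + offs[0]
            return adjacent(e, s0)
        for k in range(len(isos)):
            if t > 0:
                prev_end = ep[chosen[t - 1]][1] + offs[t - 1]
                if not adjacent(prev_end, ep[k][0] + offs[t]):
                    continue
            chosen.append(k)
            if rec(t + 1):
                return True
            chosen.pop()
        return False

    if not rec(0):
        raise RuntimeError("no octant stitching found")  # pragma: no cover
    return [isos[k] for k in chosen]


def moore_curve(order: int, bond_length: float = 1.0) -> Conformation:
    """Closed space-filling curve on the 2**order lattice cube.

    Built from eight rotated copies of the order-(order-1) Hilbert curve
    whose octants follow a closed Gray-code cycle, giving a Hamiltonian
    cycle through all 8**order lattice sites: every consecutive pair (and
    the last-first pair) sits at lattice distance 1, and every site is
    visited exactly once. Deterministic, no randomness.

    Coordinates are multiplied by ``bond_length`` so the curve can serve as
    a gold standard at any target bond length.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= 8:
        raise ValueError("order >= 8 refused (8**order beads would not fit in memory)")
    if order == 1:
        pts = _OCTANT_CYCLE.copy()
    else:
        m = 2 ** (order - 1)
        base = _hilbert_points(order - 1)
        trans = _stitch_octants(base[0], base[-1], m)
        blocks = []
        for t, (perm, signs) in enumerate(trans):
            blocks.append(_apply_isometry(base, perm, signs, m)
                          + _OCTANT_CYCLE[t] * m)
        pts = np.vstack(blocks)
    coords = pts.astype(np.float64) * bond_length
    n = coords.shape[0]
    return Conformation(coords, [(0, n)], box=0.0,
                        meta={"kind": "moore", "order": order})
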