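"""Force-field and integrator checks against independent oracles."""

import numpy as np
import pytest

from chromdpd import (
    DPDParams,
    SimState,
    Topology,
    UnstableIntegrationError,
    bond_forces,
    integrate,
    measure_temperature,
    pairwise_forces,
)
from chromdpd.engine import maxwell_boltzmann_velocities
from chromdpd import _kernels


def brute_force_nonbonded(pos, vel, species, params, L, seed=0, step=0):
    """O(N^2) reference: plain numpy double loop over all pairs.

    Shares only the per-pair random-variate definition with the kernel;
    pair discovery, minimum image and force algebra are independent.
    """
    a = np.array([[params.a_pp, params.a_ps], [params.a_ps, params.a_ss]])
    n = len(pos)
    f = np.zeros((n, 3))
    inv_sqrt_dt = 1.0 / np.sqrt(params.dt)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d = d - L * np.floor(d / L + 0.5)
            r = np.linalg.norm(d)
            if r >= params.r_c or r == 0:
                continue
            w = 1 - r / params.r_c
            e = d / r
            fm = a[species[i], species[j]] * w
            fm -= params.gamma * w * w * np.dot(e, vel[i] - vel[j])
            if params.sigma > 0:
                th = _kernels._theta(seed, step, i, j, False)
                fm += params.sigma * w * th * inv_sqrt_dt
            f[i] += fm * e
            f[j] -= fm * e
    return f


@pytest.fixture
def solvent_box():
    rng = np.random.default_rng(3)
    L = 3.5
    n = 120  # large enough to exercise the cell-list path
    pos = rng.uniform(0, L, (n, 3))
    vel = rng.normal(scale=0.7, size=(n, 3))
    species = (rng.random(n) < 0.4).astype(np.int8)
    topo = Topology(n, species=species)
    return SimState(pos, vel, L), topo


class TestPairwiseForces:
    def test_cell_list_matches_brute_force(self, solvent_box):
        state, topo = solvent_box
        p = DPDParams()
        f = pairwise_forces(state, topo, p, step=5, seed=11)
        ref = brute_force_nonbonded(
            state.positions, state.velocities, topo.species, p, state.box,
            seed=11, step=5,
        )
        np.testing.assert_allclose(f, ref, atol=1e-11)

    def test_force_vanishes_at_cutoff(self):
        p = DPDParams()
        state = SimState(
            np.array([[1.0, 1.0, 1.0], [1.0 + p.r_c, 1.0, 1.0]]),
            np.zeros((2, 3)), 20.0,
        )
        f = pairwise_forces(state, Topology(2), p, seed=1)
        np.testing.assert_array_equal(f, 0.0)

    def test_contact_limit_equals_repulsion_amplitude(self):
        # conservative force -> a_pp as r -> 0 (linear soft-core law)
        p = DPDParams(gamma=0.0, kT=0.0)
        state = SimState(
            np.array([[0.0, 0.0, 0.0], [1e-8, 0.0, 0.0]]),
            np.zeros((2, 3)), 20.0,
        )
        f = pairwise_forces(state, Topology(2), p)
        assert np.linalg.norm(f[1]) == pytest.approx(25.0, rel=1e-6)

    def test_newtons_third_law_with_thermostat(self, solvent_box):
        state, topo = solvent_box
        f = pairwise_forces(state, topo, DPDParams(), step=2, seed=9)
        np.testing.assert_allclose(
            f.sum(axis=0), 0.0, atol=1e-10 * state.n_beads
        )

    def test_nonfinite_coordinate_names_bead(self, solvent_box):
        state, topo = solvent_box
        state.positions[7, 1] = np.nan
        with pytest.raises(ValueError, match="bead index 7"):
            pairwise_forces(state, topo, DPDParams())


class TestBondForces:
    def test_zero_at_rest_length(self):
        p = DPDParams()
        state = SimState(
            np.array([[0.0, 0.0, 0.0], [p.bond_l0, 0.0, 0.0]]),
            np.zeros((2, 3)), 10.0,
        )
        topo = Topology(2, backbone_bonds=[(0, 1)])
        np.testing.assert_allclose(bond_forces(state, topo, p), 0.0, atol=1e-14)

    def test_unit_extension_gives_k(self):
        p = DPDParams(bond_k=40.0, bond_l0=0.5)
        state = SimState(
            np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
            np.zeros((2, 3)), 10.0,
        )
        f = bond_forces(state, Topology(2, backbone_bonds=[(0, 1)]), p)
        assert f[0, 0] == pytest.approx(40.0)
        assert f[1, 0] == pytest.approx(-40.0)

    def test_three_bond_chain_term_by_term(self):
        # total bond force on each bead equals the sum of per-bond
        # closed forms -k (r - l0) rhat
        p = DPDParams(bond_k=40.0, bond_l0=0.5)
        coords = np.array(
            [[0.0, 0.0, 0.0], [0.9, 0.1, 0.0], [1.1, 1.0, 0.3],
             [0.8, 1.9, 0.7]]
        )
        state = SimState(coords, np.zeros((4, 3)), 10.0)
        topo = Topology(4, backbone_bonds=[(0, 1), (1, 2), (2, 3)])
        expected = np.zeros((4, 3))
        for i, j in topo.backbone_bonds:
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            fm = -p.bond_k * (r - p.bond_l0) / r
            expected[i] += fm * d
            expected[j] -= fm * d
        np.testing.assert_allclose(bond_forces(state, topo, p), expected,
                                   atol=1e-12)

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            Topology(3, backbone_bonds=[(1, 1)])

    def test_restraint_duplicating_backbone_rejected(self):
        with pytest.raises(ValueError, match="duplicates a backbone"):
            Topology(3, backbone_bonds=[(0, 1)], restraint_bonds=[(1, 0)])


class TestIntegrate:
    def test_zero_steps_is_identity(self, solvent_box):
        state, topo = solvent_box
        out = integrate(state, topo, DPDParams(), 0, seed=1)
        np.testing.assert_array_equal(out.positions, state.positions)
        np.testing.assert_array_equal(out.velocities, state.velocities)

    def test_same_seed_bit_identical(self, solvent_box):
        state, topo = solvent_box
        p = DPDParams()
        out1 = integrate(state, topo, p, 200, seed=42)
        out2 = integrate(state, topo, p, 200, seed=42)
        np.testing.assert_array_equal(out1.positions, out2.positions)
        np.testing.assert_array_equal(out1.velocities, out2.velocities)

    def test_different_seed_differs(self, solvent_box):
        state, topo = solvent_box
        p = DPDParams()
        out1 = integrate(state, topo, p, 50, seed=1)
        out2 = integrate(state, topo, p, 50, seed=2)
        assert not np.allclose(out1.positions, out2.positions)

    def test_momentum_conserved(self, solvent_box):
        state, topo = solvent_box
        state.velocities -= state.velocities.mean(axis=0)
        out = integrate(state, topo, DPDParams(), 500, seed=3)
        np.testing.assert_allclose(
            out.velocities.sum(axis=0), 0.0, atol=1e-9
        )

    def test_unstable_integration_aborts(self):
        # a bead crossing more than box/2 in one step must abort the run
        p = DPDParams()
        vel = np.zeros((2, 3))
        vel[0, 0] = 200.0  # dt * v = 8 > box/2
        state = SimState(
            np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]), vel, 6.0,
        )
        topo = Topology(2, backbone_bonds=[(0, 1)])
        with pytest.raises(UnstableIntegrationError, match="unstable"):
            integrate(state, topo, p, 100, seed=1)


class TestTemperature:
    def test_zero_velocities(self):
        state = SimState(np.zeros((5, 3)), np.zeros((5, 3)), 5.0)
        assert measure_temperature(state) == 0.0

    def test_maxwell_boltzmann_sample(self):
        rng = np.random.default_rng(0)
        v = maxwell_boltzmann_velocities(20000, 1.0, rng)
        state = SimState(np.zeros((20000, 3)), v, 5.0)
        assert measure_temperature(state) == pytest.approx(1.0, abs=0.02)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        v = maxwell_boltzmann_velocities(500, 1.0, rng)
        t1 = measure_temperature(SimState(np.zeros((500, 3)), v, 5.0))
        t2 = measure_temperature(SimState(np.zeros((500, 3)), 2 * v, 5.0))
        assert t2 == pytest.approx(4 * t1)


def _ring(n_ring, radius, center, plane):
    th = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    if plane == "xy":
        pts = np.column_stack(
            [radius * np.cos(th), radius * np.sin(th), np.zeros(n_ring)])
    else:
        pts = np.column_stack(
            [radius * np.cos(th), np.zeros(n_ring), radius * np.sin(th)])
    return pts + center


def _linking_number(c1, c2):
    """Discrete Gauss double sum over segment midpoints."""
    t1 = np.roll(c1, -1, axis=0) - c1
    m1 = c1 + 0.5 * t1
    t2 = np.roll(c2, -1, axis=0) - c2
    m2 = c2 + 0.5 * t2
    r = m1[:, None, :] - m2[None, :, :]
    num = np.einsum("ijk,ijk->ij", np.cross(t1[:, None, :], t2[None, :, :]), r)
    den = np.sqrt((r**2).sum(-1)) ** 3
    return (num / den).sum() / (4 * np.pi)


class TestPhantomness:
    """Soft potentials let strands cross at l0 = 0.5 but not at l0 = 0.2.

    Two linked rings of identical geometry (radius ~1.27) differ only in
    bead spacing. At l0 = 0.5 thermal motion unlinks them quickly; at
    l0 = 0.2 the quasi-continuous bead tube raises the crossing barrier
    and most runs stay topologically linked over the same horizon.
    """

    HORIZON = 20000
    SEEDS = (1, 2, 3)

    def _run(self, l0, n_ring, seed):
        radius = 16 * 0.5 / (2 * np.pi)
        L = 8.0
        c1 = _ring(n_ring, radius, np.array([L / 2, L / 2, L / 2]), "xy")
        c2 = _ring(n_ring, radius,
                   np.array([L / 2 + radius, L / 2, L / 2]), "xz")
        n = 2 * n_ring
        bonds = [(i, (i + 1) % n_ring) for i in range(n_ring)]
        bonds += [(n_ring + i, n_ring + (i + 1) % n_ring)
                  for i in range(n_ring)]
        topo = Topology(n, backbone_bonds=bonds,
                        species=np.zeros(n, dtype=np.int8))
        p = DPDParams().replace(bond_l0=l0)
        rng = np.random.default_rng(seed)
        state = SimState(np.vstack([c1, c2]),
                         maxwell_boltzmann_velocities(n, 1.0, rng), L)
        off = 0
        while off < self.HORIZON:
            state = integrate(state, topo, p, 1000, seed=seed * 7 + 1,
                              step_offset=off)
            off += 1000
            lk = _linking_number(state.positions[:n_ring],
                                 state.positions[n_ring:])
            if abs(lk) < 0.3:
                return True
        return False

    def test_crossing_at_l05_but_not_at_l02(self):
        unlinked_05 = sum(self._run(0.5, 16, s) for s in self.SEEDS)
        unlinked_02 = sum(self._run(0.2, 40, s) for s in self.SEEDS)
        assert unlinked_05 == len(self.SEEDS)
        assert unlinked_02 < unlinked_05
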