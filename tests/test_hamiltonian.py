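"""Extended-dipole couplings, Hamiltonian assembly and diagonalization."""

import numpy as np
import pytest
import scipy.linalg

from excitube import (
    ExtendedDipoleSpec,
    K_COULOMB,
    build_hamiltonian,
    collective_dipoles,
    coupling_extended_dipole,
    coupling_point_dipole,
    coupling_sum_per_site,
    coupling_sum_stats,
    delocalization_size,
    diagonalize,
    exciton_bandwidth,
    participation_sizes,
    scale_unit_cell,
    solve_structure,
)
from excitube.hamiltonian import ExcitonHamiltonian
from excitube.lattice import OverlapError, RollingSpec, build_tube

from conftest import make_chain, make_ring


def four_term_sum(pos_i, dip_i, pos_j, dip_j, q, length):
    """Independent oracle: explicit four-term transition-charge sum."""
    ends_i = [pos_i + 0.5 * length * dip_i, pos_i - 0.5 * length * dip_i]
    ends_j = [pos_j + 0.5 * length * dip_j, pos_j - 0.5 * length * dip_j]
    signs = [(0, 0, +1), (1, 1, +1), (0, 1, -1), (1, 0, -1)]
    total = 0.0
    for a, b, s in signs:
        total += s / np.linalg.norm(np.asarray(ends_i[a]) - np.asarray(ends_j[b]))
    return K_COULOMB * q**2 * total


class TestExtendedDipoleCoupling:
    spec = ExtendedDipoleSpec(charge=1.0, length=0.7)

    def test_side_by_side_h_type(self):
        """Parallel side-by-side dipoles: positive (H-type) coupling
        k*(2 - 2/sqrt(1.49)) ~ +4.199e3 cm^-1."""
        z = np.array([0.0, 0.0, 1.0])
        j = coupling_extended_dipole(
            np.zeros(3), z, np.array([1.0, 0.0, 0.0]), z, self.spec
        )
        oracle = four_term_sum(np.zeros(3), z, np.array([1.0, 0.0, 0.0]), z, 1.0, 0.7)
        assert np.isclose(j, oracle, rtol=1e-12)
        assert np.isclose(j, K_COULOMB * (2 - 2 / np.sqrt(1.49)), rtol=1e-9)
        assert 4.19e3 < j < 4.21e3

    def test_head_to_tail_j_type(self):
        """Collinear head-to-tail dipoles: negative (J-type) coupling
        k*(1 - 1/1.3 - 1/2.7) ~ -1.621e3 cm^-1."""
        z = np.array([0.0, 0.0, 1.0])
        j = coupling_extended_dipole(
            np.zeros(3), z, np.array([0.0, 0.0, 2.0]), z, self.spec
        )
        assert np.isclose(j, K_COULOMB * (2 / 2 - 1 / 1.3 - 1 / 2.7), rtol=1e-9)
        assert -1.63e3 < j < -1.61e3

    def test_scales_with_charge_squared(self):
        z = np.array([0.0, 0.0, 1.0])
        x1 = np.array([1.0, 0.0, 0.0])
        j1 = coupling_extended_dipole(np.zeros(3), z, x1, z, ExtendedDipoleSpec(0.2, 0.7))
        j2 = coupling_extended_dipole(np.zeros(3), z, x1, z, ExtendedDipoleSpec(0.4, 0.7))
        assert np.isclose(j2, 4 * j1)

    def test_screening_divides(self):
        z = np.array([0.0, 0.0, 1.0])
        x1 = np.array([1.0, 0.0, 0.0])
        j1 = coupling_extended_dipole(np.zeros(3), z, x1, z, self.spec)
        j2 = coupling_extended_dipole(np.zeros(3), z, x1, z, self.spec, screening=2.0)
        assert np.isclose(j2, j1 / 2)

    def test_overlap_guard(self):
        z = np.array([0.0, 0.0, 1.0])
        with pytest.raises(OverlapError):
            coupling_extended_dipole(
                np.zeros(3), z, np.array([0.05, 0.0, 0.0]), z, self.spec
            )

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(50):
            pos_j = rng.normal(scale=3.0, size=3)
            if np.linalg.norm(pos_j) < 1.5:
                continue
            d_i = rng.normal(size=3)
            d_i /= np.linalg.norm(d_i)
            d_j = rng.normal(size=3)
            d_j /= np.linalg.norm(d_j)
            j = coupling_extended_dipole(np.zeros(3), d_i, pos_j, d_j, self.spec)
            assert np.isclose(
                j, four_term_sum(np.zeros(3), d_i, pos_j, d_j, 1.0, 0.7), rtol=1e-12
            )


class TestPointDipoleCoupling:
    def test_collinear(self):
        z = np.array([0.0, 0.0, 1.0])
        j = coupling_point_dipole(np.zeros(3), z, np.array([0, 0, 2.0]), z, mu=0.5)
        assert np.isclose(j, -2 * K_COULOMB * 0.25 / 8.0)

    def test_side_by_side(self):
        z = np.array([0.0, 0.0, 1.0])
        j = coupling_point_dipole(np.zeros(3), z, np.array([2.0, 0, 0]), z, mu=0.5)
        assert np.isclose(j, K_COULOMB * 0.25 / 8.0)

    def test_magic_angle(self):
        z = np.array([0.0, 0.0, 1.0])
        theta = np.arccos(1 / np.sqrt(3))
        r = 2.0 * np.array([np.sin(theta), 0.0, np.cos(theta)])
        j = coupling_point_dipole(np.zeros(3), z, r, z, mu=0.5)
        assert abs(j) < 1e-10

    def test_coincident_sites_rejected(self):
        z = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            coupling_point_dipole(np.zeros(3), z, np.zeros(3), z, mu=0.5)

    def test_far_field_limit(self, rng):
        """Extended dipole converges to the point dipole at r >= 20 l.

        The deviation is measured against the dipolar kernel scale
        k mu^2 / r^3; the raw ratio |J_ext - J_pt| / |J_pt| has a
        removable singularity at magic-angle orientations where the
        point coupling itself vanishes.
        """
        spec = ExtendedDipoleSpec(1.0, 0.7)
        for _ in range(20):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = (20.0 + 10.0 * rng.random()) * spec.length
            pos_j = r * direction
            d_i = rng.normal(size=3)
            d_i /= np.linalg.norm(d_i)
            d_j = rng.normal(size=3)
            d_j /= np.linalg.norm(d_j)
            je = coupling_extended_dipole(np.zeros(3), d_i, pos_j, d_j, spec)
            jp = coupling_point_dipole(np.zeros(3), d_i, pos_j, d_j, spec.mu)
            scale = K_COULOMB * spec.mu**2 / r**3
            assert abs(je - jp) / scale < 0.005


class TestBuildHamiltonian:
    spec = ExtendedDipoleSpec(0.34, 0.7)

    def test_two_site_matrix(self):
        chain = make_chain(2, 2.0)
        h = build_hamiltonian(chain, self.spec, e0=0.0)
        j = coupling_extended_dipole(
            chain.positions[0], chain.dipoles[0],
            chain.positions[1], chain.dipoles[1], self.spec,
        )
        assert np.allclose(h.matrix, [[0.0, j], [j, 0.0]])

    def test_zero_cutoff_gives_diagonal(self):
        ring = make_ring(10, 2.0)
        h = build_hamiltonian(ring, self.spec, e0=5.0, cutoff=0.0)
        assert np.allclose(h.matrix, 5.0 * np.eye(10))

    def test_ring_all_pairs_symmetric(self):
        ring = make_ring(100, 15.0)
        h = build_hamiltonian(ring, self.spec, e0=0.0)
        off = h.couplings
        assert np.count_nonzero(np.triu(off, k=1)) == 4950
        assert np.array_equal(h.matrix, h.matrix.T)

    def test_shifts_on_diagonal(self):
        chain = make_chain(3, 2.0)
        shifts = np.array([1.0, -2.0, 3.0])
        h = build_hamiltonian(chain, self.spec, e0=100.0, shifts=shifts)
        assert np.allclose(np.diag(h.matrix), 100.0 + shifts)
        with pytest.raises(ValueError):
            build_hamiltonian(chain, self.spec, shifts=np.array([np.nan, 0, 0]))

    def test_axial_images_require_periodic_structure(self):
        chain = make_chain(3, 2.0)
        with pytest.raises(ValueError):
            build_hamiltonian(chain, self.spec, axial_images=2)

    def test_axial_images_deepen_coupling_sum(self, cell):
        """Periodic images add the couplings lost at the open ends."""
        tube = build_tube(cell, RollingSpec(3.2, 30.0, 6.0), periodic_axial=True)
        h0 = build_hamiltonian(tube, self.spec, e0=0.0)
        h1 = build_hamiltonian(tube, self.spec, e0=0.0, axial_images=2)
        assert coupling_sum_per_site(h1).mean() < coupling_sum_per_site(h0).mean()
        assert np.allclose(h1.matrix, h1.matrix.T)


class TestDiagonalize:
    def test_dimer_eigenvalues(self):
        h = ExcitonHamiltonian(
            matrix=np.array([[0.0, -50.0], [-50.0, 0.0]]),
            walls=np.array(["IW", "IW"]), e0=0.0,
        )
        states = diagonalize(h)
        assert np.allclose(states.energies, [-50.0, 50.0])

    def test_three_ring_circulant(self):
        j = -30.0
        h = ExcitonHamiltonian(
            matrix=j * (np.ones((3, 3)) - np.eye(3)),
            walls=np.array(["IW"] * 3), e0=0.0,
        )
        states = diagonalize(h)
        assert np.allclose(np.sort(states.energies), sorted([2 * j, -j, -j]))

    def test_matches_independent_solver(self, rng):
        a = rng.normal(size=(50, 50))
        sym = 0.5 * (a + a.T)
        h = ExcitonHamiltonian(matrix=sym, walls=np.full(50, "IW"), e0=0.0)
        states = diagonalize(h)
        ref = scipy.linalg.eigh(sym, eigvals_only=True)
        assert np.allclose(states.energies, ref, atol=1e-9)

    def test_trace_conserved(self, rng):
        a = rng.normal(size=(40, 40))
        sym = 0.5 * (a + a.T) + np.diag(rng.normal(100, 10, 40))
        h = ExcitonHamiltonian(matrix=sym, walls=np.full(40, "IW"), e0=0.0)
        states = diagonalize(h)
        assert np.isclose(
            states.energies.sum(), np.trace(sym), rtol=1e-8
        )

    def test_orthonormal_eigenvectors(self, rng):
        a = rng.normal(size=(30, 30))
        h = ExcitonHamiltonian(
            matrix=0.5 * (a + a.T), walls=np.full(30, "IW"), e0=0.0
        )
        states = diagonalize(h)
        assert np.allclose(states.coeffs @ states.coeffs.T, np.eye(30), atol=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            ExcitonHamiltonian(
                matrix=np.array([[0.0, 1.0], [2.0, 0.0]]),
                walls=np.array(["IW", "IW"]), e0=0.0,
            )


class TestCollectiveDipoles:
    def test_parallel_dimer_bright_state(self):
        chain = make_ring(2, 1.0)  # side-by-side, dipoles parallel z
        spec = ExtendedDipoleSpec(0.34, 0.7)
        _, states = solve_structure(chain, spec, e0=0.0)
        f = states.oscillator_strengths
        mu2 = spec.mu**2
        assert np.isclose(f.max(), 2 * mu2, rtol=1e-9)
        assert np.isclose(f.min(), 0.0, atol=1e-12)
        # H-type: the bright (symmetric) state lies above the dark one
        assert f.argmax() == 1

    def test_sum_rule(self, small_tube, dipole_spec):
        _, states = solve_structure(small_tube, dipole_spec, e0=0.0)
        total = states.oscillator_strengths.sum()
        assert np.isclose(
            total, len(small_tube) * dipole_spec.mu**2, rtol=1e-8
        )

    def test_single_site_identity(self):
        single = make_chain(1, 1.0)
        states = diagonalize(
            ExcitonHamiltonian(np.zeros((1, 1)), np.array(["IW"]), 0.0)
        )
        mu = collective_dipoles(states, single, 0.4)
        assert np.allclose(np.abs(mu), [[0, 0, 0.4]])


class TestCouplingSums:
    spec = ExtendedDipoleSpec(0.34, 0.7)

    def test_dimer_both_entries_equal(self):
        chain = make_chain(2, 2.0)
        h = build_hamiltonian(chain, self.spec, e0=0.0)
        sums = coupling_sum_per_site(h)
        assert np.isclose(sums[0], sums[1])
        assert np.isclose(sums[0], h.matrix[0, 1])

    def test_three_ring(self):
        j = -30.0
        h = ExcitonHamiltonian(
            j * (np.ones((3, 3)) - np.eye(3)), np.array(["IW"] * 3), 0.0
        )
        assert np.allclose(coupling_sum_per_site(h), 2 * j)

    def test_j_aggregate_sign(self, small_tube, dipole_spec):
        """The tubular lattice is a J-aggregate: negative coupling sums."""
        h = build_hamiltonian(small_tube, dipole_spec, e0=0.0)
        stats = coupling_sum_stats(h)
        assert stats["IW"]["mean"] < -2000.0

    def test_ow_expansion_weakens_couplings(self, cell, dipole_spec):
        """Expanding the lattice by 2.4% strictly reduces |sum_j J_ij|."""
        spec_roll = RollingSpec(3.2, 30.0, 6.0)
        h_iw = build_hamiltonian(
            build_tube(cell, spec_roll, wall="IW"), dipole_spec, e0=0.0
        )
        h_ow = build_hamiltonian(
            build_tube(scale_unit_cell(cell, 1.024), spec_roll, wall="OW"),
            dipole_spec, e0=0.0,
        )
        mean_iw = coupling_sum_stats(h_iw)["IW"]["mean"]
        mean_ow = coupling_sum_stats(h_ow)["OW"]["mean"]
        assert abs(mean_ow) < abs(mean_iw)


class TestBandwidthAndDelocalization:
    def test_dimer_bandwidth(self):
        h = ExcitonHamiltonian(
            np.array([[0.0, -40.0], [-40.0, 0.0]]), np.array(["IW", "IW"]), 0.0
        )
        assert np.isclose(exciton_bandwidth(diagonalize(h)), 80.0)

    def test_uncoupled_bandwidth_zero(self):
        h = ExcitonHamiltonian(np.zeros((5, 5)), np.full(5, "IW"), 0.0)
        assert exciton_bandwidth(diagonalize(h)) == 0.0

    def test_uniform_state_ipr(self):
        n = 16
        states = diagonalize(
            ExcitonHamiltonian(np.zeros((n, n)), np.full(n, "IW"), 0.0)
        )
        states.coeffs = np.full((1, n), 1 / np.sqrt(n))
        states.energies = np.zeros(1)
        assert np.isclose(participation_sizes(states)[0], n)

    def test_localized_state_ipr(self):
        states = diagonalize(
            ExcitonHamiltonian(np.diag([0.0, 1.0, 2.0]), np.full(3, "IW"), 0.0)
        )
        assert np.allclose(participation_sizes(states), 1.0)

    def test_ring_bright_state_fully_delocalized(self):
        """On a disorder-free ring the bright state spans all N sites."""
        n = 24
        ring = make_ring(n, 4.0)
        _, states = solve_structure(ring, ExtendedDipoleSpec(0.34, 0.7), e0=0.0)
        bright = int(np.argmax(states.oscillator_strengths))
        assert np.isclose(participation_sizes(states)[bright], n, rtol=1e-6)
        size = delocalization_size(states)
        assert np.isclose(size, n, rtol=1e-6)
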