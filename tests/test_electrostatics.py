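"""Microelectrostatics: Coulomb energies, induction, solvent shifts."""

import numpy as np
import pytest

from excitube import (
    AtomicChargeModel,
    K_COULOMB,
    PolarizableEnvironment,
    carve_cluster,
    coulomb_interaction_energy,
    shift_statistics,
    solve_induced_dipoles,
    solvent_shift,
)
from excitube.electrostatics import InductionError
from excitube.synthetic import (
    dye_charge_model,
    sodium_ion,
    solvated_cluster,
    water_molecule,
)


def point(q, pos, alpha=0.0, label="pt"):
    return AtomicChargeModel(
        positions=np.atleast_2d(pos),
        q_ground=np.array([q]),
        q_excited=np.array([q]),
        alpha=np.array([alpha]),
        label=label,
    )


class TestCoulomb:
    def test_unit_charges_at_one_nm(self):
        e = coulomb_interaction_energy(
            np.zeros((1, 3)), [1.0], np.array([[1.0, 0, 0]]), [1.0]
        )
        assert np.isclose(e, K_COULOMB, rtol=1e-12)
        assert np.isclose(e, 1.1614e4, rtol=1e-4)

    def test_opposite_charges_negative(self):
        e = coulomb_interaction_energy(
            np.zeros((1, 3)), [1.0], np.array([[1.0, 0, 0]]), [-1.0]
        )
        assert np.isclose(e, -K_COULOMB)

    def test_zero_charges(self):
        e = coulomb_interaction_energy(
            np.zeros((2, 3)), [0.0, 0.0], np.ones((3, 3)), [1.0, 1.0, 1.0]
        )
        assert e == 0.0

    def test_overlap_guard_names_pair(self):
        with pytest.raises(ValueError, match=r"A\[0\].*B\[1\]"):
            coulomb_interaction_energy(
                np.zeros((1, 3)), [1.0],
                np.array([[5.0, 0, 0], [0.01, 0, 0]]), [1.0, 1.0],
            )

    def test_rigid_motion_invariance(self, rng):
        """Coulomb energy is invariant under global rotation+translation."""
        pos_a = rng.normal(size=(4, 3))
        pos_b = rng.normal(size=(5, 3)) + 5.0
        q_a = rng.normal(size=4)
        q_b = rng.normal(size=5)
        e0 = coulomb_interaction_energy(pos_a, q_a, pos_b, q_b)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([1.0, -2.0, 3.0])
        e1 = coulomb_interaction_energy(
            pos_a @ rot.T + shift, q_a, pos_b @ rot.T + shift, q_b
        )
        assert np.isclose(e0, e1, rtol=1e-9)


class TestCarve:
    def _mols(self, distances):
        mols = [dye_charge_model()]
        for d in distances:
            mols.append(point(1.0, [d, 0.0, 0.0], label=f"at{d}"))
        return mols

    def test_inclusion_by_cog_distance(self):
        central, env = carve_cluster(self._mols([2.9, 3.1]), 0, radius=3.0)
        assert len(env) == 1
        assert env.sources == ["at2.9"]

    def test_central_excluded(self):
        central, env = carve_cluster(self._mols([1.0]), 0, radius=10.0)
        assert len(env) == 1
        assert central.label == "dye"

    def test_empty_environment(self):
        central, env = carve_cluster([dye_charge_model()], 0, radius=3.0)
        assert len(env) == 0
        assert solvent_shift(central, env) == 0.0

    def test_bad_index(self):
        with pytest.raises(ValueError):
            carve_cluster(self._mols([1.0]), 5, radius=3.0)


class TestInduction:
    def test_single_site_closed_form(self):
        """p = alpha*q/r^2 along the axis; U = -1/2 alpha E^2."""
        q, r, alpha = 0.8, 1.5, 2e-3
        dipoles, energy, _ = solve_induced_dipoles(
            np.zeros((1, 3)), [q], np.array([[r, 0.0, 0.0]]), [alpha]
        )
        field = q / r**2
        assert np.allclose(dipoles, [[alpha * field, 0.0, 0.0]], atol=1e-12)
        assert np.isclose(energy, -0.5 * K_COULOMB * alpha * field**2, rtol=1e-9)

    def test_zero_polarizability(self):
        dipoles, energy, _ = solve_induced_dipoles(
            np.zeros((1, 3)), [1.0], np.ones((3, 3)), [0.0, 0.0, 0.0]
        )
        assert energy == 0.0
        assert np.allclose(dipoles, 0.0)

    def test_two_sites_match_linear_solve(self):
        """Jacobi fixed point equals the direct 6x6 linear-system solution."""
        q = 1.0
        charge_pos = np.zeros((1, 3))
        pol_pos = np.array([[1.2, 0.0, 0.0], [0.0, 1.5, 0.3]])
        alpha = np.array([1.5e-3, 2.5e-3])
        dipoles, energy, _ = solve_induced_dipoles(
            charge_pos, [q], pol_pos, alpha, tolerance=1e-13
        )

        # oracle: solve (I - alpha T) p = alpha E0 exactly
        def field_at(p):
            d = p - charge_pos[0]
            r = np.linalg.norm(d)
            return q * d / r**3

        e0 = np.array([field_at(p) for p in pol_pos]).ravel()
        t = np.zeros((6, 6))
        d = pol_pos[1] - pol_pos[0]
        r = np.linalg.norm(d)
        dyad = (3.0 * np.outer(d, d) / r**2 - np.eye(3)) / r**3
        t[0:3, 3:6] = dyad
        t[3:6, 0:3] = dyad
        a = np.repeat(alpha, 3)
        p_exact = np.linalg.solve(np.eye(6) - a[:, None] * t, a * e0)
        assert np.allclose(dipoles.ravel(), p_exact, atol=1e-10)
        assert np.isclose(energy, -0.5 * K_COULOMB * p_exact @ e0, rtol=1e-8)

    def test_initial_guess_independence(self):
        """Damped updates converge to the same fixed point from any start:
        two solver configurations agree to tolerance."""
        pol_pos = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.7, 0.7, 0.7]])
        alpha = np.full(3, 1e-3)
        _, e1, _ = solve_induced_dipoles(
            np.zeros((1, 3)), [1.0], pol_pos, alpha, damping=0.5, tolerance=1e-12
        )
        _, e2, _ = solve_induced_dipoles(
            np.zeros((1, 3)), [1.0], pol_pos, alpha, damping=0.9, tolerance=1e-12
        )
        assert np.isclose(e1, e2, rtol=1e-9)

    def test_nonconvergence_raises(self):
        with pytest.raises(InductionError):
            solve_induced_dipoles(
                np.zeros((1, 3)), [1.0],
                np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
                [1e-3, 1e-3], tolerance=1e-14, max_iter=1,
            )

    def test_catastrophe_warning(self):
        """Sites inside the (4 a_i a_j)^(1/6) distance are flagged; the
        undamped response there diverges (spectral radius > 1)."""
        with pytest.warns(UserWarning, match="polariz"):
            with pytest.raises(InductionError):
                solve_induced_dipoles(
                    np.zeros((1, 3)), [1.0],
                    np.array([[1.0, 0.0, 0.0], [1.05, 0.0, 0.0]]),
                    [0.3, 0.3], max_iter=50,
                )


class TestSolventShift:
    def test_identical_state_charges_zero_shift(self):
        central = point(0.5, [0.0, 0.0, 0.0])  # ground == excited
        env = PolarizableEnvironment([water_molecule().translated([1.0, 0, 0])])
        assert solvent_shift(central, env) == pytest.approx(0.0, abs=1e-12)

    def test_flipped_dumbbell_shift(self):
        """Excited state flips the central dumbbell: delta = -2 E_ground,
        verified against an explicit hand-summed Coulomb energy."""
        central = AtomicChargeModel(
            positions=np.array([[0.0, 0.0, 0.35], [0.0, 0.0, -0.35]]),
            q_ground=np.array([0.1, -0.1]),
            q_excited=np.array([-0.1, 0.1]),
            alpha=np.zeros(2),
        )
        env = PolarizableEnvironment([point(1.0, [1.0, 0.0, 0.0])])
        r_plus = np.linalg.norm([1.0, 0.0, -0.35])
        r_minus = np.linalg.norm([1.0, 0.0, 0.35])
        e_ground = K_COULOMB * (0.1 / r_plus - 0.1 / r_minus)
        shift = solvent_shift(central, env)
        assert np.isclose(shift, -2.0 * e_ground, rtol=1e-12)

    def test_additivity_without_polarizability(self):
        """Pure electrostatic shifts add over disjoint environment subsets
        (the solvent-vs-aggregate decomposition)."""
        central = dye_charge_model()
        waters = [
            water_molecule().translated([1.2, 0.3, 0.1]),
            water_molecule().translated([-1.1, 0.5, -0.4]),
        ]
        ion = sodium_ion().translated([0.0, 1.3, 0.2])
        for mol in waters + [ion]:
            mol.alpha[:] = 0.0
        env = PolarizableEnvironment(waters + [ion], ["water", "water", "ion"])
        full = solvent_shift(central, env)
        parts = sum(
            solvent_shift(central, env.subset([tag])) for tag in ("water", "ion")
        )
        assert np.isclose(full, parts, rtol=1e-10)

    def test_induction_contributes(self):
        central = dye_charge_model()
        water = water_molecule().translated([1.0, 0.0, 0.0])
        with_pol = solvent_shift(central, PolarizableEnvironment([water]))
        without = solvent_shift(
            central, PolarizableEnvironment([water]), include_induction=False
        )
        assert with_pol != without

    def test_charge_conservation_enforced(self):
        with pytest.raises(ValueError, match="total"):
            AtomicChargeModel(
                positions=np.zeros((2, 3)),
                q_ground=np.array([0.5, -0.5]),
                q_excited=np.array([0.5, 0.0]),
                alpha=np.zeros(2),
            )


class TestShiftStatistics:
    def test_gaussian_recovery(self):
        rng = np.random.default_rng(21)
        shifts = rng.normal(350.0, 213.0, size=10_000)
        dist = shift_statistics(shifts, np.full(10_000, "IW"))
        fit = dist.fits["IW"]
        assert abs(fit["mean"] - 350.0) < 5.0
        assert abs(fit["sigma"] - 213.0) < 4.0

    def test_constant_shifts(self):
        dist = shift_statistics(np.full(50, 42.0), np.full(50, "OW"))
        assert dist.fits["OW"]["sigma"] == 0.0
        assert dist.fits["OW"]["mean"] == 42.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            shift_statistics(np.arange(5.0), np.full(5, "IW"))


class TestSolvatedCluster:
    def test_cluster_is_reproducible_and_clash_free(self):
        central, env = solvated_cluster(
            np.random.default_rng(2), n_water=15, n_ions=1
        )
        central2, env2 = solvated_cluster(
            np.random.default_rng(2), n_water=15, n_ions=1
        )
        assert len(env) == 16
        assert np.array_equal(env.arrays()[0], env2.arrays()[0])
        env_pos = env.arrays()[0]
        from scipy.spatial.distance import cdist

        assert cdist(central.positions, env_pos).min() >= 0.25

    def test_shift_pipeline_produces_finite_values(self):
        rng = np.random.default_rng(8)
        shifts = []
        for _ in range(3):
            central, env = solvated_cluster(rng, n_water=10, n_ions=1)
            shifts.append(solvent_shift(central, env))
        assert np.isfinite(shifts).all()
        assert np.ptp(shifts) > 0  # different environments, different shifts
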