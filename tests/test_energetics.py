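"""Pair potentials, GB/SASA solvation, and the MM/GBSA composition."""

import numpy as np
import pytest
from scipy.integrate import quad

import mdtrend as mt
from mdtrend.energetics import (
    EPS_OUT,
    GB_OFFSET,
    KE,
    SASA_BETA,
    EnergeticsError,
    fibonacci_sphere,
    lj_pair,
    nonpolar_energy,
)


def _params(charges, sigmas=None, epsilons=None, radii=None):
    n = len(charges)
    return mt.ForceFieldParams(
        charge=np.asarray(charges, dtype=float),
        lj_sigma=np.asarray(sigmas if sigmas is not None else [0.3] * n),
        lj_epsilon=np.asarray(epsilons if epsilons is not None else [0.0] * n),
        intrinsic_radius=np.asarray(radii if radii is not None else [0.15] * n),
    )


class TestPairPotentials:
    def test_coulomb_unit_charges(self):
        assert mt.coulomb_pair(1, 1, 0.1) == pytest.approx(1389.35458)

    def test_coulomb_zero_charge_and_antisymmetry(self):
        assert mt.coulomb_pair(0, 1, 0.2) == 0
        assert mt.coulomb_pair(-1, 1, 0.2) == -mt.coulomb_pair(1, 1, 0.2)

    def test_coulomb_singularity(self):
        with pytest.raises(EnergeticsError):
            mt.coulomb_pair(1, 1, 0.0)

    def test_lj_zero_at_sigma_minimum_at_r_min(self):
        assert lj_pair(0.3, 2.0, 0.3) == pytest.approx(0.0, abs=1e-12)
        assert lj_pair(0.3, 2.0, 2 ** (1 / 6) * 0.3) == pytest.approx(-2.0)

    def test_lj_attractive_tail_asymptote(self):
        sigma, eps, r = 0.3, 2.0, 0.9
        tail = -4 * eps * (sigma / r) ** 6
        assert abs(lj_pair(sigma, eps, r) - tail) < 1e-3 * eps


class TestInteractionEnergy:
    def test_two_unit_charges(self):
        frame = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        params = _params([1.0, 1.0])
        a = mt.Selection("a", [0])
        b = mt.Selection("b", [1])
        ele, vdw = mt.interaction_energy(frame, a, b, params)
        assert ele == pytest.approx(1389.35458)
        assert vdw == 0.0

    def test_all_zero_parameters(self, rng):
        frame = rng.normal(size=(6, 3))
        params = _params([0.0] * 6)
        ele, vdw = mt.interaction_energy(
            frame, mt.Selection("a", [0, 1, 2]), mt.Selection("b", [3, 4, 5]),
            params)
        assert (ele, vdw) == (0.0, 0.0)

    def test_overlapping_groups_raise(self, rng):
        frame = rng.normal(size=(4, 3))
        with pytest.raises(EnergeticsError):
            mt.interaction_energy(frame, mt.Selection("a", [0, 1]),
                                  mt.Selection("b", [1, 2]), _params([0.0] * 4))

    def test_matches_triple_loop_oracle(self, rng):
        """Vectorised double sum equals the naive pair loop to 1e-10 rel."""
        frame = rng.normal(size=(10, 3))
        params = _params(rng.uniform(-1, 1, 10), rng.uniform(0.25, 0.35, 10),
                         rng.uniform(0.1, 1.0, 10))
        ia, ib = np.arange(4), np.arange(4, 10)
        ele, vdw = mt.interaction_energy(
            frame, mt.Selection("a", ia), mt.Selection("b", ib), params)
        ele_ref = vdw_ref = 0.0
        for i in ia:
            for j in ib:
                r = np.linalg.norm(frame[i] - frame[j])
                ele_ref += KE * params.charge[i] * params.charge[j] / r
                sig = 0.5 * (params.lj_sigma[i] + params.lj_sigma[j])
                eps = np.sqrt(params.lj_epsilon[i] * params.lj_epsilon[j])
                vdw_ref += lj_pair(sig, eps, r)
        assert ele == pytest.approx(ele_ref, rel=1e-10)
        assert vdw == pytest.approx(vdw_ref, rel=1e-10)

    def test_cutoff_truncates(self, rng):
        frame = np.array([[0, 0, 0], [0.1, 0, 0], [5.0, 0, 0.0]])
        params = _params([1.0, 1.0, 1.0])
        a = mt.Selection("a", [0])
        b = mt.Selection("b", [1, 2])
        full, _ = mt.interaction_energy(frame, a, b, params)
        cut, _ = mt.interaction_energy(frame, a, b, params, cutoff=1.0)
        assert cut == pytest.approx(1389.35458)
        assert full > cut


class TestDecomposition:
    def test_rows_sum_to_total(self, toy_traj, ligand_sel, protein_sel):
        series = mt.per_residue_decomposition(toy_traj, ligand_sel)
        for f in range(toy_traj.n_frames):
            ele, vdw = mt.interaction_energy(
                toy_traj.frames[f], protein_sel, ligand_sel,
                toy_traj.system.params)
            assert series.ele[:, f].sum() == pytest.approx(ele, rel=1e-9)
            assert series.vdw[:, f].sum() == pytest.approx(vdw, rel=1e-9)

    def test_single_charged_residue_only_nonzero_row(self):
        spec = mt.SyntheticSpec(n_residues=5, ligand_atoms=4,
                                key_residues=frozenset({3}), n_frames=2, seed=2)
        system = mt.make_toy_complex(spec)
        params = system.params
        charges = np.zeros_like(params.charge)
        sel3 = mt.select(system, "resid 3-3")
        lig = mt.select(system, "resname LIG")
        charges[sel3.indices] = 0.5
        charges[lig.indices] = -0.5
        quiet = mt.ForceFieldParams(charges, params.lj_sigma * 0 + 0.3,
                                    params.lj_epsilon * 0, params.intrinsic_radius)
        traj = mt.simulate_trajectory(system, spec)
        series = mt.per_residue_decomposition(traj, lig, quiet)
        nonzero = np.abs(series.ele).max(axis=1) > 1e-12
        assert series.residue_numbers[nonzero].tolist() == [3]

    def test_static_trajectory_identical_columns(self, toy_system):
        frames = np.repeat(toy_system.positions[None], 3, axis=0)
        traj = mt.Trajectory(frames, np.arange(3.0), toy_system)
        series = mt.per_residue_decomposition(
            traj, mt.select(toy_system, "resname LIG"))
        assert np.ptp(series.ele, axis=1).max() == pytest.approx(0.0, abs=1e-12)

    def test_ligand_covering_all_atoms_raises(self, toy_traj, toy_system):
        every = mt.Selection("all", np.arange(toy_system.n_atoms))
        with pytest.raises(EnergeticsError):
            mt.per_residue_decomposition(toy_traj, every)


class TestBornRadii:
    def test_isolated_atom_equals_reduced_radius(self):
        params = _params([0.0], radii=[0.15])
        radii = mt.born_radii(np.zeros((1, 3)), params)
        assert radii[0] == pytest.approx(0.15 - GB_OFFSET, rel=1e-12)

    @pytest.mark.parametrize("d", [0.25, 0.35, 0.5])
    def test_two_atom_descreening_matches_quadrature(self, d):
        """HCT analytic integral vs numerical shell quadrature, within 2%.

        The descreening term is (1/4pi) * integral of r^-4 over the part of
        the neighbour sphere outside the self sphere; in spherical shells
        around atom i that is the 1D integral of (shell fraction)/t^2.
        """
        rho_i, rho_j = 0.15 - GB_OFFSET, 0.17 - GB_OFFSET
        params = _params([0.0, 0.0], radii=[0.15, 0.17])
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = mt.born_radii(frame, params, scales=np.ones(2))

        def shell_fraction(t):
            cos = (d * d + t * t - rho_j * rho_j) / (2 * d * t)
            return (1 - np.clip(cos, -1, 1)) / 2

        lo, hi = max(rho_i, d - rho_j), d + rho_j
        integral, _ = quad(lambda t: shell_fraction(t) / t ** 2, lo, hi)
        expected = 1.0 / (1.0 / rho_i - integral)
        assert radii[0] == pytest.approx(expected, rel=0.02)

    def test_distant_atom_changes_nothing(self):
        params2 = _params([0.0, 0.0], radii=[0.15, 0.17])
        params3 = _params([0.0, 0.0, 0.0], radii=[0.15, 0.17, 0.17])
        near = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        far = np.vstack([near, [[12.0, 0, 0]]])
        r2 = mt.born_radii(near, params2, scales=np.ones(2))
        r3 = mt.born_radii(far, params3, scales=np.ones(3))
        assert abs(r3[0] - r2[0]) < 1e-6

    def test_coincident_atoms_raise(self):
        params = _params([0.0, 0.0])
        with pytest.raises(EnergeticsError):
            mt.born_radii(np.zeros((2, 3)), params)


class TestGBPolar:
    def test_born_ion_closed_form(self):
        e = mt.gb_polar(np.zeros((1, 3)), np.array([1.0]), np.array([0.2]))
        expected = -0.5 * KE * (1 - 1 / EPS_OUT) / 0.2
        assert e == pytest.approx(expected, rel=1e-12)

    def test_zero_charges_and_vacuum_limit(self, rng):
        frame = rng.normal(size=(4, 3))
        radii = np.full(4, 0.2)
        assert mt.gb_polar(frame, np.zeros(4), radii) == 0.0
        q = rng.uniform(-1, 1, 4)
        assert mt.gb_polar(frame, q, radii, eps_in=5.0, eps_out=5.0) == 0.0

    def test_fgb_approaches_coulomb_at_large_separation(self):
        """Cross term tends to the screened Coulomb pair energy as r >> R."""
        R = 0.2
        r = 100 * R
        frame = np.array([[0.0, 0, 0], [r, 0, 0]])
        q = np.array([1.0, -1.0])
        radii = np.array([R, R])
        total = mt.gb_polar(frame, q, radii)
        self_terms = sum(
            mt.gb_polar(np.zeros((1, 3)), q[[i]], radii[[i]]) for i in range(2)
        )
        cross = total - self_terms
        coulomb_screened = -KE * (1 - 1 / EPS_OUT) * (q[0] * q[1]) / r
        assert cross == pytest.approx(coulomb_screened, rel=1e-4)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        params = _params([0.0], radii=[0.17])
        area = mt.sasa(np.zeros((1, 3)), params, probe=0.14, n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * 0.31 ** 2, rel=0.01)

    def test_buried_atom_zero(self):
        # central atom caged by 26 neighbours on a tight lattice
        offsets = [np.array([i, j, k]) * 0.15
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        frame = np.vstack([[0.0, 0, 0], offsets])
        params = _params([0.0] * 27, radii=[0.17] * 27)
        area = mt.sasa(frame, params, probe=0.14, n_points=480)
        assert area[0] == 0.0

    def test_total_decreases_as_atoms_approach(self):
        params = _params([0.0, 0.0], radii=[0.17, 0.17])
        totals = []
        for d in np.linspace(1.0, 0.2, 9):
            frame = np.array([[0.0, 0, 0], [d, 0, 0]])
            totals.append(mt.sasa(frame, params, n_points=960).sum())
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_point_count_convergence(self, toy_system):
        a1 = mt.sasa(toy_system.positions, toy_system.params, n_points=960).sum()
        a2 = mt.sasa(toy_system.positions, toy_system.params, n_points=1920).sum()
        assert abs(a2 - a1) / a1 < 0.005

    def test_matches_independent_shrake_rupley(self, toy_system):
        """Cross-check against biotite's Shrake–Rupley implementation."""
        import biotite.structure as struc

        array = struc.AtomArray(toy_system.n_atoms)
        array.coord = toy_system.positions * 10.0
        array.atom_name = toy_system.names
        array.element = toy_system.elements
        array.res_id = toy_system.residue_numbers
        array.res_name = toy_system.residue_names
        array.chain_id = toy_system.chain_ids
        array.set_annotation("hetero", toy_system.residue_names == "LIG")
        ref = struc.sasa(
            array, probe_radius=1.4, point_number=960,
            vdw_radii=toy_system.params.intrinsic_radius * 10.0,
        )
        mine = mt.sasa(toy_system.positions, toy_system.params,
                       probe=0.14, n_points=960)
        # different deterministic point sets: agree to a few percent in total
        assert mine.sum() * 100.0 == pytest.approx(np.nansum(ref), rel=0.03)

    def test_fibonacci_sphere_is_unit_and_even(self):
        pts = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert abs(pts.mean(axis=0)).max() < 0.01


class TestNonpolar:
    def test_linear_model(self):
        assert nonpolar_energy(0.0) == pytest.approx(SASA_BETA)
        assert nonpolar_energy(2.0) - SASA_BETA == pytest.approx(
            2 * (nonpolar_energy(1.0) - SASA_BETA))
        assert nonpolar_energy(1.0, gamma=0.0, beta=0.0) == 0.0


class TestEnergyBreakdown:
    def test_identities_enforced(self):
        bd = mt.EnergyBreakdown(dE_ele=-10.0, dE_vdw=-5.0, dG_polar=8.0,
                                dG_nonpolar=-1.0)
        assert bd.dE_MM == pytest.approx(-15.0)
        assert bd.dG_sol == pytest.approx(7.0)
        assert bd.dG == pytest.approx(-8.0)

    def test_violating_identity_raises(self):
        with pytest.raises(EnergeticsError):
            mt.EnergyBreakdown(dE_ele=-10.0, dE_vdw=-5.0, dG_polar=8.0,
                               dG_nonpolar=-1.0, dE_MM=3.0)


class TestMmgbsa:
    def _two_particle(self, separation):
        system = mt.MolecularSystem(
            names=["C1", "L1"], elements=["C", "C"],
            residue_numbers=[1, 2], residue_names=["ALA", "LIG"],
            chain_ids=["A", "B"],
            positions=np.array([[0.0, 0, 0], [separation, 0, 0]]),
            params=_params([0.5, -0.5], [0.3, 0.3], [0.4, 0.4], [0.17, 0.17]),
        )
        frames = system.positions[None]
        return mt.Trajectory(frames, np.zeros(1), system), system

    def test_all_zero_parameters_give_zero_terms(self, rng):
        traj, system = self._two_particle(0.5)
        quiet = _params([0.0, 0.0], [0.3, 0.3], [0.0, 0.0], [0.17, 0.17])
        bd, _ = mt.mmgbsa(traj, mt.Selection("r", [0]), mt.Selection("l", [1]),
                          quiet, n_points=240)
        assert bd.dE_ele == 0.0 and bd.dE_vdw == 0.0 and bd.dG_polar == 0.0

    def test_separated_ligand_has_no_interaction(self):
        """Neutral receptor/ligand translated 100 nm apart interact ~zero."""
        system = mt.MolecularSystem(
            names=["C1", "C2", "L1", "L2"], elements=["C"] * 4,
            residue_numbers=[1, 1, 2, 2],
            residue_names=["ALA", "ALA", "LIG", "LIG"],
            chain_ids=["A", "A", "B", "B"],
            positions=np.array([
                [0.0, 0, 0], [0.05, 0, 0], [100.0, 0, 0], [100.05, 0, 0],
            ]),
            params=_params([0.5, -0.5, 0.5, -0.5], [0.3] * 4, [0.4] * 4,
                           [0.17] * 4),
        )
        traj = mt.Trajectory(system.positions[None], np.zeros(1), system)
        bd, _ = mt.mmgbsa(traj, mt.Selection("r", [0, 1]),
                          mt.Selection("l", [2, 3]), n_points=240)
        assert abs(bd.dE_ele) < 1e-6
        assert abs(bd.dE_vdw) < 1e-6
        # SASA of the parts equals the complex, leaving only the constant
        assert bd.dG_nonpolar == pytest.approx(-SASA_BETA, abs=1e-9)

    def test_two_particle_terms_match_direct_recomputation(self):
        from mdtrend.energetics import born_radii, gb_polar, hct_scales

        traj, system = self._two_particle(0.4)
        bd, table = mt.mmgbsa(traj, mt.Selection("r", [0]),
                              mt.Selection("l", [1]), n_points=480)
        assert bd.dE_ele == pytest.approx(mt.coulomb_pair(0.5, -0.5, 0.4))

        params = system.params
        scales = hct_scales(system.elements)
        frame = system.positions
        gb_c = gb_polar(frame, params.charge,
                        born_radii(frame, params, scales))
        gb_parts = sum(
            gb_polar(frame[[i]], params.charge[[i]],
                     born_radii(frame[[i]], _params(
                         [params.charge[i]], radii=[0.17]), scales[[i]]))
            for i in range(2)
        )
        assert bd.dG_polar == pytest.approx(gb_c - gb_parts, rel=1e-9)

    def test_breakdown_identities_on_toy_complex(self, toy_traj, toy_system):
        receptor = mt.select(toy_system, "protein")
        ligand = mt.select(toy_system, "resname LIG")
        bd, table = mt.mmgbsa(toy_traj, receptor, ligand, frame_range=(0, 2),
                              n_points=240)
        assert bd.dG == pytest.approx(bd.dE_MM + bd.dG_sol - bd.TdS, rel=1e-12)
        assert bd.dE_MM == pytest.approx(bd.dE_vdw + bd.dE_ele + bd.dE_bonded,
                                         rel=1e-12)
        assert bd.dG_sol == pytest.approx(bd.dG_polar + bd.dG_nonpolar,
                                          rel=1e-12)
        assert bd.dE_bonded == 0.0 and bd.TdS == 0.0

    def test_empty_frame_range_raises(self, toy_traj, toy_system):
        with pytest.raises(EnergeticsError):
            mt.mmgbsa(toy_traj, mt.select(toy_system, "protein"),
                      mt.select(toy_system, "resname LIG"), frame_range=(2, 2))
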