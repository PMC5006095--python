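"""Finite-difference PB solver: grids, maps, Born oracle, focusing, identities."""

import numpy as np
import pytest

from dmmpbsa import (
    AtomRecord,
    PBParams,
    Structure,
    assign_maps,
    born_ion,
    build_grids,
    merge,
    polar_energy,
    polar_solvation,
    solve,
)
from dmmpbsa.pb_solver import PBError, debye_huckel_boundary, solute_mask

COULOMB = 1389.354


def born_exact(q, radius, eps_int=2.0, eps_ext=80.0):
    return -(COULOMB * q * q / (2 * radius)) * (1 / eps_int - 1 / eps_ext)


def dimer(d=6.0, q=0.5):
    """Two opposite charges d apart -- a minimal polar binding toy."""
    a = Structure([AtomRecord(1, "A1", "TOY", "A", 1, np.zeros(3), q, 1.8)])
    b = Structure([AtomRecord(2, "B1", "TOY", "B", 1, np.array([d, 0.0, 0.0]), -q, 1.8)])
    return merge(a, b), a, b


class TestGrids:
    def test_padding_and_containment(self, toy):
        complex_, _ = toy
        params = PBParams(grid_spacing=0.5)
        coarse, fine = build_grids(complex_, params)
        lo, hi = complex_.coords.min(axis=0), complex_.coords.max(axis=0)
        assert np.all(np.asarray(fine.origin) <= lo - 10.0 + 1e-9)
        assert np.all(np.asarray(fine.upper) >= hi + 10.0 - 1e-9)
        assert np.all(np.asarray(coarse.origin) <= np.asarray(fine.origin))
        assert coarse.contains(fine)
        assert fine.spacing <= 0.5

    def test_box_size_yields_enough_points(self):
        s = Structure([
            AtomRecord(1, "A", "T", "A", 1, np.zeros(3), 0.0, 1.0),
            AtomRecord(2, "B", "T", "A", 2, np.full(3, 10.0), 0.0, 1.0),
        ])
        _, fine = build_grids(s, PBParams(grid_spacing=0.5, fine_pad=10.0))
        # 10 A extent + 2 x 10 A pad at 0.5 A needs > 61 nodes per axis
        assert all(n >= 61 for n in fine.npoints)

    def test_single_atom_grids_centred(self):
        coarse, fine = build_grids(born_ion(1.0, 2.0), PBParams())
        for g in (coarse, fine):
            centre = np.asarray(g.origin) + g.spacing * (np.asarray(g.npoints) - 1) / 2
            np.testing.assert_allclose(centre, 0.0, atol=1e-9)
            assert len(set(g.npoints)) == 1  # cubic by symmetry


class TestMaps:
    def test_dielectric_inside_and_outside(self):
        ion = born_ion(1.0, 2.0)
        params = PBParams(salt=0.0)
        _, fine = build_grids(ion, params)
        eps, _, _ = assign_maps(ion, fine, params)
        ax = fine.axes()
        centre_idx = tuple(int(np.argmin(np.abs(a))) for a in ax)
        assert eps[centre_idx] == params.eps_int
        assert eps[0, 0, 0] == params.eps_ext

    def test_charge_conservation(self, toy):
        complex_, _ = toy
        params = PBParams()
        _, fine = build_grids(complex_, params)
        _, _, charge = assign_maps(complex_, fine, params)
        assert charge.sum() == pytest.approx(complex_.total_charge, abs=1e-9)

    def test_zero_salt_zero_screening(self):
        ion = born_ion(1.0, 2.0)
        params = PBParams(salt=0.0)
        _, fine = build_grids(ion, params)
        _, kappa2, _ = assign_maps(ion, fine, params)
        assert not np.any(kappa2)

    def test_stern_layer_excludes_ions(self):
        ion = born_ion(1.0, 2.0)
        params = PBParams(salt=0.15)
        _, fine = build_grids(ion, params)
        _, kappa2, _ = assign_maps(ion, fine, params)
        ax = fine.axes()
        centre_idx = tuple(int(np.argmin(np.abs(a))) for a in ax)
        assert kappa2[centre_idx] == 0.0       # inside radius + Stern layer
        assert kappa2[0, 0, 0] > 0.0           # bulk solvent

    def test_atom_outside_grid_is_error(self):
        ion = born_ion(1.0, 2.0)
        _, fine = build_grids(ion, PBParams())
        far = Structure([AtomRecord(1, "X", "T", "A", 1, np.array([500.0, 0, 0]), 1.0, 2.0)])
        with pytest.raises(PBError, match="outside"):
            assign_maps(far, fine, PBParams())

    def test_probe_shell_reverts_to_solvent(self):
        # for an isolated atom every node in the shell r < d < r + probe is
        # probe-reachable and must revert to solvent in pass 2, leaving the
        # solute volume equal to the bare atom sphere
        s = born_ion(0.0, 1.5)
        _, fine = build_grids(s, PBParams(grid_spacing=0.25, fine_pad=6, coarse_pad=12))
        mask = solute_mask(s, fine, probe_radius=1.4)
        ax = fine.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        d = np.sqrt(xx**2 + yy**2 + zz**2)
        shell = (d > 1.5 + 0.3) & (d < 2.9 - 0.3)  # strict shell interior
        core = d < 1.5 - 0.3
        assert not mask[shell].any()
        assert mask[core].all()


class TestSolve:
    def test_uncharged_structure_zero_potential(self, fast_pb):
        s = born_ion(0.0, 2.0)
        _, fine = build_grids(s, fast_pb)
        sol = solve(s, fine, fast_pb)
        assert sol.g_elec == 0.0
        assert not np.any(sol.potential)

    def test_mirror_symmetric_charges_give_mirror_potential(self, fast_pb):
        s = Structure([
            AtomRecord(1, "A", "T", "A", 1, np.array([-2.0, 0, 0]), 1.0, 1.6),
            AtomRecord(2, "B", "T", "A", 2, np.array([+2.0, 0, 0]), 1.0, 1.6),
        ])
        _, fine = build_grids(s, fast_pb)
        sol = solve(s, fine, fast_pb)
        np.testing.assert_allclose(sol.potential, sol.potential[::-1, :, :], atol=1e-6)

    def test_nonlinear_close_to_linear_for_born_ion(self):
        ion = born_ion(1.0, 2.0)
        base = dict(grid_spacing=0.5, fine_pad=8, coarse_pad=16, salt=0.15)
        p_lin = PBParams(nonlinear=False, **base)
        p_non = PBParams(nonlinear=True, **base)
        g_lin = polar_energy(ion, *build_grids(ion, p_lin), p_lin)
        g_non = polar_energy(ion, *build_grids(ion, p_non), p_non)
        assert g_non == pytest.approx(g_lin, rel=0.005)

    def test_debye_huckel_boundary_decays_with_salt(self):
        ion = born_ion(1.0, 2.0)
        coarse, _ = build_grids(ion, PBParams())
        u0 = debye_huckel_boundary(ion, coarse, PBParams(salt=0.0))
        u1 = debye_huckel_boundary(ion, coarse, PBParams(salt=0.15))
        assert 0 < u1[0, 0, 0] < u0[0, 0, 0]


class TestBornOracle:
    def test_born_energy_close_to_closed_form(self):
        params = PBParams(salt=0.0, grid_spacing=0.25, nonlinear=False)
        ion = born_ion(1.0, 2.0)
        g = polar_energy(ion, *build_grids(ion, params), params)
        assert g == pytest.approx(born_exact(1.0, 2.0), rel=0.03)

    def test_charge_scaling_quadratic(self):
        params = PBParams(salt=0.0, grid_spacing=0.5, nonlinear=False,
                          fine_pad=8, coarse_pad=16)
        g1 = polar_energy(born_ion(1.0, 2.0), *build_grids(born_ion(1.0, 2.0), params), params)
        g2 = polar_energy(born_ion(2.0, 2.0), *build_grids(born_ion(2.0, 2.0), params), params)
        assert g2 == pytest.approx(4.0 * g1, rel=0.01)

    def test_focusing_consistent_when_coarse_matches_target(self):
        params = PBParams(salt=0.0, grid_spacing=0.5, nonlinear=False,
                          coarse_spacing_factor=1.0, fine_pad=8, coarse_pad=16)
        ion = born_ion(1.0, 2.0)
        coarse, fine = build_grids(ion, params)
        focused = polar_energy(ion, coarse, fine, params)
        direct_solv = solve(ion, fine, params, boundary="debye-huckel")
        direct_dry = solve(ion, fine, params, boundary="uniform", uniform=True)
        direct = direct_solv.g_elec - direct_dry.g_elec
        assert focused == pytest.approx(direct, rel=0.01)


class TestPolarBinding:
    def test_uncharged_states_give_zero(self, fast_pb):
        complex_, a, b = dimer(q=0.0)
        res = polar_solvation(complex_, a, b, fast_pb)
        assert res.g_polar_complex == 0.0
        assert res.dg_polar == 0.0

    def test_difference_identity_exact(self, fast_pb):
        complex_, a, b = dimer()
        res = polar_solvation(complex_, a, b, fast_pb)
        assert res.dg_polar == pytest.approx(
            res.g_polar_complex - res.g_polar_receptor - res.g_polar_peptide, abs=1e-9
        )
        # separating opposite charges into solvent is favourable per state
        assert res.g_polar_complex < 0

    def test_matched_dielectrics_give_zero(self):
        params = PBParams(salt=0.0, eps_int=2.0, eps_ext=2.0 + 1e-9, nonlinear=False,
                          grid_spacing=0.8, fine_pad=6, coarse_pad=12)
        complex_, a, b = dimer()
        res = polar_solvation(complex_, a, b, params)
        assert abs(res.g_polar_complex) < 1e-2
        assert abs(res.dg_polar) < 1e-2

    def test_inconsistent_partition_rejected(self, fast_pb):
        complex_, a, b = dimer()
        with pytest.raises(ValueError, match="partition"):
            polar_solvation(complex_, a, a, fast_pb)

    def test_grid_translation_robustness(self):
        params = PBParams(salt=0.0, grid_spacing=0.25, nonlinear=False,
                          fine_pad=6, coarse_pad=12)
        complex_, a, b = dimer()
        res0 = polar_solvation(complex_, a, b, params)

        def shifted(s, delta):
            return Structure([
                AtomRecord(at.serial, at.name, at.residue_name, at.chain_id,
                           at.residue_index, at.position + delta, at.charge, at.radius)
                for at in s.atoms
            ], title=s.title)

        delta = np.array([0.125, 0.125, 0.125])  # half a grid cell
        res1 = polar_solvation(shifted(complex_, delta), shifted(a, delta),
                               shifted(b, delta), params)
        assert abs(res1.dg_polar - res0.dg_polar) < 2.0
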