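"""Interacting-induced-dipole model: tensors, response, coarse-graining."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iedrf.environment import (PointCharge, PolarizableEnvironment,
                               PolarizableSite)
from iedrf.polarization import (PolarizationCatastropheError,
                                SingularGeometryError,
                                build_dipole_field_tensor,
                                build_effective_polarizability, coarse_grain,
                                dipole_tensor_derivative, induced_dipoles,
                                molecular_polarizability, point_charge_fields,
                                polarization_energy)

from conftest import random_sites, rotation_matrix


class TestDipoleFieldTensor:
    def test_axial_pair_is_standard_point_dipole_tensor(self):
        sites = [PolarizableSite([0, 0, 0], 1.0), PolarizableSite([0, 0, 2.0], 1.0)]
        T = build_dipole_field_tensor(sites, damped=False)
        np.testing.assert_allclose(T.blocks[0, 1],
                                   np.diag([-1.0, -1.0, 2.0]) / 8.0, atol=1e-15)

    def test_block_symmetry(self, rng):
        sites = random_sites(rng, 4)
        T = build_dipole_field_tensor(sites)
        for i in range(4):
            for j in range(4):
                np.testing.assert_allclose(T.blocks[i, j], T.blocks[j, i].T,
                                           atol=1e-14)
                np.testing.assert_allclose(T.blocks[i, j], T.blocks[i, j].T,
                                           atol=1e-14)

    def test_damped_blocks_finite_at_close_approach(self):
        a_i, a_j = 1.0, 1.3
        sites = [PolarizableSite([0, 0, 0], a_i), PolarizableSite([0, 0, 0.1], a_j)]
        T = build_dipole_field_tensor(sites)
        assert np.all(np.isfinite(T.blocks))
        # r -> 0 limit of the Thole-damped tensor is -a/sqrt(ai*aj) * identity
        bound = 2.0 * 2.1304 / np.sqrt(a_i * a_j)
        assert np.abs(T.blocks[0, 1]).max() <= bound
        diag = np.diag(T.blocks[0, 1])
        assert np.allclose(diag[:2], -2.1304 / np.sqrt(a_i * a_j), rtol=0.2)

    def test_coincident_sites_without_damping_raise(self):
        sites = [PolarizableSite([0, 0, 0], 1.0), PolarizableSite([0, 0, 0], 1.0)]
        with pytest.raises(SingularGeometryError):
            build_dipole_field_tensor(sites, damped=False)


class TestEffectivePolarizability:
    def test_single_site_is_isotropic_atomic_polarizability(self):
        sites = [PolarizableSite([0.3, -0.2, 1.0], 1.5)]
        A = build_effective_polarizability(
            sites, build_dipole_field_tensor(sites))
        np.testing.assert_allclose(A.A, 1.5 * np.eye(3), atol=1e-14)

    def test_two_site_closed_form_response(self):
        # uniform field along the axis: total moment 2 alpha / (1 - 2 alpha/r^3)
        alpha, r = 1.0, 10.0
        sites = [PolarizableSite([0, 0, 0], alpha), PolarizableSite([0, 0, r], alpha)]
        A = build_effective_polarizability(
            sites, build_dipole_field_tensor(sites, damped=False))
        f = np.tile([0.0, 0.0, 1.0], 2)
        p = induced_dipoles(A, f)
        expected = 2.0 * alpha / (1.0 - 2.0 * alpha / r ** 3)
        assert abs((p[2] + p[5]) - expected) / expected < 1e-12

    def test_small_alpha_limit_vanishes(self):
        sites = [PolarizableSite([0, 0, 0], 1e-9), PolarizableSite([0, 0, 3.0], 1e-9)]
        A = build_effective_polarizability(
            sites, build_dipole_field_tensor(sites, damped=False))
        assert np.abs(A.A).max() < 1e-8

    def test_matches_explicit_coupled_equations(self, rng):
        # independent oracle: solve (1 - alpha T) p = alpha f directly
        for n in (2, 5, 12, 20):
            sites = random_sites(rng, n)
            T = build_dipole_field_tensor(sites)
            A = build_effective_polarizability(sites, T).A
            f = rng.normal(size=3 * n)
            p = A @ f
            M = np.eye(3 * n)
            for i in range(n):
                for j in range(n):
                    if i != j:
                        M[3 * i:3 * i + 3, 3 * j:3 * j + 3] = \
                            -sites[i].alpha * T.blocks[i, j]
            p_ref = np.linalg.solve(M, np.repeat([s.alpha for s in sites], 3) * f)
            assert np.abs(p - p_ref).max() / np.abs(p_ref).max() < 1e-10

    def test_symmetry_and_psd(self, rng):
        sites = random_sites(rng, 6)
        A = build_effective_polarizability(
            sites, build_dipole_field_tensor(sites)).A
        np.testing.assert_allclose(A, A.T, atol=1e-13)
        assert np.linalg.eigvalsh(A).min() > -1e-12

    def test_polarization_catastrophe_names_pair(self):
        sites = [PolarizableSite([0, 0, 0], 8.0, tag=7),
                 PolarizableSite([0, 0, 1.2], 8.0, tag=8),
                 PolarizableSite([0, 0, 8.0], 1.0, tag=9)]
        tensor = build_dipole_field_tensor(sites, damped=False)
        with pytest.raises(PolarizationCatastropheError, match="7.*8"):
            build_effective_polarizability(sites, tensor, cond_limit=1e3)


class TestFieldsAndEnergy:
    def test_single_charge_coulomb_field_with_sign(self):
        # +1 charge at distance r below the site: field points up (+z)
        site = PolarizableSite([0, 0, 0], 1.0, damping_radius=0.1, tag=0)
        chg = PointCharge([0, 0, -4.0], 1.0, tag=1)
        f = point_charge_fields([chg], [site])
        np.testing.assert_allclose(f, [0, 0, 1.0 / 16.0], rtol=1e-6)

    def test_excluded_charge_contributes_nothing(self):
        site = PolarizableSite([0, 0, 0], 1.0, tag=0)
        chg = PointCharge([0, 0, -4.0], 1.0, exclusion_ids={0}, tag=1)
        np.testing.assert_allclose(point_charge_fields([chg], [site]), 0.0)

    def test_two_symmetric_charges_add(self):
        site = PolarizableSite([0, 0, 0], 1.0, damping_radius=0.1, tag=0)
        up = PointCharge([0, 0, 4.0], 1.0, tag=1)
        dn = PointCharge([0, 0, -4.0], -1.0, tag=2)
        f = point_charge_fields([up, dn], [site])
        single = point_charge_fields([up], [site])
        np.testing.assert_allclose(f, 2.0 * single, rtol=1e-12)

    def test_energy_identity_and_sign(self, rng):
        sites = random_sites(rng, 5)
        A = build_effective_polarizability(
            sites, build_dipole_field_tensor(sites)).A
        for _ in range(5):
            f = rng.normal(size=15)
            e = polarization_energy(A, f)
            assert e <= 0.0
            assert abs(e - (-0.5 * f @ induced_dipoles(A, f))) < 1e-12

    def test_single_site_energy_value(self):
        A = 2.0 * np.eye(3)
        assert abs(polarization_energy(A, [0, 0, 1.0]) + 1.0) < 1e-15
        assert polarization_energy(A, np.zeros(3)) == 0.0

    def test_energy_rotation_invariance(self, rng):
        sites = random_sites(rng, 4)
        charges = [PointCharge(rng.normal(scale=6.0, size=3),
                               float(rng.uniform(-0.5, 0.5)), tag=100 + k)
                   for k in range(3)]
        Q = rotation_matrix(rng)

        def energy(sts, chgs):
            A = build_effective_polarizability(
                sts, build_dipole_field_tensor(sts)).A
            return polarization_energy(A, point_charge_fields(chgs, sts))

        e1 = energy(sites, charges)
        sites_r = [PolarizableSite(Q @ s.position, s.alpha, s.damping_radius,
                                   s.tag) for s in sites]
        charges_r = [PointCharge(Q @ c.position, c.charge, c.exclusion_ids,
                                 c.tag) for c in charges]
        e2 = energy(sites_r, charges_r)
        assert abs(e1 - e2) < 1e-12 * max(abs(e1), 1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(alpha=st.floats(0.2, 3.0), r=st.floats(4.0, 20.0),
       fz=st.floats(-2.0, 2.0))
def test_axial_two_site_response_closed_form(alpha, r, fz):
    """Anywhere in the stable regime, the axial response follows the
    closed-form geometric series of the two-dipole problem."""
    sites = [PolarizableSite([0, 0, 0], alpha), PolarizableSite([0, 0, r], alpha)]
    A = build_effective_polarizability(
        sites, build_dipole_field_tensor(sites, damped=False))
    p = induced_dipoles(A, np.tile([0.0, 0.0, fz], 2))
    expected = 2.0 * alpha * fz / (1.0 - 2.0 * alpha / r ** 3)
    assert abs((p[2] + p[5]) - expected) <= 1e-10 * max(1.0, abs(expected))


class TestDipoleTensorDerivative:
    def test_matches_finite_differences(self, rng):
        sites = random_sites(rng, 2)
        h = 1e-6
        an = dipole_tensor_derivative(sites, 0, 1)
        for g in range(3):
            d = np.zeros(3); d[g] = h
            sp = [sites[0], PolarizableSite(sites[1].position + d, sites[1].alpha)]
            sm = [sites[0], PolarizableSite(sites[1].position - d, sites[1].alpha)]
            fd = (build_dipole_field_tensor(sp).blocks[0, 1]
                  - build_dipole_field_tensor(sm).blocks[0, 1]) / (2 * h)
            np.testing.assert_allclose(an[g], fd, atol=1e-8)


class TestCoarseGraining:
    def _shell(self, rng, n_mol=3, far=12.0):
        sites, charges = [], []
        for m in range(n_mol):
            c = rng.normal(size=3)
            c = far * c / np.linalg.norm(c)
            axis = rng.normal(size=3); axis /= np.linalg.norm(axis)
            for k, (dq, al) in enumerate(zip((-0.1, 0.2, -0.1), (1.0, 1.5, 1.0))):
                pos = c + (k - 1) * 2.0 * axis
                tag = 10 * m + k
                sites.append(PolarizableSite(pos, al, tag=tag, molecule=m))
                charges.append(PointCharge(pos, dq, exclusion_ids={10 * m, 10 * m + 1, 10 * m + 2}, tag=tag, molecule=m))
        return PolarizableEnvironment(sites, charges)

    def test_all_near_molecules_untouched(self, rng):
        env = self._shell(rng)
        out = coarse_grain(env, np.zeros((1, 3)), cutoff=50.0)
        assert len(out.sites) == len(env.sites)

    def test_far_molecules_become_single_sites(self, rng):
        env = self._shell(rng, n_mol=3)
        out = coarse_grain(env, np.zeros((1, 3)), cutoff=5.0)
        assert len(out.sites) == 3
        assert len(out.charges) == len(env.charges)

    def test_scalar_polarizability_rotation_invariant(self, rng):
        sites = [PolarizableSite([0, 0, 0], 1.0, molecule=0, tag=0),
                 PolarizableSite([0, 0, 2.0], 1.5, molecule=0, tag=1),
                 PolarizableSite([1.8, 0, 1.0], 0.8, molecule=0, tag=2)]
        base = np.linalg.eigvalsh(molecular_polarizability(sites)).mean()
        for _ in range(5):
            Q = rotation_matrix(rng)
            rot = [PolarizableSite(Q @ s.position, s.alpha, tag=s.tag,
                                   molecule=0) for s in sites]
            val = np.linalg.eigvalsh(molecular_polarizability(rot)).mean()
            assert abs(val - base) < 1e-10

    def test_single_atom_molecule_keeps_atomic_alpha(self):
        env = PolarizableEnvironment(
            [PolarizableSite([20.0, 0, 0], 1.3, tag=0, molecule=0)])
        out = coarse_grain(env, np.zeros((1, 3)), cutoff=5.0)
        assert len(out.sites) == 1
        assert abs(out.sites[0].alpha - 1.3) < 1e-14

    def test_far_test_charge_energy_almost_unchanged(self):
        # designed far-shell fixture: weakly coupled linear molecules many
        # molecular diameters from the probe (grouping-error analysis in the
        # methods note)
        from iedrf.fixtures import far_shell_fixture
        env = far_shell_fixture(5, n_molecules=40)
        probe = [PointCharge([0, 0, 0], 1.0, tag=999)]

        def epol(e):
            A = build_effective_polarizability(
                e.sites, build_dipole_field_tensor(e.sites)).A
            f = point_charge_fields(probe, e.sites)
            return polarization_energy(A, f)

        e_full = epol(env)
        e_cg = epol(coarse_grain(env, np.zeros((1, 3)), cutoff=9.45))
        assert abs(e_cg - e_full) <= 0.01 * abs(e_full)
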