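"""Gaussian integral engines vs the independent quadrature oracle."""

import numpy as np
import pytest

from iedrf.basis import BasisShell, build_shells
from iedrf.damping import DampingFunction
from iedrf.fixtures import h2
from iedrf.geometry import Molecule
from iedrf.integrals import (cpp_integrals, damped_field_integrals,
                             electron_repulsion, kinetic, nuclear_attraction,
                             overlap, overlap_kinetic_nuclear)
from iedrf.integrals.one_electron import charge_attraction
from iedrf.integrals.quadrature import (QuadratureError,
                                        adaptive_spherical_quadrature,
                                        basis_function_values,
                                        quadrature_coulomb,
                                        quadrature_cpp_integral,
                                        quadrature_field_integral,
                                        quadrature_kinetic, quadrature_overlap)

from conftest import random_shell


def s_shell(center, exps, coefs):
    return BasisShell(center=np.asarray(center, float), l=0,
                      exps=np.asarray(exps, float), coefs=np.asarray(coefs, float))


class TestOverlapKineticNuclear:
    def test_single_normalized_s_function(self):
        sh = [s_shell([0, 0, 0], [0.8], [1.0])]
        np.testing.assert_allclose(overlap(sh), [[1.0]], atol=1e-14)

    def test_duplicate_basis_is_singular(self):
        sh = [s_shell([0, 0, 0], [0.8], [1.0]), s_shell([0, 0, 0], [0.8], [1.0])]
        S = overlap(sh)
        assert abs(S[0, 1] - 1.0) < 1e-14
        mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
        *_, min_eig = overlap_kinetic_nuclear(sh, mol)
        assert min_eig < 1e-12

    def test_h2_matrices_match_quadrature(self, h2_molecule, h2_shells):
        S = overlap(h2_shells)
        T = kinetic(h2_shells)
        V1 = charge_attraction(h2_shells, [h2_molecule.coords[0]], [1.0])
        for (i, j) in ((0, 0), (0, 1), (1, 1)):
            ov, _ = quadrature_overlap(h2_shells[i], 0, h2_shells[j], 0, tol=1e-11)
            assert abs(ov - S[i, j]) < 1e-8
            tv, _ = quadrature_kinetic(h2_shells[i], 0, h2_shells[j], 0)
            assert abs(tv - T[i, j]) < 1e-6  # FD-Laplacian oracle accuracy
            cv, _ = quadrature_coulomb(h2_shells[i], 0, h2_shells[j], 0,
                                       h2_molecule.coords[0], tol=1e-11)
            assert abs(-cv - V1[i, j]) < 1e-8

    def test_p_function_blocks_against_quadrature(self, rng):
        shells = [random_shell(rng, l=1), random_shell(rng, l=0)]
        S = overlap(shells)
        for comp in range(3):
            ov, _ = quadrature_overlap(shells[0], comp, shells[1], 0, tol=1e-11)
            assert abs(ov - S[comp, 3]) < 1e-8

    def test_translation_invariance(self, rng, h2_molecule):
        shift = rng.normal(size=3)
        mol2 = Molecule(["H", "H"], h2_molecule.coords + shift)
        s1 = build_shells(h2_molecule)
        s2 = build_shells(mol2)
        np.testing.assert_allclose(overlap(s1), overlap(s2), atol=1e-13)
        np.testing.assert_allclose(nuclear_attraction(s1, h2_molecule),
                                   nuclear_attraction(s2, mol2), atol=1e-12)


class TestElectronRepulsion:
    def test_self_repulsion_positive(self):
        sh = [s_shell([0, 0, 0], [0.8], [1.0])]
        assert electron_repulsion(sh)[0, 0, 0, 0] > 0

    def test_permutational_symmetry(self, rng):
        shells = [random_shell(rng, l=0), random_shell(rng, l=1)]
        eri = electron_repulsion(shells)
        np.testing.assert_allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-13)
        np.testing.assert_allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-13)
        np.testing.assert_allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-13)

    def test_h2_value_against_erf_potential_oracle(self, h2_shells):
        """(mu nu|la si) for s pairs equals the 3-D quadrature of the bra
        density against the analytic erf-form potential of the ket density."""
        eri = electron_repulsion(h2_shells)

        def ket_potential(pts, shk, shl):
            out = np.zeros(len(pts))
            for ak, ck in zip(shk.exps, shk.coefs):
                for al, cl in zip(shl.exps, shl.coefs):
                    p = ak + al
                    P = (ak * shk.center + al * shl.center) / p
                    pref = np.exp(-ak * al / p *
                                  float(((shk.center - shl.center) ** 2).sum()))
                    d = np.linalg.norm(pts - P[None, :], axis=1)
                    d = np.where(d > 1e-12, d, 1e-12)
                    from scipy.special import erf
                    out += ck * cl * pref * (np.pi / p) ** 1.5 \
                        * erf(np.sqrt(p) * d) / d
            return out

        for (i, j, k, l) in ((0, 0, 0, 0), (0, 1, 0, 1), (0, 0, 1, 1)):
            shi, shj, shk, shl = (h2_shells[x] for x in (i, j, k, l))

            def f(pts):
                return (basis_function_values(shi, 0, pts)
                        * basis_function_values(shj, 0, pts)
                        * ket_potential(pts, shk, shl))

            P = 0.5 * (shi.center + shj.center)
            val, _ = adaptive_spherical_quadrature(
                f, P, rmax=np.linalg.norm(shi.center - shj.center) + 18.0,
                axis=shj.center - shi.center + 1e-3, tol=1e-10)
            assert abs(val - eri[i, j, k, l]) < 1e-8

    def test_p_eri_equals_derivative_of_s_eri(self):
        """(p_z s|ss) from the analytic engine equals the center-derivative of
        the pure-s integral (independent recursion check)."""
        a = 0.9
        sh_s = lambda c: s_shell(c, [a], [1.0])
        zs = 0.45
        base = [sh_s([0, 0, zs]), sh_s([0, 0, -0.3]), sh_s([0.4, 0, 0.6]),
                sh_s([0, -0.2, 0.1])]
        h = 1e-5
        up = [sh_s([0, 0, zs + h])] + base[1:]
        dn = [sh_s([0, 0, zs - h])] + base[1:]
        fd = (electron_repulsion(up)[0, 1, 2, 3]
              - electron_repulsion(dn)[0, 1, 2, 3]) / (2 * h)
        # d/dZ_A (normalized s_A) = 2a (z - A_z) N_s exp(...) = sqrt(a) p_z
        # with p_z the unit-normalized primitive (N_p = 2 sqrt(a) N_s)
        pshell = BasisShell(center=[0, 0, zs], l=1, exps=[a], coefs=[1.0])
        mixed = [pshell] + base[1:]
        val = electron_repulsion(mixed)[2, 3, 4, 5]  # p_z is AO 2
        assert abs(fd - np.sqrt(a) * val) < 1e-7


class TestFieldIntegrals:
    def test_site_centered_s_pair_vanishes(self):
        sh = [s_shell([0, 0, 0], [0.7, 2.0], [0.5, 0.5])]
        F = damped_field_integrals(sh, [[0.0, 0.0, 0.0]], [DampingFunction(1.0)])
        np.testing.assert_allclose(F, 0.0, atol=1e-14)

    def test_far_site_multipole_limit(self):
        # spherical s.s pair centered at the origin, site at R = 20 bohr:
        # the component along the separation approaches S_munu / R^2 (and is
        # exact here by the shell theorem since damping ~ 1)
        sh = [s_shell([0, 0, 0], [0.9], [1.0]), s_shell([0, 0, 0], [1.4], [1.0])]
        S = overlap(sh)
        R = 20.0
        F = damped_field_integrals(sh, [[0.0, 0.0, R]], [DampingFunction(1.0)])
        assert abs(F[0, 2, 0, 1] + S[0, 1] / R ** 2) < 1e-6 * abs(S[0, 1] / R ** 2)
        assert abs(F[0, 0, 0, 1]) < 1e-10
        assert abs(F[0, 1, 0, 1]) < 1e-10

    @pytest.mark.parametrize("l1,l2", [(0, 0), (0, 1), (1, 1)])
    def test_against_quadrature_oracle(self, rng, l1, l2):
        shells = [random_shell(rng, l=l1, center_scale=1.0),
                  random_shell(rng, l=l2, center_scale=1.0)]
        site = rng.normal(scale=2.0, size=3)
        damp = DampingFunction(float(rng.uniform(0.7, 1.5)))
        F = damped_field_integrals(shells, [site], [damp])
        nao1 = shells[0].n_ao
        for ci in range(nao1):
            for cj in range(shells[1].n_ao):
                for comp in range(3):
                    ref, _ = quadrature_field_integral(
                        shells[0], ci, shells[1], cj, site, damp, comp, tol=1e-10)
                    assert abs(ref - F[0, comp, ci, nao1 + cj]) < 1e-8


class TestCPPIntegrals:
    def test_symmetry_and_psd_diagonal(self, rng):
        shells = [random_shell(rng, l=1, center_scale=1.0)]
        site = rng.normal(scale=1.5, size=3)
        I = cpp_integrals(shells, [site], [DampingFunction(1.0)])
        np.testing.assert_allclose(I[0], I[0].transpose(1, 0, 2, 3), atol=1e-13)
        for mu in range(3):
            w = np.linalg.eigvalsh(I[0, :, :, mu, mu])
            assert w.min() >= -1e-12

    def test_far_site_outer_product_limit(self):
        # sharp s.s pair (widths << R) at the origin, site at R = 20 bohr:
        # I approaches S_munu * Rhat Rhat^T / R^4
        sh = [s_shell([0, 0, 0], [600.0], [1.0]), s_shell([0, 0, 0], [700.0], [1.0])]
        S = overlap(sh)
        R = 20.0
        I = cpp_integrals(sh, [[0.0, 0.0, R]], [DampingFunction(1.0)])
        assert abs(I[0, 2, 2, 0, 1] - S[0, 1] / R ** 4) \
            < 1e-5 * abs(S[0, 1] / R ** 4)
        assert abs(I[0, 0, 0, 0, 1]) < 1e-5 * abs(I[0, 2, 2, 0, 1])
        assert abs(I[0, 0, 2, 0, 1]) < 1e-12

    @pytest.mark.parametrize("l1,l2", [(0, 0), (0, 1), (1, 1)])
    def test_against_quadrature_oracle(self, rng, l1, l2):
        shells = [random_shell(rng, l=l1, center_scale=1.0),
                  random_shell(rng, l=l2, center_scale=1.0)]
        site = rng.normal(scale=2.0, size=3)
        damp = DampingFunction(float(rng.uniform(0.7, 1.5)))
        I = cpp_integrals(shells, [site], [damp])
        nao1 = shells[0].n_ao
        for ci in range(nao1):
            for (a, b) in ((0, 0), (0, 2), (1, 2), (2, 2)):
                ref, _ = quadrature_cpp_integral(
                    shells[0], ci, shells[1], 0, site, damp, a, b, tol=1e-10)
                assert abs(ref - I[0, a, b, ci, nao1]) < 1e-8

    def test_radial_grid_convergence(self, rng):
        shells = [random_shell(rng, l=1, center_scale=1.0),
                  random_shell(rng, l=0, center_scale=1.0)]
        site = rng.normal(scale=1.0, size=3)
        damp = DampingFunction(1.0)
        I1 = cpp_integrals(shells, [site], [damp], n_radial=100)
        I2 = cpp_integrals(shells, [site], [damp], n_radial=200)
        assert np.abs(I1 - I2).max() < 1e-11


class TestNeutralAtomCancellation:
    def test_nuclear_and_electronic_fields_cancel(self):
        """Point nucleus Z=1 plus a matching normalized s-density at the same
        center: the damped net field at a distant site nearly vanishes."""
        from iedrf.drf import site_fields_from_charges
        sh = [s_shell([0, 0, 0], [0.9, 2.5], [0.6, 0.5])]
        site = np.array([0.0, 0.0, 8.0])
        damp = DampingFunction(1.0)
        F = damped_field_integrals(sh, [site], [damp])
        fe = F[0, :, 0, 0]  # field of the unit s-density (electron, charge -1)
        fn = site_fields_from_charges([[0, 0, 0]], [1.0], [site], [damp])[0]
        assert np.linalg.norm(fn + fe) < 1e-6 * np.linalg.norm(fn)


class TestQuadratureOracle:
    def test_normalized_s_density_integrates_to_one(self):
        sh = s_shell([0.2, -0.1, 0.4], [0.9], [1.0])

        def f(pts):
            return basis_function_values(sh, 0, pts) ** 2

        val, err = adaptive_spherical_quadrature(f, sh.center, rmax=12.0, tol=1e-10)
        assert abs(val - 1.0) < 1e-9
        assert err < 1e-9

    def test_displaced_gaussian_overlap_closed_form(self):
        # Gaussian product theorem: for unit-norm s primitives with exponents
        # a, b at separation d: S = (4ab/(a+b)^2)^(3/4) exp(-ab d^2/(a+b))
        a, b, d = 0.7, 1.9, 1.3
        sh1, sh2 = s_shell([0, 0, 0], [a], [1.0]), s_shell([0, 0, d], [b], [1.0])

        def f(pts):
            return (basis_function_values(sh1, 0, pts)
                    * basis_function_values(sh2, 0, pts))

        val, _ = adaptive_spherical_quadrature(
            f, np.array([0, 0, d / 2]), rmax=14.0, tol=1e-11)
        closed = (4 * a * b / (a + b) ** 2) ** 0.75 * np.exp(-a * b * d * d / (a + b))
        assert abs(val - closed) < 1e-10

    def test_symmetric_site_field_is_zero(self):
        sh = s_shell([0, 0, 0], [1.2], [1.0])
        damp = DampingFunction(1.0)
        val, _ = quadrature_field_integral(sh, 0, sh, 0, np.zeros(3), damp, 2)
        assert abs(val) < 1e-10

    def test_unreachable_tolerance_raises(self):
        sh = s_shell([0, 0, 0], [1.2], [1.0])

        def f(pts):
            return basis_function_values(sh, 0, pts) ** 2

        with pytest.raises(QuadratureError):
            adaptive_spherical_quadrature(f, sh.center, rmax=12.0, tol=1e-18,
                                          max_level=1)
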