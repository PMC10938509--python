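"""Damped electric-field integrals F^(e) and their gradient contractions.

The matrix elements are

    F_(i,alpha,mu nu) = int mu(r) C_i(|r - R_i|) (r - R_i)_alpha / |r - R_i|^3 nu(r) d^3r

with the sign convention that tracing with an electron *number* density D
yields the physical electric field of the (negatively charged) electron cloud
at the site: field = sum_munu D_munu F_(i,munu).

Because the default damping C(r) is a finite sum of Gaussians, each term
merges with the AO-pair Gaussian and the integral reduces to a derivative of
a Boys-function Coulomb integral — this is the exact ("integral-exact")
analytic path.
"""

from __future__ import annotations

import numpy as np

from ..basis import BasisShell
from .hermite import PairBatch, hermite_coeffs_1d, hermite_R
from .one_electron import _ao_offsets
from .eri import _shift_terms


def _merged_coeffs(pair: PairBatch, pa, pb, q, Q):
    out = []
    for d in range(3):
        factors = [(pa[d], Q[:, d] - pair.A[d]), (pb[d], Q[:, d] - pair.B[d])]
        out.append(hermite_coeffs_1d(factors, q))
    return out


def _field_prim(pair, pa, pb, site, damping):
    """Batched (nprimpair, 3) values of the damped field integral."""
    coefs, exps = damping.gaussian_expansion()
    out = np.zeros((len(pair.p), 3))
    for cm, km in zip(coefs, exps):
        q, Q, pref = pair.with_damping_gaussian(km, site)
        cx, cy, cz = _merged_coeffs(pair, pa, pb, q, Q)
        tmax = (cx.shape[0], cy.shape[0], cz.shape[0])  # +1 slot for the shift
        R = hermite_R(tmax, q, Q - site[None, :])
        tx, ty, tz = cx.shape[0] - 1, cy.shape[0] - 1, cz.shape[0] - 1
        for alpha, (dx, dy, dz) in enumerate(((1, 0, 0), (0, 1, 0), (0, 0, 1))):
            acc = np.einsum("tn,un,vn,tuvn->n", cx, cy, cz,
                            R[dx:dx + tx + 1, dy:dy + ty + 1, dz:dz + tz + 1])
            out[:, alpha] += -cm * (2.0 * np.pi / q) * pref * acc
    return out


def damped_field_integrals(shells: list[BasisShell], sites,
                           dampings) -> np.ndarray:
    """F^(e) array of shape (n_sites, 3, n_AO, n_AO).

    ``sites`` is an (n_sites, 3) position array (bohr); ``dampings`` a list of
    per-site damping functions.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    offs, nao = _ao_offsets(shells)
    F = np.zeros((len(sites), 3, nao, nao))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            for isite, (R, damp) in enumerate(zip(sites, dampings)):
                for ci, pa in enumerate(shi.ao_powers):
                    for cj, pb in enumerate(shj.ao_powers):
                        vals = pair.cc @ _field_prim(pair, pa, pb, R, damp)
                        mu, nu = offs[i] + ci, offs[j] + cj
                        F[isite, :, mu, nu] = vals
                        F[isite, :, nu, mu] = vals
    return F


def contract_field_derivatives(shells, sites, dampings, weights, n_atoms):
    """Contract dF^(e)/dx with a weight supertensor in one integral-direct pass.

    ``weights`` has shape (n_sites, 3, n_AO, n_AO). Returns
    ``(grad_atoms (n_atoms, 3), grad_sites (n_sites, 3))`` — the derivative
    integrals are never stored, matching the integral-direct contraction
    contract.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 3)
    weights = np.asarray(weights, dtype=float)
    offs, nao = _ao_offsets(shells)
    grad_atoms = np.zeros((n_atoms, 3))
    grad_sites = np.zeros((len(sites), 3))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            # F is symmetric in (mu, nu); for i != j each unordered AO pair is
            # visited once, so it picks up the symmetrized weight twice.
            sym = 1.0 if i == j else 2.0
            for isite, (R, damp) in enumerate(zip(sites, dampings)):
                for ci, pa in enumerate(shi.ao_powers):
                    for cj, pb in enumerate(shj.ao_powers):
                        mu, nu = offs[i] + ci, offs[j] + cj
                        w = 0.5 * (weights[isite, :, mu, nu] + weights[isite, :, nu, mu])
                        if np.abs(w).max() < 1e-16:
                            continue
                        for dim in range(3):
                            dA = np.zeros(3)
                            for scale, newp in _shift_terms(pa, dim, pair.a):
                                vals = _field_prim_scaled(pair, newp, pb, R, damp, scale)
                                dA += vals
                            dB = np.zeros(3)
                            for scale, newp in _shift_terms(pb, dim, pair.b):
                                vals = _field_prim_scaled(pair, pa, newp, R, damp, scale)
                                dB += vals
                            ga = sym * float(w @ dA)
                            gb = sym * float(w @ dB)
                            grad_atoms[shi.atom_index, dim] += ga
                            grad_atoms[shj.atom_index, dim] += gb
                            grad_sites[isite, dim] += -(ga + gb)
    return grad_atoms, grad_sites


def _field_prim_scaled(pair, pa, pb, site, damp, scale):
    vals = _field_prim(pair, pa, pb, site, damp)
    return (pair.cc * scale) @ vals
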