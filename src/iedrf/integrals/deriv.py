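"""Gradient contractions of the base one-electron integrals.

Derivatives are taken at the primitive level by Cartesian power shifting
(d/dA_x raises/lowers the monomial power), and contracted immediately with a
weight matrix; translation invariance supplies the remaining center.
"""

from __future__ import annotations

import numpy as np

from .hermite import PairBatch
from .one_electron import _ao_offsets, _overlap_prim, _coulomb_prim, _laplacian_terms
from .eri import _shift_terms


def _pair_weight(W, mu, nu):
    return 0.5 * (W[mu, nu] + W[nu, mu])


def contract_overlap_derivative(shells, W, n_atoms) -> np.ndarray:
    """sum_munu W_munu dS_munu/dx per atom; dB = -dA by translation."""
    offs, _ = _ao_offsets(shells)
    grad = np.zeros((n_atoms, 3))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            sym = 1.0 if i == j else 2.0
            if shi.atom_index == shj.atom_index:
                continue  # same-center pair: dA = -dB cancels on one atom
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    w = sym * _pair_weight(W, offs[i] + ci, offs[j] + cj)
                    if abs(w) < 1e-16:
                        continue
                    for dim in range(3):
                        dA = 0.0
                        for scale, newp in _shift_terms(pa, dim, pair.a):
                            dA += float((pair.cc * scale
                                         * _overlap_prim(pair, newp, pb)).sum())
                        grad[shi.atom_index, dim] += w * dA
                        grad[shj.atom_index, dim] -= w * dA
    return grad


def contract_kinetic_derivative(shells, W, n_atoms) -> np.ndarray:
    offs, _ = _ao_offsets(shells)
    grad = np.zeros((n_atoms, 3))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            sym = 1.0 if i == j else 2.0
            if shi.atom_index == shj.atom_index:
                continue
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    w = sym * _pair_weight(W, offs[i] + ci, offs[j] + cj)
                    if abs(w) < 1e-16:
                        continue
                    for dim in range(3):
                        dA = 0.0
                        for scale, newp in _shift_terms(pa, dim, pair.a):
                            acc = np.zeros_like(pair.p)
                            for lsc, pow2 in _laplacian_terms(pb, pair.b):
                                acc = acc + lsc * _overlap_prim(pair, newp, pow2)
                            dA += -0.5 * float((pair.cc * scale * acc).sum())
                        grad[shi.atom_index, dim] += w * dA
                        grad[shj.atom_index, dim] -= w * dA
    return grad


def contract_charge_attraction_derivative(shells, W, positions, charges,
                                          n_atoms):
    """Gradient of sum W_munu * [-sum_n Q_n (mu|1/|r-C_n||nu)].

    Returns ``(grad_atoms, grad_centers)``; the operator-center force follows
    from translation invariance of each single-charge matrix.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    offs, _ = _ao_offsets(shells)
    grad_atoms = np.zeros((n_atoms, 3))
    grad_centers = np.zeros((len(positions), 3))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            sym = 1.0 if i == j else 2.0
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    w = sym * _pair_weight(W, offs[i] + ci, offs[j] + cj)
                    if abs(w) < 1e-16:
                        continue
                    for n, (C, Q) in enumerate(zip(positions, charges)):
                        if Q == 0.0:
                            continue
                        for dim in range(3):
                            dA = 0.0
                            for scale, newp in _shift_terms(pa, dim, pair.a):
                                dA += float((pair.cc * scale
                                             * _coulomb_prim(pair, newp, pb, C)).sum())
                            dB = 0.0
                            for scale, newp in _shift_terms(pb, dim, pair.b):
                                dB += float((pair.cc * scale
                                             * _coulomb_prim(pair, pa, newp, C)).sum())
                            ga, gb = -Q * w * dA, -Q * w * dB
                            grad_atoms[shi.atom_index, dim] += ga
                            grad_atoms[shj.atom_index, dim] += gb
                            grad_centers[n, dim] += -(ga + gb)
    return grad_atoms, grad_centers
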