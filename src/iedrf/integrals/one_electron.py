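"""Overlap, kinetic and nuclear/point-charge attraction matrices."""

from __future__ import annotations

import numpy as np

from ..basis import BasisShell, n_ao
from .hermite import PairBatch, hermite_R


def _ao_offsets(shells):
    offs, acc = [], 0
    for sh in shells:
        offs.append(acc)
        acc += sh.n_ao
    return offs, acc


def _overlap_prim(pair: PairBatch, pa, pb):
    cx, cy, cz = pair.coeffs(pa, pb)
    return pair.prefE * (np.pi / pair.p) ** 1.5 * cx[0] * cy[0] * cz[0]


def overlap(shells: list[BasisShell]) -> np.ndarray:
    offs, nao = _ao_offsets(shells)
    S = np.zeros((nao, nao))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    val = float((pair.cc * _overlap_prim(pair, pa, pb)).sum())
                    S[offs[i] + ci, offs[j] + cj] = val
                    S[offs[j] + cj, offs[i] + ci] = val
    return S


def _laplacian_terms(pb_pow, b):
    """Expansion of the Laplacian acting on a primitive with powers ``pb_pow``.

    Returns a list of ``(scale, powers)`` where ``scale`` may depend on the
    batched exponent ``b``.
    """
    terms = []
    for d in range(3):
        j = pb_pow[d]
        up = list(pb_pow); up[d] = j + 2
        terms.append((4.0 * b * b, tuple(up)))
        terms.append((-2.0 * b * (2 * j + 1), tuple(pb_pow)))
        if j >= 2:
            dn = list(pb_pow); dn[d] = j - 2
            terms.append((float(j * (j - 1)), tuple(dn)))
    return terms


def kinetic(shells: list[BasisShell]) -> np.ndarray:
    offs, nao = _ao_offsets(shells)
    T = np.zeros((nao, nao))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    acc = np.zeros_like(pair.p)
                    for scale, pow2 in _laplacian_terms(pb, pair.b):
                        acc = acc + scale * _overlap_prim(pair, pa, pow2)
                    val = -0.5 * float((pair.cc * acc).sum())
                    T[offs[i] + ci, offs[j] + cj] = val
                    T[offs[j] + cj, offs[i] + ci] = val
    return T


def _coulomb_prim(pair: PairBatch, pa, pb, C):
    """Batch values of int mu nu / |r - C| for one primitive pair batch."""
    cx, cy, cz = pair.coeffs(pa, pb)
    tmax = (cx.shape[0] - 1, cy.shape[0] - 1, cz.shape[0] - 1)
    R = hermite_R(tmax, pair.p, pair.P - C[None, :])
    acc = np.einsum("tn,un,vn,tuvn->n", cx, cy, cz, R)
    return pair.prefE * (2.0 * np.pi / pair.p) * acc


def charge_attraction(shells, positions, charges) -> np.ndarray:
    """Matrix of -sum_n Q_n int mu nu / |r - R_n| (electron-charge energy).

    For QM nuclei (Q = Z) this is the usual nuclear attraction; for MM point
    charges it is the electrostatic-embedding contribution to the core
    Hamiltonian.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    offs, nao = _ao_offsets(shells)
    V = np.zeros((nao, nao))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j < i:
                continue
            pair = PairBatch(shi, shj)
            for ci, pa in enumerate(shi.ao_powers):
                for cj, pb in enumerate(shj.ao_powers):
                    acc = np.zeros_like(pair.p)
                    for C, Q in zip(positions, charges):
                        acc = acc - Q * _coulomb_prim(pair, pa, pb, C)
                    val = float((pair.cc * acc).sum())
                    V[offs[i] + ci, offs[j] + cj] = val
                    V[offs[j] + cj, offs[i] + ci] = val
    return V


def nuclear_attraction(shells, molecule) -> np.ndarray:
    return charge_attraction(shells, molecule.coords, molecule.atomic_numbers)


def overlap_kinetic_nuclear(shells, molecule, lindep_threshold: float = 1e-10):
    """S, T, V plus a linear-dependence report on S.

    Returns ``(S, T, V, min_eig_S)``; callers engage the pseudoinverse pathway
    downstream when ``min_eig_S`` falls below the threshold.
    """
    S = overlap(shells)
    T = kinetic(shells)
    V = nuclear_attraction(shells, molecule)
    w = np.linalg.eigvalsh(S)
    return S, T, V, float(w[0])
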