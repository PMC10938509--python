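"""Electron repulsion integrals (mu nu | lambda sigma) and their gradient
contractions, via McMurchie-Davidson Hermite expansions.

Dense storage only: the targets are desk-scale molecules, so no screening or
sparsity is attempted.
"""

from __future__ import annotations

import numpy as np

from ..basis import BasisShell, n_ao
from .hermite import PairBatch, hermite_R
from .one_electron import _ao_offsets

#: refuse dense ERI tensors beyond this AO count
MAX_DENSE_AO = 40


def _pair_list(shells):
    pairs = []
    for i in range(len(shells)):
        for j in range(i, len(shells)):
            pairs.append((i, j, PairBatch(shells[i], shells[j])))
    return pairs


def _component_coeffs(pair: PairBatch, pa, pb, signed=False):
    """Per-dimension Hermite coefficients, optionally with (-1)^t folded in."""
    cs = pair.coeffs(pa, pb)
    if signed:
        cs = [c * ((-1.0) ** np.arange(c.shape[0]))[:, None] for c in cs]
    return cs


def _quartet_R(bra: PairBatch, ket: PairBatch, tmax):
    p = bra.p[:, None]
    q = ket.p[None, :]
    omega = p * q / (p + q)
    PQ = bra.P[:, None, :] - ket.P[None, :, :]
    R = hermite_R(tmax, omega, PQ)
    pref = (2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
            * bra.prefE[:, None] * ket.prefE[None, :])
    return R, pref


def _contract_quartet(R, pref, c1, c2, cc):
    """Contract Hermite coefficients with the shifted R tensor.

    ``c1``/``c2`` are per-dimension coefficient arrays for bra/ket; ``cc`` is
    the contraction-coefficient outer product (nb, nk).
    """
    t1 = [c.shape[0] for c in c1]
    t2 = [c.shape[0] for c in c2]
    ix = np.arange(t1[0])[:, None] + np.arange(t2[0])[None, :]
    iy = np.arange(t1[1])[:, None] + np.arange(t2[1])[None, :]
    iz = np.arange(t1[2])[:, None] + np.arange(t2[2])[None, :]
    R6 = R[ix[:, None, None, :, None, None],
           iy[None, :, None, None, :, None],
           iz[None, None, :, None, None, :]]  # (t,u,v,x,y,z,nb,nk)
    val = np.einsum("tb,ub,vb,xk,yk,zk,tuvxyzbk,bk->",
                    c1[0], c1[1], c1[2], c2[0], c2[1], c2[2], R6, pref * cc,
                    optimize=True)
    return float(val)


def electron_repulsion(shells: list[BasisShell]) -> np.ndarray:
    """Dense (mu nu | lambda sigma) tensor in chemists' notation."""
    offs, nao = _ao_offsets(shells)
    if nao > MAX_DENSE_AO:
        raise MemoryError(f"dense ERI refused for {nao} AOs (> {MAX_DENSE_AO})")
    eri = np.zeros((nao, nao, nao, nao))
    pairs = _pair_list(shells)
    for ip1, (i, j, bra) in enumerate(pairs):
        for ip2 in range(ip1, len(pairs)):
            k, l, ket = pairs[ip2]
            lsum = (shells[i].l + shells[j].l, shells[k].l + shells[l].l)
            tmax = tuple(lsum[0] + lsum[1] for _ in range(3))
            R, pref = _quartet_R(bra, ket, tmax)
            cc = bra.cc[:, None] * ket.cc[None, :]
            for ci, pa in enumerate(shells[i].ao_powers):
                for cj, pb in enumerate(shells[j].ao_powers):
                    c1 = _component_coeffs(bra, pa, pb)
                    for ck, pc in enumerate(shells[k].ao_powers):
                        for cl, pd in enumerate(shells[l].ao_powers):
                            c2 = _component_coeffs(ket, pc, pd, signed=True)
                            v = _contract_quartet(R, pref, c1, c2, cc)
                            mu, nu = offs[i] + ci, offs[j] + cj
                            la, si = offs[k] + ck, offs[l] + cl
                            for (p_, q_, r_, s_) in ((mu, nu, la, si), (nu, mu, la, si),
                                                     (mu, nu, si, la), (nu, mu, si, la),
                                                     (la, si, mu, nu), (si, la, mu, nu),
                                                     (la, si, nu, mu), (si, la, nu, mu)):
                                eri[p_, q_, r_, s_] = v
    return eri


def _shift_terms(powers, dim, exps):
    """Terms of d/dX_dim acting on (r-X)^powers exp(-a|r-X|^2).

    Returns a list of ``(scale_array, new_powers)``.
    """
    out = []
    up = list(powers); up[dim] += 1
    out.append((2.0 * exps, tuple(up)))
    if powers[dim] >= 1:
        dn = list(powers); dn[dim] -= 1
        out.append((-float(powers[dim]) * np.ones_like(exps), tuple(dn)))
    return out


def symmetrized_weight(W: np.ndarray) -> np.ndarray:
    """Average of the 8 ERI index permutations of a weight tensor."""
    acc = (W + W.transpose(1, 0, 2, 3) + W.transpose(0, 1, 3, 2)
           + W.transpose(1, 0, 3, 2))
    acc = acc + acc.transpose(2, 3, 0, 1)
    return acc / 8.0


def contract_eri_derivative(shells: list[BasisShell], W: np.ndarray,
                            n_centers: int) -> np.ndarray:
    """Gradient contraction sum_munulasi W d(mu nu|la si)/dx, per atom.

    ``W`` is symmetrized internally; returns an ``(n_centers, 3)`` array of
    contributions on the AO-carrying atoms (``shell.atom_index``).
    """
    offs, nao = _ao_offsets(shells)
    Ws = symmetrized_weight(W)
    grad = np.zeros((n_centers, 3))
    pairs = _pair_list(shells)
    for ip1, (i, j, bra) in enumerate(pairs):
        for ip2 in range(ip1, len(pairs)):
            k, l, ket = pairs[ip2]
            mult = ((2.0 if i != j else 1.0) * (2.0 if k != l else 1.0)
                    * (2.0 if ip1 != ip2 else 1.0))
            lsum = shells[i].l + shells[j].l + shells[k].l + shells[l].l
            tmax = tuple(lsum + 1 for _ in range(3))
            R, pref = _quartet_R(bra, ket, tmax)
            cc = bra.cc[:, None] * ket.cc[None, :]
            atoms = [shells[s].atom_index for s in (i, j, k, l)]
            for ci, pa in enumerate(shells[i].ao_powers):
                for cj, pb in enumerate(shells[j].ao_powers):
                    for ck, pc in enumerate(shells[k].ao_powers):
                        for cl, pd in enumerate(shells[l].ao_powers):
                            w = mult * Ws[offs[i] + ci, offs[j] + cj,
                                          offs[k] + ck, offs[l] + cl]
                            if abs(w) < 1e-16:
                                continue
                            base = (pa, pb, pc, pd)
                            for dim in range(3):
                                contribs = np.zeros(4)
                                for slot in range(3):  # 4th from translation
                                    exps = (bra.a, bra.b, ket.a, ket.b)[slot]
                                    acc = 0.0
                                    for scale, newp in _shift_terms(base[slot], dim, exps):
                                        pw = list(base)
                                        pw[slot] = newp
                                        if slot < 2:
                                            c1 = pair_coeffs_scaled(bra, pw[0], pw[1],
                                                                    scale, slot)
                                            c2 = _component_coeffs(ket, pw[2], pw[3],
                                                                   signed=True)
                                        else:
                                            c1 = _component_coeffs(bra, pw[0], pw[1])
                                            c2 = pair_coeffs_scaled(ket, pw[2], pw[3],
                                                                    scale, slot - 2,
                                                                    signed=True)
                                        acc += _contract_quartet(R, pref, c1, c2, cc)
                                    contribs[slot] = acc
                                contribs[3] = -contribs[:3].sum()
                                for slot in range(4):
                                    grad[atoms[slot], dim] += w * contribs[slot]
    return grad


def pair_coeffs_scaled(pair: PairBatch, pa, pb, scale, slot, signed=False):
    """Coefficient arrays with a per-primitive scale folded into dimension 0.

    The scale multiplies along the primitive axis; folding it into the first
    dimension's coefficients applies it to the whole product.
    """
    cs = list(pair.coeffs(pa, pb))
    cs[0] = cs[0] * scale[None, :]
    if signed:
        cs = [c * ((-1.0) ** np.arange(c.shape[0]))[:, None] for c in cs]
    return cs
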