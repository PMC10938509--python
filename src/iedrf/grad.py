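"""Analytical gradients of the IEDRF-RHF energy.

Strategy: the polarization energy is an explicit function of the arrays
(A, F^(e), F^(n), S, I_cpp) and the converged density D.  Its array-adjoints
(dE/dA etc.) are formed analytically and chained with geometric derivatives:

* dF^(e)/dx and dI/dx are contracted integral-direct (derivative integrals
  are never stored) by Cartesian power shifting, with site-position
  contributions from translation invariance;
* dA/dx = A (dT/dx) A, since the atomic polarizabilities (and the damping
  lengths derived from them) are geometry-independent;
* dS/dx enters both through the Pulay energy-weighted-density term and
  explicitly through the RI metric inverse (dS^-1 = -S^-1 dS S^-1).

Every component is validated against central finite differences of the total
SCF energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals.deriv import (contract_charge_attraction_derivative,
                              contract_kinetic_derivative,
                              contract_overlap_derivative)
from .integrals.eri import contract_eri_derivative
from .integrals.field import contract_field_derivatives
from .integrals.cpp import contract_cpp_derivatives
from .polarization import dipole_tensor_derivative
from .scf import IEDRFSystem, SCFState


@dataclass
class EnergyWeightedDensity:
    """W = 2 sum_(k in occ) eps_k C_muk C_nuk (doubled-occupation convention),
    the matrix contracting with dS/dx in the Pulay term."""

    W: np.ndarray


@dataclass
class GradientReport:
    """Per-particle gradients (hartree/bohr) with a component breakdown."""

    nuclei: np.ndarray            # (n_atoms, 3)
    charges: np.ndarray           # (n_charges, 3)
    sites: np.ndarray             # (n_pol_sites, 3)
    components: dict = field(default_factory=dict)

    @property
    def net_force(self) -> np.ndarray:
        return -(self.nuclei.sum(axis=0) + self.charges.sum(axis=0)
                 + self.sites.sum(axis=0))

    def net_torque(self, system) -> np.ndarray:
        """Total torque about the origin (vanishes for isolated systems)."""
        tau = np.zeros(3)
        for pos, g in zip(system.molecule.coords, self.nuclei):
            tau += np.cross(pos, -g)
        for pos, g in zip(system.environment.charge_positions, self.charges):
            tau += np.cross(pos, -g)
        for pos, g in zip(system.site_pos, self.sites):
            tau += np.cross(pos, -g)
        return tau


def energy_weighted_density(state: SCFState) -> EnergyWeightedDensity:
    if not state.converged:
        raise ValueError("energy-weighted density requires a converged state")
    return EnergyWeightedDensity(_energy_weighted(state, state.n_occ))


def _energy_weighted(state: SCFState, nocc: int) -> np.ndarray:
    Cocc = state.C[:, :nocc]
    return 2.0 * (Cocc * state.eps[:nocc]) @ Cocc.T


class _Accumulator:
    def __init__(self, system: IEDRFSystem):
        self.n_at = system.molecule.n_atoms
        self.n_q = len(system.environment.charges)
        self.n_s = system.n_pol
        self.components: dict = {}

    def add(self, name, nuclei=None, charges=None, sites=None):
        comp = self.components.setdefault(
            name, (np.zeros((self.n_at, 3)), np.zeros((self.n_q, 3)),
                   np.zeros((self.n_s, 3))))
        if nuclei is not None:
            comp[0][:] += nuclei
        if charges is not None:
            comp[1][:] += charges
        if sites is not None:
            comp[2][:] += sites

    def totals(self):
        nuc = sum(c[0] for c in self.components.values())
        chg = sum(c[1] for c in self.components.values())
        sit = sum(c[2] for c in self.components.values())
        return nuc, chg, sit


# -- classical pieces -----------------------------------------------------

def _pairwise_coulomb_gradient(pos_a, q_a, pos_b, q_b):
    """Gradients of sum_(m,n) q_a[m] q_b[n] / |r_m - r_n| (two disjoint sets)."""
    ga = np.zeros_like(pos_a)
    gb = np.zeros_like(pos_b)
    for m, (ra, qa) in enumerate(zip(pos_a, q_a)):
        rvec = ra[None, :] - pos_b
        r = np.linalg.norm(rvec, axis=1)
        gvec = -(qa * q_b / r ** 3)[:, None] * rvec
        ga[m] += gvec.sum(axis=0)
        gb -= gvec
    return ga, gb


def _nuclear_repulsion_gradient(molecule):
    n = molecule.n_atoms
    z = molecule.atomic_numbers
    g = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            rvec = molecule.coords[i] - molecule.coords[j]
            r = np.linalg.norm(rvec)
            f = -z[i] * z[j] / r ** 3 * rvec
            g[i] += f
            g[j] -= f
    return g


def contract_charge_field_derivatives(WFn, src_pos, src_q, sites_pos, dampings,
                                      mask=None):
    """Contract a weight (n_sites, 3) with d f_i / dx of classical damped
    fields; returns ``(grad_sources, grad_sites)``."""
    src_pos = np.asarray(src_pos, dtype=float).reshape(-1, 3)
    src_q = np.asarray(src_q, dtype=float)
    g_src = np.zeros_like(src_pos)
    g_sit = np.zeros((len(sites_pos), 3))
    eye = np.eye(3)
    for i, (R, damp) in enumerate(zip(sites_pos, dampings)):
        w = WFn[i]
        if np.abs(w).max() < 1e-18:
            continue
        for n, (rn, q) in enumerate(zip(src_pos, src_q)):
            if q == 0.0 or (mask is not None and mask[n, i]):
                continue
            rvec = R - rn
            r = float(np.linalg.norm(rvec))
            C = float(damp.value(r))
            dC = float(damp.derivative(r))
            rhat = rvec / r
            # d/dR_i[gamma] of C(r) r_alpha / r^3
            dmat = (dC * np.outer(rhat, rvec) / r ** 3
                    + C * (eye / r ** 3 - 3.0 * np.outer(rvec, rvec) / r ** 5))
            contrib = q * (dmat @ w)   # gamma component: sum_alpha dmat[g,a] w[a]
            g_sit[i] += contrib
            g_src[n] -= contrib
    return g_src, g_sit


# -- polarization adjoints -------------------------------------------------

def polarization_adjoints(system: IEDRFSystem, D: np.ndarray):
    """Array-adjoints of the total polarization energy.

    Returns dict with WF (n,3,nao,nao), WFn (n,3), U (3N x 3N), WS (nao,nao)
    and WI (n,3,3) such that dE_pol = <WF, dF> + <WFn, dFn> + <U, dA>
    + <WS, dS> + sum WI_iab dI_iab:D.
    """
    n = system.n_pol
    nao = system.nao
    F, Fn, A, Sinv = system.F_e, system.Fn, system.A, system.S_inv
    AF = system.AF
    exact = system.options.ri_mode == "exact-same-site"
    fD = np.einsum("iamn,mn->ia", F, D)
    ft = (Fn + fD).reshape(-1)
    Aft = (A @ ft).reshape(n, 3)

    WFn = -Aft
    WF = np.empty_like(F)
    Ab = A.reshape(n, 3, n, 3)
    Adiag = np.einsum("iaib->iab", Ab)
    Fd = np.einsum("iab,ibmn->iamn", Adiag, F)
    WSinv = np.zeros((nao, nao))
    for i in range(n):
        for a in range(3):
            DAF = D @ AF[i, a]
            WF[i, a] = (-Aft[i, a] * D
                        - 0.5 * (DAF @ Sinv + Sinv @ AF[i, a] @ D)
                        + 0.5 * (D @ AF[i, a] @ D))
            WSinv += -0.5 * (F[i, a] @ D @ AF[i, a])
            if exact:
                WF[i, a] += 0.5 * (D @ Fd[i, a] @ Sinv + Sinv @ Fd[i, a] @ D)
                WSinv += 0.5 * (F[i, a] @ D @ Fd[i, a])
    WSinv = 0.5 * (WSinv + WSinv.T)
    WS = -Sinv @ WSinv @ Sinv

    # dE/dA supermatrix
    G = np.einsum("iaml,ls,jbsn,nm->iajb", F, Sinv, F, D, optimize=True)
    H = np.einsum("iaml,lp,jbpn,nm->iajb", F, D, F, D, optimize=True)
    U = (-0.5 * np.einsum("p,q->pq", ft, ft).reshape(n, 3, n, 3)
         - 0.5 * G + 0.25 * H)
    WI = None
    if exact:
        Gd = np.einsum("iaml,ls,ibsn,nm->iab", F, Sinv, F, D, optimize=True)
        trDI = np.einsum("iabmn,nm->iab", system.cpp, D)
        for i in range(n):
            U[i, :, i, :] += 0.5 * Gd[i] - 0.5 * trDI[i]
        WI = -0.5 * Adiag
    U = U.reshape(3 * n, 3 * n)
    U = 0.5 * (U + U.T)
    return {"WF": WF, "WFn": WFn, "U": U, "WS": WS, "WI": WI}


def polarizability_derivative_contraction(system: IEDRFSystem,
                                          U: np.ndarray) -> np.ndarray:
    """Site gradients of <U, dA/dx> using dA/dx = A (dT/dx) A."""
    n = system.n_pol
    g = np.zeros((n, 3))
    if n < 2:
        return g
    V = system.A @ U @ system.A
    Vb = V.reshape(n, 3, n, 3)
    damped = system.options.thole_damped
    a = system.options.thole_a
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dT = dipole_tensor_derivative(system.pol_sites, i, j,
                                          thole_a=a, damped=damped)
            # dT[g, a, b] = d T^(ij)_ab / d R_j[g]
            contrib = np.einsum("ab,gab->g", Vb[i, :, j, :], dT)
            g[j] += contrib
            g[i] -= contrib
    return g


# -- total gradient --------------------------------------------------------

def total_gradient(system: IEDRFSystem, state: SCFState) -> GradientReport:
    """Full analytical gradient of the IEDRF-RHF energy.

    Includes the vacuum RHF terms (Pulay, core, two-electron, nuclear
    repulsion), the classical embedding terms, and every polarization term.
    """
    if not state.converged:
        raise ValueError("gradients require a converged SCF state")
    D = state.D
    mol = system.molecule
    env = system.environment
    nocc = mol.n_electrons // 2
    acc = _Accumulator(system)
    n_at = mol.n_atoms

    # classical charge-charge terms
    acc.add("nuclear_repulsion", nuclei=_nuclear_repulsion_gradient(mol))
    if env.charges:
        gn, gq = _pairwise_coulomb_gradient(mol.coords, mol.atomic_numbers,
                                            env.charge_positions,
                                            env.charge_values)
        acc.add("nuclear_mm_charge", nuclei=gn, charges=gq)

    # overlap (Pulay + RI metric) -----------------------------------------
    W_ew = _energy_weighted(state, nocc)
    WS = -W_ew
    adj = None
    if system.n_pol:
        adj = polarization_adjoints(system, D)
        WS = WS + adj["WS"]
    acc.add("overlap", nuclei=contract_overlap_derivative(system.shells, WS, n_at))

    # core Hamiltonian -----------------------------------------------------
    acc.add("kinetic", nuclei=contract_kinetic_derivative(system.shells, D, n_at))
    ga, gc = contract_charge_attraction_derivative(
        system.shells, D, mol.coords, mol.atomic_numbers, n_at)
    acc.add("nuclear_attraction", nuclei=ga + gc)
    if env.charges:
        ga, gc = contract_charge_attraction_derivative(
            system.shells, D, env.charge_positions, env.charge_values, n_at)
        acc.add("mm_charge_attraction", nuclei=ga, charges=gc)

    # two-electron repulsion ----------------------------------------------
    W2 = (0.5 * np.einsum("mn,ls->mnls", D, D)
          - 0.25 * np.einsum("ml,ns->mnls", D, D))
    acc.add("two_electron", nuclei=contract_eri_derivative(system.shells, W2, n_at))

    # polarization terms ---------------------------------------------------
    if system.n_pol:
        gat, gst = contract_field_derivatives(
            system.shells, system.site_pos, system.dampings, adj["WF"], n_at)
        acc.add("field_integrals", nuclei=gat, sites=gst)
        if adj["WI"] is not None:
            WIfull = adj["WI"][:, :, :, None, None] * D[None, None, None, :, :]
            gat, gst = contract_cpp_derivatives(
                system.shells, system.site_pos, system.dampings, WIfull, n_at)
            acc.add("cpp_integrals", nuclei=gat, sites=gst)
        # classical field sources: nuclei (never excluded) and MM charges
        gsrc, gsit = contract_charge_field_derivatives(
            adj["WFn"], mol.coords, mol.atomic_numbers, system.site_pos,
            system.dampings)
        acc.add("nuclear_fields", nuclei=gsrc, sites=gsit)
        if env.charges:
            from .drf import _site_exclusion_mask
            mask = _site_exclusion_mask(env)
            gsrc, gsit = contract_charge_field_derivatives(
                adj["WFn"], env.charge_positions, env.charge_values,
                system.site_pos, system.dampings, mask)
            acc.add("mm_charge_fields", charges=gsrc, sites=gsit)
        acc.add("polarizability",
                sites=polarizability_derivative_contraction(system, adj["U"]))

    nuc, chg, sit = acc.totals()
    return GradientReport(nuclei=nuc, charges=chg, sites=sit,
                          components=acc.components)


# -- single-coordinate contraction helpers ---------------------------------

def field_integral_derivative_contraction(system: IEDRFSystem,
                                          E_supertensor: np.ndarray,
                                          which: str, index: int,
                                          dim: int) -> float:
    """Single-coordinate contraction sum dF^(e)/dx : E, integral-direct.

    ``which`` is "atom" or "site"; ``index``/``dim`` select the coordinate.
    """
    gat, gst = contract_field_derivatives(
        system.shells, system.site_pos, system.dampings, E_supertensor,
        system.molecule.n_atoms)
    if which == "atom":
        return float(gat[index, dim])
    if which == "site":
        return float(gst[index, dim])
    raise ValueError(f"unsupported displacement type {which!r}")


def jk_gradient_corrections(system: IEDRFSystem, D1: np.ndarray,
                            D2: np.ndarray) -> GradientReport:
    """Gradients of Tr(D1 dJ[D2]) - 1/2 Tr(D1 dK[D2]) for two generalized
    densities (the extension seam for response-theory gradients)."""
    n = system.n_pol
    acc = _Accumulator(system)
    if n == 0:
        nuc, chg, sit = acc.totals() if acc.components else (
            np.zeros((system.molecule.n_atoms, 3)),
            np.zeros((len(system.environment.charges), 3)), np.zeros((0, 3)))
        return GradientReport(nuc, chg, sit)
    F, A, AF = system.F_e, system.A, system.AF
    D1s = 0.5 * (D1 + D1.T)
    f1 = np.einsum("iamn,mn->ia", F, D1)
    f2 = np.einsum("iamn,mn->ia", F, D2)
    Af2 = (A @ f2.reshape(-1)).reshape(n, 3)
    Af1 = (A @ f1.reshape(-1)).reshape(n, 3)
    # Coulomb part: Tr(D1 dJ[D2]) = -f1^T A f2
    WF = np.empty_like(F)
    for i in range(n):
        for a in range(3):
            WF[i, a] = -(Af2[i, a] * D1s + Af1[i, a] * 0.5 * (D2 + D2.T))
            # exchange part: -1/2 Tr(D1 dK[D2]) = +1/2 sum A tr(D1 F D2 F)
            AFD = AF[i, a]
            WF[i, a] += 0.5 * 0.5 * (D1 @ AFD @ D2 + D2 @ AFD @ D1
                                     + (D1 @ AFD @ D2 + D2 @ AFD @ D1).T)
    gat, gst = contract_field_derivatives(system.shells, system.site_pos,
                                          system.dampings, WF,
                                          system.molecule.n_atoms)
    acc.add("jk_field", nuclei=gat, sites=gst)
    U = (-np.einsum("p,q->pq", f1.reshape(-1), f2.reshape(-1))
         + 0.5 * np.einsum("iaml,lp,jbpn,nm->iajb", F, D2, F, D1,
                           optimize=True).reshape(3 * n, 3 * n))
    U = 0.5 * (U + U.T)
    acc.add("jk_polarizability",
            sites=polarizability_derivative_contraction(system, U))
    nuc, chg, sit = acc.totals()
    return GradientReport(nuclei=nuc, charges=chg, sites=sit,
                          components=acc.components)
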