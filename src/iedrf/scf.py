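"""Restricted Hartree-Fock with the direct-reaction-field corrections.

The Fock operator is F = H_core + H_pol + (J + dJ) - 1/2 (K + dK), where
H_core contains the kinetic energy, nuclear attraction and the classical
electrostatic embedding of the MM point charges, H_pol the one-electron DRF
correction, and dJ/dK the factorized two-electron DRF corrections.  The total
energy adds the nuclear repulsion, the nucleus/MM-charge Coulomb energy and
the zero-electron constant E0_pol (which contains the MM self-polarization).
Density convention: Tr(D S) = N_elec (doubly occupied spatial orbitals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import drf
from .basis import build_shells, n_ao
from .damping import DampingFunction, damping_radius
from .environment import PolarizableEnvironment
from .geometry import Molecule
from .integrals import (cpp_integrals, damped_field_integrals,
                        electron_repulsion, overlap_kinetic_nuclear)
from .integrals.one_electron import charge_attraction
from .polarization import (build_dipole_field_tensor,
                           build_effective_polarizability)


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFOptions:
    conv_commutator: float = 1e-8     # max |FDS - SDF| (orthonormal basis)
    conv_energy: float = 1e-10        # |dE| between iterations, hartree
    max_iterations: int = 200
    diis: bool = True
    diis_start: int = 2
    diis_space: int = 8
    mixing: float = 0.3               # plain damping before/without DIIS
    ri_mode: str = "exact-same-site"  # or "pure-ri"
    damping_factor: float = 1.0       # r0 = factor * alpha^(1/3)
    thole_a: float = 2.1304
    thole_damped: bool = True
    pseudo_threshold: float = 1e-8
    lindep_threshold: float = 1e-10


@dataclass
class MeanFieldResponse:
    """State-dependent mean-field polarization quantities."""

    fields_at_sites: np.ndarray   # (n_sites, 3)
    induced_p: np.ndarray         # (n_sites, 3)
    E_pol_state: float            # -1/2 f^T A f, hartree


@dataclass
class SCFState:
    D: np.ndarray
    C: np.ndarray
    eps: np.ndarray
    E_total: float
    E_components: dict
    converged: bool
    n_iter: int
    fock: np.ndarray
    n_occ: int = 0


class IEDRFSystem:
    """A QM molecule embedded in a polarizable MM environment.

    Builds and caches every geometry-dependent quantity (integrals, the
    effective polarizability, the DRF corrections); `run_rhf` then iterates
    the SCF on top.
    """

    def __init__(self, molecule: Molecule,
                 environment: PolarizableEnvironment | None = None,
                 basis="sto-3g", options: SCFOptions | None = None):
        self.molecule = molecule
        self.environment = environment or PolarizableEnvironment()
        self.options = options or SCFOptions()
        self.basis = basis
        self.shells = build_shells(molecule, basis)
        self.nao = n_ao(self.shells)
        opts = self.options

        self.S, self.T, self.Vnuc, self.min_eig_S = overlap_kinetic_nuclear(
            self.shells, molecule, opts.lindep_threshold)
        self.eri = electron_repulsion(self.shells)

        env = self.environment
        if env.charges:
            self.Vmm = charge_attraction(self.shells, env.charge_positions,
                                         env.charge_values)
        else:
            self.Vmm = np.zeros_like(self.S)
        self.Hcore = self.T + self.Vnuc + self.Vmm

        # polarizable sites (alpha > 0 only enter the supermatrix)
        self.pol_sites = [s for s in env.sites if s.alpha > 0]
        self.n_pol = len(self.pol_sites)
        self.site_pos = (np.array([s.position for s in self.pol_sites])
                         if self.pol_sites else np.zeros((0, 3)))
        self.dampings = [DampingFunction(
            s.damping_radius if s.damping_radius > 0
            else damping_radius(s.alpha, opts.damping_factor))
            for s in self.pol_sites]

        if self.n_pol:
            tensor = build_dipole_field_tensor(
                self.pol_sites, thole_a=opts.thole_a, damped=opts.thole_damped)
            self.A = build_effective_polarizability(self.pol_sites, tensor).A
            self.F_e = damped_field_integrals(self.shells, self.site_pos,
                                              self.dampings)
            self.Fn = drf.nuclear_field_vectors(molecule, env, self.site_pos,
                                                self.dampings)
            self.AF, self.AFn, self.S_inv = drf.build_intermediates(
                self.F_e, self.Fn, self.A, self.S, opts.pseudo_threshold)
            self.cpp = (cpp_integrals(self.shells, self.site_pos, self.dampings)
                        if opts.ri_mode == "exact-same-site" else None)
            self.H_pol = drf.one_electron_correction(
                self.F_e, self.Fn, self.AF, self.AFn, self.S_inv, self.cpp,
                self.A, opts.ri_mode)
            self.E0_pol = drf.zero_electron_term(self.Fn, self.A)
        else:
            self.A = np.zeros((0, 0))
            self.F_e = np.zeros((0, 3, self.nao, self.nao))
            self.Fn = np.zeros((0, 3))
            self.AF = np.zeros_like(self.F_e)
            self.AFn = np.zeros((0, 3))
            self.S_inv = drf.inverse_overlap(self.S, opts.pseudo_threshold)
            self.cpp = None
            self.H_pol = np.zeros_like(self.S)
            self.E0_pol = 0.0

        self.Vnn = molecule.nuclear_repulsion()
        self.E_nuc_charge = self._nucleus_charge_energy()

    def _nucleus_charge_energy(self) -> float:
        env = self.environment
        if not env.charges:
            return 0.0
        z = self.molecule.atomic_numbers
        d = np.linalg.norm(self.molecule.coords[:, None, :]
                           - env.charge_positions[None, :, :], axis=-1)
        return float((z[:, None] * env.charge_values[None, :] / d).sum())

    # -- J/K builds -------------------------------------------------------
    def jk(self, D: np.ndarray):
        J = np.einsum("mnls,ls->mn", self.eri, D)
        K = np.einsum("mlns,ls->mn", self.eri, D)
        return J, K

    def generalized_jk(self, D: np.ndarray):
        """(J + dJ, K + dK) for an arbitrary real density-like matrix.

        The seam for response/CI layers: D need not be symmetric or
        idempotent.
        """
        J, K = self.jk(D)
        return (J + drf.delta_J(D, self.F_e, self.AF),
                K + drf.delta_K(D, self.F_e, self.AF))

    def fock(self, D: np.ndarray):
        J, K = self.generalized_jk(D)
        return self.Hcore + self.H_pol + J - 0.5 * K, J, K

    def electronic_energy(self, D, J, K) -> float:
        return float(np.einsum("mn,mn->", D, self.Hcore + self.H_pol)
                     + 0.5 * np.einsum("mn,mn->", D, J)
                     - 0.25 * np.einsum("mn,mn->", D, K))

    def total_energy(self, D, J, K) -> float:
        return (self.electronic_energy(D, J, K) + self.Vnn
                + self.E_nuc_charge + self.E0_pol)

    # -- SCF --------------------------------------------------------------
    def run_rhf(self) -> SCFState:
        opts = self.options
        nelec = self.molecule.n_electrons
        if nelec % 2 != 0:
            raise ValueError("restricted closed-shell SCF needs an even "
                             f"electron count, got {nelec}")
        nocc = nelec // 2

        w, V = np.linalg.eigh(self.S)
        keep = w > opts.lindep_threshold * w.max()
        X = V[:, keep] / np.sqrt(w[keep])

        H1 = self.Hcore + self.H_pol
        C, eps = self._diagonalize(H1, X)
        D = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        E_old = None
        diis_F, diis_err = [], []
        converged = False
        for it in range(1, opts.max_iterations + 1):
            F, J, K = self.fock(D)
            E = self.total_energy(D, J, K)
            err = X.T @ (F @ D @ self.S - self.S @ D @ F) @ X
            max_err = np.abs(err).max()
            if E_old is not None and abs(E - E_old) < opts.conv_energy \
                    and max_err < opts.conv_commutator:
                E_old = E
                converged = True
                break
            E_old = E
            if opts.diis and it >= opts.diis_start:
                diis_F.append(F.copy())
                diis_err.append(err.copy())
                if len(diis_F) > opts.diis_space:
                    diis_F.pop(0), diis_err.pop(0)
                if len(diis_F) >= 2:
                    F = _diis_extrapolate(diis_F, diis_err)
            C, eps = self._diagonalize(F, X)
            D_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
            if not opts.diis or it < opts.diis_start:
                D = (1.0 - opts.mixing) * D_new + opts.mixing * D
            else:
                D = D_new

        F, J, K = self.fock(D)
        E = self.total_energy(D, J, K)
        C, eps = self._diagonalize(F, X)
        comps = {
            "nuclear_repulsion": self.Vnn,
            "nuclear_mm_charge": self.E_nuc_charge,
            "E0_pol": self.E0_pol,
            "one_electron": float(np.einsum("mn,mn->", D, self.Hcore)),
            "H_pol": float(np.einsum("mn,mn->", D, self.H_pol)),
            "two_electron": float(0.5 * np.einsum("mn,mn->", D, J)
                                  - 0.25 * np.einsum("mn,mn->", D, K)),
        }
        return SCFState(D=D, C=C, eps=eps, E_total=E, E_components=comps,
                        converged=converged, n_iter=it, fock=F, n_occ=nocc)

    def _diagonalize(self, F, X):
        Ft = X.T @ F @ X
        e, Ct = np.linalg.eigh(Ft)
        return X @ Ct, e

    # -- state-dependent response ----------------------------------------
    def state_polarization(self, state: SCFState) -> MeanFieldResponse:
        """Mean-field fields, induced dipoles and polarization energy of a
        converged state: f = F(n) + tr(D F(e)), p = A f, E = -1/2 f^T A f."""
        f = self.Fn + drf.electron_site_fields(self.F_e, state.D)
        fv = f.reshape(-1)
        p = (self.A @ fv).reshape(-1, 3) if self.n_pol else np.zeros((0, 3))
        E = -0.5 * float(fv @ self.A @ fv) if self.n_pol else 0.0
        return MeanFieldResponse(fields_at_sites=f, induced_p=p, E_pol_state=E)


def _diis_extrapolate(Fs, errs):
    n = len(Fs)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = float((errs[i] * errs[j]).sum())
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return Fs[-1]
    return sum(ci * Fi for ci, Fi in zip(c, Fs))


def run_rhf(molecule: Molecule, basis="sto-3g",
            environment: PolarizableEnvironment | None = None,
            options: SCFOptions | None = None) -> tuple[SCFState, IEDRFSystem]:
    """Convenience wrapper: assemble the system and converge the RHF."""
    system = IEDRFSystem(molecule, environment, basis, options)
    state = system.run_rhf()
    return state, system
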