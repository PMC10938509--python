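"""Assembly of the direct-reaction-field corrections to the Hamiltonian.

The polarization Hamiltonian -1/2 f^T A f, with f the total field operator at
the polarizable sites (QM nuclei + MM charges + electrons), separates into

* a zero-electron constant  E0 = -1/2 F(n)^T A F(n), which also contains the
  MM self-polarization energy (never add it again elsewhere);
* a one-electron correction H_pol: the nucleus-electron cross term plus the
  single-electron self-interaction, the latter evaluated with a
  resolution-of-identity (RI) split over the primary basis, optionally with
  the same-site RI blocks replaced by exact core-polarization-potential (CPP)
  integrals;
* a two-electron correction with factorizable integrals
  (mu nu|la si)_pol = -F(e)_munu^T A F(e)_lasi, consumed through the
  Coulomb/exchange builds delta_J and delta_K.

Sign convention: F(e) is defined with the (r - R_i) numerator so that tracing
with the electron *number* density gives the physical field of the electron
cloud; F(n) uses (R_i - R_n) for positive charges.  The convention is pinned
by the term-by-term energy-assembly identity tested against the SCF energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .damping import DampingFunction
from .environment import PolarizableEnvironment
from .polarization import point_charge_fields

#: refuse the explicit four-index tensor beyond this AO count (oracle use)
MAX_EXPLICIT_AO = 12


@dataclass
class DRFCorrections:
    """Precomputed density-independent DRF quantities."""

    E0_pol: float
    H_pol: np.ndarray           # (nao, nao)
    AF: np.ndarray              # (n_sites, 3, nao, nao)
    AFn: np.ndarray             # (n_sites, 3)
    S_inv: np.ndarray           # (nao, nao), inverse or pseudoinverse of S


def site_fields_from_charges(positions, charges, sites, dampings,
                             exclusion_mask=None) -> np.ndarray:
    """Damped fields of classical point charges at the sites, (n_sites, 3).

    Vectorized kernel shared by the nuclear and MM-charge field builders.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    out = np.zeros((len(sites), 3))
    for i, (R, damp) in enumerate(zip(sites, dampings)):
        rvec = R[None, :] - positions
        r = np.linalg.norm(rvec, axis=1)
        C = damp.value(r)
        w = charges * C / np.where(r > 0, r, 1.0) ** 3
        if exclusion_mask is not None:
            w = np.where(exclusion_mask[:, i], 0.0, w)
        out[i] = (w[:, None] * rvec).sum(axis=0)
    return out


def nuclear_field_vectors(molecule, environment: PolarizableEnvironment,
                          sites_pos, dampings) -> np.ndarray:
    """F^(n): damped fields of QM nuclei and MM point charges, (n_sites, 3).

    QM nuclei are never excluded; MM charges honor the exclusion lists.  The
    damping function is the same one used for the electronic field integrals.
    """
    out = np.zeros((len(sites_pos), 3))
    if molecule is not None and molecule.n_atoms:
        out += site_fields_from_charges(molecule.coords, molecule.atomic_numbers,
                                        sites_pos, dampings)
    if environment is not None and environment.charges:
        mask = _site_exclusion_mask(environment)
        out += site_fields_from_charges(environment.charge_positions,
                                        environment.charge_values,
                                        sites_pos, dampings, mask)
    return out


def _site_exclusion_mask(environment):
    polarizable = [s for s in environment.sites if s.alpha > 0]
    mask = np.zeros((len(environment.charges), len(polarizable)), dtype=bool)
    for n, chg in enumerate(environment.charges):
        for i, s in enumerate(polarizable):
            if s.tag in chg.exclusion_ids:
                mask[n, i] = True
    return mask


def zero_electron_term(Fn: np.ndarray, A: np.ndarray) -> float:
    """E0 = -1/2 F(n)^T A F(n) (Hartree): QM-nuclear polarization energy plus
    the MM polarization energy, added to the classical nuclear repulsion."""
    f = np.asarray(Fn, dtype=float).reshape(-1)
    if f.size == 0:
        return 0.0
    return -0.5 * float(f @ A @ f)


def inverse_overlap(S: np.ndarray, pseudo_threshold: float = 1e-8,
                    allow_pseudo: bool = True) -> np.ndarray:
    """Inverse of S, or the pseudoinverse with small singular values dropped."""
    w, V = np.linalg.eigh(S)
    cut = pseudo_threshold * w.max()
    if w.min() <= cut:
        if not allow_pseudo:
            raise np.linalg.LinAlgError(
                f"overlap matrix near singular (min eig {w.min():.3e}) and the "
                "pseudoinverse pathway is disabled")
        keep = w > cut
        return (V[:, keep] / w[keep]) @ V[:, keep].T
    return (V / w) @ V.T


def build_intermediates(F_e: np.ndarray, Fn: np.ndarray, A: np.ndarray,
                        S: np.ndarray, pseudo_threshold: float = 1e-8):
    """Density-independent tensors AF, AFn and the (pseudo)inverse overlap.

    AF_(i,a,munu) = sum_jb A_(ia,jb) F_(j,b,munu); precomputable once per
    geometry, it carries the only N_pol^2 contraction of the method.
    """
    nsite = F_e.shape[0]
    nao = F_e.shape[-1]
    Ab = A.reshape(nsite, 3, nsite, 3) if nsite else A.reshape(0, 3, 0, 3)
    AF = np.einsum("iajb,jbmn->iamn", Ab, F_e) if nsite else np.zeros_like(F_e)
    AFn = (A @ np.asarray(Fn).reshape(-1)).reshape(nsite, 3) if nsite \
        else np.zeros((0, 3))
    S_inv = inverse_overlap(S, pseudo_threshold)
    return AF, AFn, S_inv


def one_electron_correction(F_e, Fn, AF, AFn, S_inv, cpp, A,
                            ri_mode: str = "exact-same-site") -> np.ndarray:
    """H_pol: cross (nuclear x electronic) term plus electron self-term.

    ``ri_mode``: "exact-same-site" replaces the same-site RI contributions by
    exact CPP integrals weighted with diag(A); "pure-ri" keeps the RI form
    throughout (then ``cpp`` may be None).
    """
    nsite, _, nao, _ = F_e.shape
    H = np.zeros((nao, nao))
    if nsite == 0:
        return H
    H -= np.einsum("ia,iamn->mn", AFn, F_e)
    M = np.einsum("iaml,ls,iasn->mn", F_e, S_inv, AF, optimize=True)
    H -= 0.5 * 0.5 * (M + M.T)
    if ri_mode == "exact-same-site":
        if cpp is None:
            raise ValueError("exact-same-site mode requires CPP integrals")
        Ab = A.reshape(nsite, 3, nsite, 3)
        Adiag = np.einsum("iaib->iab", Ab)
        Mdiag = np.einsum("iaml,ls,ibsn,iab->mn", F_e, S_inv, F_e, Adiag,
                          optimize=True)
        H += 0.5 * 0.5 * (Mdiag + Mdiag.T)
        H -= 0.5 * np.einsum("iab,iabmn->mn", Adiag, cpp)
    elif ri_mode != "pure-ri":
        raise ValueError(f"unknown ri_mode {ri_mode!r}")
    return 0.5 * (H + H.T)


def electron_site_fields(F_e: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Mean field of the electron density at the sites: sum_munu D_munu F_munu."""
    return np.einsum("iamn,mn->ia", F_e, D)


def delta_J(D: np.ndarray, F_e: np.ndarray, AF: np.ndarray) -> np.ndarray:
    """Coulomb-type correction: contraction of (mu nu|la si)_pol with D_lasi,
    via the factorized route."""
    if F_e.shape[0] == 0:
        return np.zeros_like(D)
    fD = electron_site_fields(AF, D)
    return -np.einsum("iamn,ia->mn", F_e, fD)


def delta_K(D: np.ndarray, F_e: np.ndarray, AF: np.ndarray) -> np.ndarray:
    """Exchange-type correction: contraction of (mu la|nu si)_pol with D_lasi."""
    if F_e.shape[0] == 0:
        return np.zeros_like(D)
    return -np.einsum("iaml,ls,iasn->mn", F_e, D, AF, optimize=True)


def explicit_two_electron_tensor(F_e: np.ndarray, A: np.ndarray) -> np.ndarray:
    """(mu nu|la si)_pol = -F(e)_munu^T A F(e)_lasi, dense (oracle use only).

    Carries the full 8-fold ERI permutational symmetry.
    """
    nsite, _, nao, _ = F_e.shape
    if nao > MAX_EXPLICIT_AO:
        raise MemoryError(
            f"explicit four-index polarization tensor refused for {nao} AOs")
    if nsite == 0:
        return np.zeros((nao, nao, nao, nao))
    Fflat = F_e.reshape(3 * nsite, nao, nao)
    return -np.einsum("pmn,pq,qls->mnls",
                      Fflat, A.reshape(3 * nsite, 3 * nsite)[
                          :Fflat.shape[0], :Fflat.shape[0]], Fflat,
                      optimize=True)
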