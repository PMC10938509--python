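"""Interacting induced-dipole model of the MM environment.

An external field f induces dipoles p_i = alpha_i (f_i + sum_j T^(ij) p_j);
solving the coupled equations gives p = A f with the effective polarizability
supermatrix A = (alpha^-1 - T)^-1 (Applequist's model).  The dipole field
tensor T^(ij) is damped at short range with Thole's exponential-density
scheme to suppress the polarization catastrophe.

Units: positions bohr, polarizabilities bohr^3, fields hartree/(e bohr),
energies hartree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .damping import DampingFunction
from .environment import PolarizableEnvironment, PolarizableSite, PointCharge

#: Thole width parameter for the exponential damping density (van
#: Duijnen-Swart refit).
THOLE_A_DEFAULT = 2.1304


class SingularGeometryError(ValueError):
    pass


class PolarizationCatastropheError(ValueError):
    pass


@dataclass
class DipoleFieldTensor:
    """All 3x3 blocks T^(ij) (bohr^-3) plus the damping scheme used."""

    blocks: np.ndarray          # (N, N, 3, 3); diagonal blocks zero
    damping_scheme: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.blocks.shape[0]


@dataclass
class EffectivePolarizability:
    """Dense symmetric supermatrix A (3N x 3N, bohr^3) with p = A f."""

    A: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.A.shape[0] // 3


def _thole_lambdas(r: float, s: float, a: float):
    """Damping factors lambda3, lambda5 and radial derivatives at separation r.

    s = (alpha_i alpha_j)^(1/6) is the Thole width; x = a (r/s)^3.
    """
    x = a * (r / s) ** 3
    ex = np.exp(-x)
    l3 = -np.expm1(-x)
    l5 = 1.0 - (1.0 + x) * ex
    dxdr = 3.0 * a * r * r / s ** 3
    return l3, l5, ex * dxdr, x * ex * dxdr


def _pair_tensor(rvec: np.ndarray, s: float, a: float, damped: bool):
    r = float(np.linalg.norm(rvec))
    if r == 0.0:
        raise SingularGeometryError("coincident polarizable sites")
    if damped:
        l3, l5, _, _ = _thole_lambdas(r, s, a)
    else:
        l3 = l5 = 1.0
    rr = np.outer(rvec, rvec) / r ** 2
    return (3.0 * l5 * rr - l3 * np.eye(3)) / r ** 3


def build_dipole_field_tensor(sites: list[PolarizableSite], *,
                              thole_a: float = THOLE_A_DEFAULT,
                              damped: bool = True) -> DipoleFieldTensor:
    """All N^2 blocks of the (damped) point-dipole interaction tensor.

    Block (i, j) gives the field at site i of a unit dipole at site j.
    Undamped far field: (3 rhat rhat^T - 1)/r^3.
    """
    if not sites:
        raise ValueError("at least one polarizable site required")
    n = len(sites)
    blocks = np.zeros((n, n, 3, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rvec = sites[i].position - sites[j].position
            s = (sites[i].alpha * sites[j].alpha) ** (1.0 / 6.0)
            if s == 0.0 and damped:
                # zero-alpha sites carry no dipole; damping scale irrelevant
                s = 1.0
            blocks[i, j] = _pair_tensor(rvec, s, thole_a, damped)
    scheme = {"form": "thole-exponential" if damped else "none", "a": thole_a}
    return DipoleFieldTensor(blocks, scheme)


def build_effective_polarizability(sites: list[PolarizableSite],
                                   tensor: DipoleFieldTensor,
                                   cond_limit: float = 1e12) -> EffectivePolarizability:
    """Solve the Applequist system: A = (alpha^-1 - T)^-1 via dense LU.

    Sites with alpha = 0 must be excluded by the caller (the inverted
    formulation presumes invertible atomic polarizabilities).
    """
    n = len(sites)
    alphas = np.array([s.alpha for s in sites])
    if np.any(alphas <= 0):
        raise ValueError("all sites must have alpha > 0; drop alpha = 0 sites")
    M = np.zeros((3 * n, 3 * n))
    for i in range(n):
        M[3 * i: 3 * i + 3, 3 * i: 3 * i + 3] = np.eye(3) / alphas[i]
        for j in range(n):
            if i != j:
                M[3 * i: 3 * i + 3, 3 * j: 3 * j + 3] = -tensor.blocks[i, j]
    M = 0.5 * (M + M.T)
    # stability: the damped Applequist system is physical only when
    # alpha^-1 - T is positive definite
    w = np.linalg.eigvalsh(M)
    if w[0] <= 0.0 or w[-1] / w[0] > cond_limit:
        i, j = _offending_pair(sites)
        raise PolarizationCatastropheError(
            f"dipole-interaction matrix is unstable or near singular "
            f"(polarization catastrophe); closest scaled pair: sites "
            f"{sites[i].tag} and {sites[j].tag}")
    lu, piv = scipy.linalg.lu_factor(M)
    A = scipy.linalg.lu_solve((lu, piv), np.eye(3 * n))
    return EffectivePolarizability(0.5 * (A + A.T))


def _offending_pair(sites):
    best, pair = np.inf, (0, 0)
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            r = np.linalg.norm(sites[i].position - sites[j].position)
            s = max((sites[i].alpha * sites[j].alpha) ** (1.0 / 6.0), 1e-12)
            if r / s < best:
                best, pair = r / s, (i, j)
    return pair


def point_charge_fields(charges: list[PointCharge],
                        sites: list[PolarizableSite],
                        warn_close: float = 1e-6) -> np.ndarray:
    """Damped fields of the MM point charges at the sites (supervector, 3N).

    f_i = sum_n Q_n C_i(r_in) (R_i - R_n) / r_in^3, skipping excluded charges;
    the field of a positive charge points from the charge toward the site.
    Each site's own damping function C_i regularizes close approaches.
    """
    f = np.zeros(3 * len(sites))
    for i, site in enumerate(sites):
        damp = DampingFunction(site.damping_radius) if site.alpha > 0 else None
        acc = np.zeros(3)
        for chg in charges:
            if site.tag in chg.exclusion_ids:
                continue
            rvec = site.position - chg.position
            r = np.linalg.norm(rvec)
            if r < warn_close:
                warnings.warn(
                    f"point charge {chg.tag} coincides with polarizable site "
                    f"{site.tag} and is not excluded; damping keeps the field finite")
                continue
            C = damp.value(r) if damp is not None else 1.0
            acc += chg.charge * C * rvec / r ** 3
        f[3 * i: 3 * i + 3] = acc
    return f


def induced_dipoles(A: EffectivePolarizability | np.ndarray,
                    f_total: np.ndarray) -> np.ndarray:
    """p = A f."""
    A = A.A if isinstance(A, EffectivePolarizability) else A
    return A @ np.asarray(f_total, dtype=float)


def polarization_energy(A: EffectivePolarizability | np.ndarray,
                        f: np.ndarray) -> float:
    """Classical mean-field polarization energy E = -1/2 f^T A f (hartree)."""
    A = A.A if isinstance(A, EffectivePolarizability) else A
    f = np.asarray(f, dtype=float)
    return -0.5 * float(f @ A @ f)


def molecular_polarizability(sites: list[PolarizableSite], *,
                             thole_a: float = THOLE_A_DEFAULT,
                             damped: bool = True) -> np.ndarray:
    """3x3 molecular polarizability tensor of a site cluster.

    Sum of all 3x3 blocks of the cluster's own effective polarizability: the
    total dipole induced by a uniform field.
    """
    if len(sites) == 1:
        return sites[0].alpha * np.eye(3)
    tensor = build_dipole_field_tensor(sites, thole_a=thole_a, damped=damped)
    A = build_effective_polarizability(sites, tensor).A
    n = len(sites)
    blocks = A.reshape(n, 3, n, 3)
    return blocks.sum(axis=(0, 2))


def coarse_grain(environment: PolarizableEnvironment, qm_coords: np.ndarray,
                 cutoff: float, *, thole_a: float = THOLE_A_DEFAULT,
                 damped: bool = True) -> PolarizableEnvironment:
    """Replace far molecules' atomic sites by one isotropic molecular site.

    A molecule is "far" when all of its polarizable atoms are farther than
    ``cutoff`` (bohr) from every QM atom.  Its sites are replaced by a single
    site placed on the member atom closest to the molecular centroid, with
    alpha equal to the eigenvalue mean of the molecular polarizability tensor
    (rotation invariant).  Point charges are untouched.
    """
    qm_coords = np.asarray(qm_coords, dtype=float).reshape(-1, 3)
    new_sites: list[PolarizableSite] = []
    for mol, members in environment.molecules().items():
        idx = members["sites"]
        if not idx:
            continue
        msites = [environment.sites[i] for i in idx]
        if mol is None:
            new_sites.extend(msites)
            continue
        pos = np.array([s.position for s in msites])
        if qm_coords.size:
            dmin = np.min(np.linalg.norm(pos[:, None, :] - qm_coords[None, :, :],
                                         axis=-1))
        else:
            dmin = np.inf
        if dmin <= cutoff:
            new_sites.extend(msites)
            continue
        if all(s.alpha == 0 for s in msites):
            warnings.warn(f"molecule {mol}: no polarizable atoms, skipped")
            new_sites.extend(msites)
            continue
        pol = molecular_polarizability([s for s in msites if s.alpha > 0],
                                       thole_a=thole_a, damped=damped)
        alpha_iso = float(np.linalg.eigvalsh(pol).mean())
        centroid = pos.mean(axis=0)
        carrier = msites[int(np.argmin(np.linalg.norm(pos - centroid, axis=1)))]
        new_sites.append(PolarizableSite(carrier.position, alpha_iso,
                                         tag=carrier.tag, molecule=mol))
    return PolarizableEnvironment(new_sites, list(environment.charges))


def dipole_tensor_derivative(sites: list[PolarizableSite], i: int, j: int, *,
                             thole_a: float = THOLE_A_DEFAULT,
                             damped: bool = True) -> np.ndarray:
    """d T^(ij) / d R_j as an array (3_gamma, 3_alpha, 3_beta).

    The derivative with respect to R_i is the negative.  Damping lengths are
    geometry-independent constants.
    """
    rvec = sites[i].position - sites[j].position
    r = float(np.linalg.norm(rvec))
    s = (sites[i].alpha * sites[j].alpha) ** (1.0 / 6.0) or 1.0
    if damped:
        l3, l5, dl3, dl5 = _thole_lambdas(r, s, thole_a)
    else:
        l3, l5, dl3, dl5 = 1.0, 1.0, 0.0, 0.0
    rhat = rvec / r
    eye = np.eye(3)
    out = np.zeros((3, 3, 3))
    for g in range(3):
        term = (3.0 * dl5 * rhat[g] * np.outer(rhat, rhat) / r ** 3
                + 3.0 * l5 * ((np.outer(eye[g], rvec) + np.outer(rvec, eye[g])) / r ** 5
                              - 5.0 * np.outer(rvec, rvec) * rvec[g] / r ** 7)
                - dl3 * rhat[g] * eye / r ** 3
                + 3.0 * l3 * eye * rvec[g] / r ** 5)
        out[g] = -term  # d/dR_j = -d/dr with r = R_i - R_j
    return out
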