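"""Synthetic fixtures: toy molecules and generated solvent shells.

The solvent-shell generator stands in for an MD solvation protocol: it packs
rigid, linear, apolar three-site "solvent" molecules (quadrupolar charge
pattern summing to zero, atomic polarizabilities on every site) around the QM
region by seeded rejection sampling with minimum-distance constraints.  It is
deliberately crude — no Lennard-Jones structure, no orientational
correlations — but reproduces the features the embedding responds to: net
neutral molecules, realistic polarizability density and exclusion lists.
"""

from __future__ import annotations

import numpy as np

from .environment import PointCharge, PolarizableEnvironment, PolarizableSite
from .geometry import Molecule

#: rigid solvent geometry/parameters (bohr, e, bohr^3)
SOLVENT_BOND = 2.8
SOLVENT_CHARGES = (-0.15, 0.30, -0.15)
SOLVENT_ALPHAS = (1.5, 3.0, 1.5)


class PackingError(RuntimeError):
    pass


def h2(bond: float = 1.4) -> Molecule:
    return Molecule(["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, bond]])


def heh_plus(bond: float = 1.46) -> Molecule:
    return Molecule(["He", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, bond]], charge=1)


def water() -> Molecule:
    from .units import angstrom_to_bohr
    coords = np.array([[0.0, 0.0, 0.1173],
                       [0.0, 0.7572, -0.4692],
                       [0.0, -0.7572, -0.4692]])
    return Molecule(["O", "H", "H"], angstrom_to_bohr(coords))


def _solvent_molecule(center, axis, mol_id, tag0, bond, alphas, charges_q):
    axis = axis / np.linalg.norm(axis)
    positions = [center - bond * axis, center, center + bond * axis]
    tags = [tag0, tag0 + 1, tag0 + 2]
    excl = frozenset(tags)
    sites = [PolarizableSite(p, a, tag=t, molecule=mol_id)
             for p, a, t in zip(positions, alphas, tags)]
    charges = [PointCharge(p, q, exclusion_ids=excl, tag=t, molecule=mol_id)
               for p, q, t in zip(positions, charges_q, tags) if q != 0.0]
    return sites, charges, positions


def generate_solvent_shell(seed: int, n_molecules: int,
                           qm_coords=None,
                           density: float = 0.002,
                           qm_exclusion_radius: float = 6.0,
                           min_intermolecular: float = 4.0,
                           max_attempts: int = 100000,
                           bond: float = SOLVENT_BOND,
                           alphas=SOLVENT_ALPHAS,
                           charges=SOLVENT_CHARGES) -> PolarizableEnvironment:
    """Pack ``n_molecules`` rigid solvent molecules around the QM region.

    ``density`` (molecules/bohr^3) sets the outer shell radius; molecule
    centers are drawn uniformly from the spherical shell between
    ``qm_exclusion_radius`` and that radius.  All placements are
    rejection-sampled so that no solvent atom comes closer than
    ``qm_exclusion_radius`` to any QM atom or ``min_intermolecular`` to an
    atom of an already-placed molecule.  Deterministic for a given seed.
    """
    if n_molecules == 0:
        return PolarizableEnvironment()
    qm = (np.asarray(qm_coords, dtype=float).reshape(-1, 3)
          if qm_coords is not None else np.zeros((1, 3)))
    rng = np.random.default_rng(seed)
    r_in = qm_exclusion_radius
    vol = n_molecules / density
    r_out = (r_in ** 3 + 3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)

    placed_atoms: list[np.ndarray] = []
    sites_all, charges_all = [], []
    count, attempts = 0, 0
    while count < n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"failed to place molecule {count + 1}/{n_molecules} after "
                f"{max_attempts} attempts; relax the packing parameters")
        # uniform point in shell
        u = rng.random()
        r = (r_in ** 3 + u * (r_out ** 3 - r_in ** 3)) ** (1.0 / 3.0)
        direc = rng.normal(size=3)
        direc /= np.linalg.norm(direc)
        center = qm.mean(axis=0) + r * direc
        axis = rng.normal(size=3)
        sites, mol_charges, positions = _solvent_molecule(
            center, axis, mol_id=count, tag0=3 * count,
            bond=bond, alphas=alphas, charges_q=charges)
        pos = np.array(positions)
        if np.min(np.linalg.norm(pos[:, None, :] - qm[None, :, :], axis=-1)) \
                < qm_exclusion_radius:
            continue
        if placed_atoms:
            prev = np.array(placed_atoms)
            if np.min(np.linalg.norm(pos[:, None, :] - prev[None, :, :],
                                     axis=-1)) < min_intermolecular:
                continue
        placed_atoms.extend(positions)
        sites_all.extend(sites)
        charges_all.extend(mol_charges)
        count += 1
    return PolarizableEnvironment(sites_all, charges_all)


def far_shell_fixture(seed: int, n_molecules: int = 40) -> PolarizableEnvironment:
    """The designed far-shell fixture for coarse-graining checks.

    Uncharged, weakly coupled solvent molecules (bond 3.5 bohr, alphas
    0.2/1.0/0.2 bohr^3) on a distant shell (60-85 bohr from the origin, well
    beyond any coarse-graining cutoff).  Designed so that the two intrinsic
    grouping errors — molecular-polarizability anisotropy lost by the
    eigenvalue mean, and the positional lumping of spread sites — each stay
    well below 1% of the polarization energy of a central probe.
    """
    return generate_solvent_shell(
        seed, n_molecules, density=n_molecules * 3.0 / (4.0 * np.pi)
        / (85.0 ** 3 - 60.0 ** 3), qm_exclusion_radius=60.0,
        min_intermolecular=9.0, bond=3.5, alphas=(0.2, 1.0, 0.2),
        charges=(0.0, 0.0, 0.0))
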