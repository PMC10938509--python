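"""The classical MM environment: point charges and polarizable sites.

The environment file is a YAML/JSON document with one ``atoms`` list; each
atom may carry a partial charge ``q`` (elementary charges), an isotropic
dipole polarizability ``alpha`` (bohr^3), or both.  Coordinates are in
Angstrom externally and bohr internally.  A ``bonds`` list (pairs of atom
ids) generates the default exclusions — the monopole field of a charge is
suppressed at polarizable sites on the same atom and on 1-2 and 1-3 bonded
neighbors; additional explicit ``exclusions`` pairs ``[charge_id, site_id]``
may be given.  Without a bond list, exclusions must be explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .damping import damping_radius
from .units import angstrom_to_bohr


@dataclass
class PolarizableSite:
    """An MM atom carrying an isotropic point polarizability (bohr^3)."""

    position: np.ndarray        # (3,), bohr
    alpha: float
    damping_radius: float = 0.0  # bohr; derived from alpha if not given
    tag: int = -1                # originating atom id
    molecule: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.alpha < 0:
            raise ValueError("site polarizability must be non-negative")
        if self.alpha > 0 and self.damping_radius <= 0:
            self.damping_radius = damping_radius(self.alpha)


@dataclass
class PointCharge:
    """An MM partial charge; ``exclusion_ids`` are site tags at which this
    charge's monopole field is suppressed."""

    position: np.ndarray        # (3,), bohr
    charge: float               # elementary charges
    exclusion_ids: frozenset = field(default_factory=frozenset)
    tag: int = -1
    molecule: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.exclusion_ids = frozenset(self.exclusion_ids)


class EnvironmentError_(ValueError):
    pass


@dataclass
class PolarizableEnvironment:
    """Container for the MM region (classical part of the charge density)."""

    sites: list[PolarizableSite] = field(default_factory=list)
    charges: list[PointCharge] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_positions(self) -> np.ndarray:
        if not self.sites:
            return np.zeros((0, 3))
        return np.array([s.position for s in self.sites])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([s.alpha for s in self.sites])

    @property
    def charge_positions(self) -> np.ndarray:
        if not self.charges:
            return np.zeros((0, 3))
        return np.array([c.position for c in self.charges])

    @property
    def charge_values(self) -> np.ndarray:
        return np.array([c.charge for c in self.charges])

    def exclusion_mask(self) -> np.ndarray:
        """Boolean (n_charges, n_sites): True where the field is suppressed."""
        mask = np.zeros((len(self.charges), len(self.sites)), dtype=bool)
        tags = [s.tag for s in self.sites]
        for n, chg in enumerate(self.charges):
            for i, t in enumerate(tags):
                if t in chg.exclusion_ids:
                    mask[n, i] = True
        return mask

    def molecules(self) -> dict:
        """Group site/charge indices by molecule label."""
        out: dict = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s.molecule, {"sites": [], "charges": []})["sites"].append(i)
        for n, c in enumerate(self.charges):
            out.setdefault(c.molecule, {"sites": [], "charges": []})["charges"].append(n)
        return out

    def displaced_site(self, i: int, delta) -> "PolarizableEnvironment":
        sites = [PolarizableSite(s.position + (delta if k == i else 0.0), s.alpha,
                                 s.damping_radius, s.tag, s.molecule)
                 for k, s in enumerate(self.sites)]
        return PolarizableEnvironment(sites, list(self.charges))

    def displaced_charge(self, n: int, delta) -> "PolarizableEnvironment":
        charges = [PointCharge(c.position + (delta if k == n else 0.0), c.charge,
                               c.exclusion_ids, c.tag, c.molecule)
                   for k, c in enumerate(self.charges)]
        return PolarizableEnvironment(list(self.sites), charges)


def _bond_exclusions(bonds, max_separation: int = 2) -> dict[int, set]:
    """Atom id -> set of atom ids within ``max_separation`` bonds (incl. self)."""
    adj: dict[int, set] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    out: dict[int, set] = {}
    ids = set(adj)
    for start in ids:
        seen = {start}
        frontier = {start}
        for _ in range(max_separation):
            frontier = set().union(*(adj.get(x, set()) for x in frontier)) - seen
            seen |= frontier
        out[start] = seen
    return out


def environment_from_dict(doc: dict) -> PolarizableEnvironment:
    """Build an environment from the documented schema (coordinates in A)."""
    known = {"atoms", "bonds", "exclusions", "comment"}
    unknown = set(doc) - known
    if unknown:
        raise EnvironmentError_(f"unknown environment keys: {sorted(unknown)}")
    atoms = doc.get("atoms", [])
    bonds = [tuple(b) for b in doc.get("bonds", [])]
    explicit = [tuple(e) for e in doc.get("exclusions", [])]
    neigh = _bond_exclusions(bonds) if bonds else {}

    sites, charges = [], []
    seen_ids = set()
    akeys = {"id", "x", "y", "z", "q", "alpha", "molecule"}
    for k, atom in enumerate(atoms):
        bad = set(atom) - akeys
        if bad:
            raise EnvironmentError_(f"atom entry {k}: unknown keys {sorted(bad)}")
        aid = atom.get("id", k)
        if aid in seen_ids:
            raise EnvironmentError_(f"duplicate atom id {aid}")
        seen_ids.add(aid)
        pos = angstrom_to_bohr(np.array([atom["x"], atom["y"], atom["z"]], dtype=float))
        mol = atom.get("molecule")
        alpha = float(atom.get("alpha", 0.0))
        if alpha > 0:
            sites.append(PolarizableSite(pos, alpha, tag=aid, molecule=mol))
        q = float(atom.get("q", 0.0))
        if q != 0.0:
            excl = set(neigh.get(aid, {aid} if bonds else set()))
            if bonds:
                excl.add(aid)
            excl |= {sid for cid, sid in explicit if cid == aid}
            charges.append(PointCharge(pos, q, frozenset(excl), tag=aid, molecule=mol))
    return PolarizableEnvironment(sites, charges)


def read_environment(path) -> PolarizableEnvironment:
    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise EnvironmentError_(f"{path}: expected a mapping at top level")
    return environment_from_dict(doc)
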