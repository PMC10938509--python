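"""QM geometries: element data, the Molecule container and XYZ input."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import angstrom_to_bohr

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}

# Standard atomic weights (amu); used only for centre-of-mass bookkeeping.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
}


@dataclass
class Molecule:
    """A QM molecule: element symbols and nuclear coordinates in bohr."""

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), bohr
    charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coords.shape[0]:
            raise ValueError("symbol/coordinate count mismatch")
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {s!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(round(self.atomic_numbers.sum())) - self.charge

    def nuclear_repulsion(self) -> float:
        z = self.atomic_numbers
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def displaced(self, atom: int, delta: np.ndarray) -> "Molecule":
        coords = self.coords.copy()
        coords[atom] += delta
        return Molecule(list(self.symbols), coords, self.charge)


def read_xyz(path, charge: int = 0) -> Molecule:
    """Read a standard XYZ file (coordinates in Angstrom)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first line of an XYZ file must be the atom count") from exc
    symbols, coords = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if len(symbols) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(symbols)}")
    return Molecule(symbols, angstrom_to_bohr(np.array(coords)), charge=charge)
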