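"""Gaussian basis sets: shells, normalization and the Gaussian-94 text dialect.

Only s and p shells are supported; that is enough for the minimal-basis
molecules this package targets, and the integral code guards against higher
angular momenta with a clear error.

AO convention: shells appear in input order; a p shell contributes three
Cartesian components in the fixed order (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import pi

import numpy as np

from .geometry import Molecule

MAX_L = 1

#: Cartesian power triples per angular momentum, in AO order.
CARTESIAN_POWERS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
}


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, powers: tuple[int, int, int]) -> float:
    """Normalization constant of a Cartesian primitive x^i y^j z^k exp(-a r^2)."""
    i, j, k = powers
    l = i + j + k
    num = (2.0 * alpha / pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(float(_double_factorial(2 * i - 1)
                        * _double_factorial(2 * j - 1)
                        * _double_factorial(2 * k - 1)))
    return num / den


@dataclass
class BasisShell:
    """A contracted shell of Cartesian Gaussians on one center.

    ``coefs`` are contraction coefficients for *unit-normalized primitives*;
    the constructor folds in primitive norms and rescales so every AO in the
    shell has <mu|mu> = 1.
    """

    center: np.ndarray            # (3,), bohr
    l: int                        # angular momentum (0 or 1)
    exps: np.ndarray              # (nprim,)
    coefs: np.ndarray             # (nprim,) raw contraction coefficients
    atom_index: int = -1          # which QM atom carries this shell

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.l > MAX_L:
            raise NotImplementedError(
                f"angular momentum l={self.l} not supported (s and p shells only)")
        if np.any(self.exps <= 0):
            raise ValueError("primitive exponents must be positive")
        # Fold primitive norms (same for every component of the shell because
        # the norm depends only on the distribution of powers up to axis
        # permutation) and rescale the contraction to unit self-overlap.
        powers = CARTESIAN_POWERS[self.l][0]
        norms = np.array([primitive_norm(a, powers) for a in self.exps])
        c = self.coefs * norms
        # <mu|mu> for a Cartesian primitive pair on one center.
        ee = self.exps[:, None] + self.exps[None, :]
        ltot = self.l
        self_ov = (c[:, None] * c[None, :] * (pi / ee) ** 1.5
                   / (2.0 * ee) ** ltot).sum() * _double_factorial(2 * ltot - 1)
        self.coefs = c / np.sqrt(self_ov)

    @property
    def n_ao(self) -> int:
        return len(CARTESIAN_POWERS[self.l])

    @property
    def ao_powers(self) -> list[tuple[int, int, int]]:
        return CARTESIAN_POWERS[self.l]


def parse_g94(text: str) -> dict[str, list[tuple[str, np.ndarray, np.ndarray]]]:
    """Parse Gaussian-94 style basis text into per-element shell blocks.

    Returns ``{element: [(shell_type, exponents, coefficient_columns), ...]}``
    where ``shell_type`` is "S", "P" or "SP" and ``coefficient_columns`` has one
    column per sub-shell.
    """
    blocks: dict[str, list] = {}
    lines = [ln.split("!")[0].strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    i = 0
    while i < len(lines):
        if lines[i] == "****":
            i += 1
            continue
        header = lines[i].split()
        element = header[0].capitalize()
        i += 1
        shells = []
        while i < len(lines) and lines[i] != "****":
            st, nprim, _scale = lines[i].split()
            st = st.upper()
            nprim = int(nprim)
            rows = [lines[i + 1 + k].replace("D", "E").replace("d", "e").split()
                    for k in range(nprim)]
            arr = np.array([[float(x) for x in row] for row in rows])
            shells.append((st, arr[:, 0], arr[:, 1:]))
            i += 1 + nprim
        blocks[element] = shells
    return blocks


def load_basis(name_or_path: str = "sto-3g") -> dict[str, list]:
    """Load a basis set by bundled name or from a Gaussian-94 text file."""
    try:
        with open(name_or_path) as fh:
            return parse_g94(fh.read())
    except (OSError, IsADirectoryError):
        pass
    fname = f"{name_or_path.lower()}.g94"
    ref = resources.files("iedrf.data").joinpath(fname)
    if not ref.is_file():
        raise FileNotFoundError(
            f"basis {name_or_path!r}: not a readable file and no bundled basis {fname!r}")
    return parse_g94(ref.read_text())


_LMAP = {"S": 0, "P": 1}


def build_shells(molecule: Molecule, basis="sto-3g") -> list[BasisShell]:
    """Construct the shell list for a molecule.

    ``basis`` may be a bundled basis name, a path to a Gaussian-94 file, or an
    already-parsed block dictionary.
    """
    blocks = basis if isinstance(basis, dict) else load_basis(basis)
    shells: list[BasisShell] = []
    for ia, sym in enumerate(molecule.symbols):
        if sym not in blocks:
            raise ValueError(f"basis has no entry for element {sym}")
        for st, exps, cols in blocks[sym]:
            subtypes = list(st) if st != "SP" else ["S", "P"]
            for col, sub in enumerate(subtypes):
                shells.append(BasisShell(
                    center=molecule.coords[ia], l=_LMAP[sub],
                    exps=exps, coefs=cols[:, col], atom_index=ia))
    return shells


def n_ao(shells: list[BasisShell]) -> int:
    return sum(sh.n_ao for sh in shells)


def ao_shell_map(shells: list[BasisShell]) -> list[tuple[int, int]]:
    """Map AO index -> (shell index, component index)."""
    out = []
    for ish, sh in enumerate(shells):
        for comp in range(sh.n_ao):
            out.append((ish, comp))
    return out
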