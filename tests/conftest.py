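import numpy as np
import pytest

from iedrf.basis import BasisShell, build_shells
from iedrf.damping import DampingFunction
from iedrf.environment import (PointCharge, PolarizableEnvironment,
                               PolarizableSite)
from iedrf.fixtures import h2, heh_plus, water
from iedrf.scf import SCFOptions


@pytest.fixture(scope="session")
def h2_molecule():
    return h2()


@pytest.fixture(scope="session")
def h2_shells(h2_molecule):
    return build_shells(h2_molecule)


@pytest.fixture(scope="session")
def water_molecule():
    return water()


@pytest.fixture(scope="session")
def tight_scf():
    return SCFOptions(conv_energy=1e-12, conv_commutator=1e-10)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_shell(rng, l=None, center_scale=2.0, nprim=2):
    """A random contracted s or p shell with exponents in [0.1, 50]."""
    if l is None:
        l = int(rng.integers(0, 2))
    exps = np.exp(rng.uniform(np.log(0.1), np.log(50.0), size=nprim))
    coefs = rng.uniform(0.3, 1.0, size=nprim)
    center = rng.normal(scale=center_scale, size=3)
    return BasisShell(center=center, l=l, exps=exps, coefs=coefs, atom_index=0)


def random_sites(rng, n, alpha_range=(0.5, 2.0), scale=4.0, min_sep=2.0,
                 tries=500):
    """Well-separated random polarizable sites (stable Applequist system)."""
    pos = []
    for _ in range(tries):
        if len(pos) == n:
            break
        cand = rng.normal(scale=scale, size=3)
        if all(np.linalg.norm(cand - p) > min_sep for p in pos):
            pos.append(cand)
    assert len(pos) == n, "could not place sites"
    return [PolarizableSite(p, float(rng.uniform(*alpha_range)), tag=i)
            for i, p in enumerate(pos)]


def rotation_matrix(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


@pytest.fixture()
def small_env():
    sites = [PolarizableSite([1.5, 1.0, 2.0], 1.1, tag=10),
             PolarizableSite([2.5, 0.2, 1.2], 0.8, tag=11)]
    charges = [PointCharge([2.0, 1.8, 2.5], 0.3, exclusion_ids={10}, tag=20),
               PointCharge([-2.0, 1.5, -0.8], -0.3, tag=21)]
    return PolarizableEnvironment(sites, charges)
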