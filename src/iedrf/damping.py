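"""Short-range damping of the polarization operator.

Point-induced-dipole sites interacting with a point charge density produce
|r - R|^(-k) kernels with k up to 6; physically the MM sites have a finite
charge distribution, so the kernels are regularized by a cutoff function C(r)
with C(0) = 0 and C -> 1 at long range. The default form

    C(r) = (1 - exp(-(r/r0)^2))^2,     r0 = factor * alpha^(1/3)

vanishes like r^4 at the origin — enough zeros to regularize every kernel used
(the core-polarization-potential kernel C^2/r^4 then behaves like r^4) — and,
being a finite sum of Gaussians, keeps the damped field integrals exactly
expressible through Boys-function machinery.  The same C(r) is applied to the
electronic, nuclear and MM point-charge fields so that the fields of a neutral
atom cancel properly at short and intermediate range.

Alternative forms can be swapped in by subclassing :class:`DampingFunction`;
only ``gaussian_expansion`` is specific to the analytic integral path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DampingFunction:
    """Gaussian-squared cutoff C(r) = (1 - exp(-(r/r0)^2))^2 for one site."""

    r0: float  # length scale, bohr

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("damping radius r0 must be positive")

    def value(self, r):
        u = (np.asarray(r, dtype=float) / self.r0) ** 2
        return np.expm1(-u) ** 2

    __call__ = value

    def derivative(self, r):
        """dC/dr."""
        r = np.asarray(r, dtype=float)
        u = (r / self.r0) ** 2
        return -2.0 * np.expm1(-u) * np.exp(-u) * 2.0 * r / self.r0 ** 2

    def gaussian_expansion(self):
        """C(r) as sum_m c_m exp(-k_m r^2); returns (coeffs, exponents)."""
        k = 1.0 / self.r0 ** 2
        return np.array([1.0, -2.0, 1.0]), np.array([0.0, k, 2.0 * k])

    def field_kernel(self, rvec):
        """Damped unit-charge field C(r) * rvec / r^3, batched over rows."""
        rvec = np.asarray(rvec, dtype=float)
        r = np.linalg.norm(rvec, axis=-1)
        u = (r / self.r0) ** 2
        # C(r)/r^3 -> expm1(-u)^2 / r^3 is ~ r of magnitude u^2/r^3 ~ r at 0.
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(r > 0, np.expm1(-u) ** 2 / np.where(r > 0, r, 1.0) ** 3, 0.0)
        return rvec * scale[..., None]

    def cpp_kernel(self, rvec):
        """Damped CPP kernel C(r)^2 r_a r_b / r^6 as a batch of 3x3 matrices."""
        rvec = np.asarray(rvec, dtype=float)
        r2 = (rvec ** 2).sum(axis=-1)
        u = r2 / self.r0 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(r2 > 0, np.expm1(-u) ** 4 / np.where(r2 > 0, r2, 1.0) ** 3, 0.0)
        return rvec[..., :, None] * rvec[..., None, :] * scale[..., None, None]


def damping_radius(alpha: float, factor: float = 1.0) -> float:
    """Damping length tied to the site polarizability: r0 = factor * alpha^(1/3)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive to derive a damping radius")
    return factor * alpha ** (1.0 / 3.0)


def site_damping(site, factor: float = 1.0) -> DampingFunction:
    r0 = getattr(site, "damping_radius", None)
    if r0 is None or r0 <= 0:
        r0 = damping_radius(site.alpha, factor)
    return DampingFunction(r0)
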