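"""McMurchie-Davidson Hermite machinery, vectorized over primitive batches.

A product of Cartesian monomial factors with a Gaussian,

    prod_k (x - C_k)^(p_k) * exp(-q (x - Q)^2),

is expanded in Hermite Gaussians Lambda_t(x; q, Q) = (d/dQ)^t exp(-q(x-Q)^2)
via the recursion (x - Q) Lambda_t = Lambda_(t+1)/(2q) + t Lambda_(t-1).
Coulomb-type integrals of Hermite Gaussians reduce to the auxiliary tensor
R_tuv built from Boys functions.
"""

from __future__ import annotations

import numpy as np

from .boys import boys


def hermite_coeffs_1d(factors, q):
    """Hermite expansion coefficients of a 1-D monomial-Gaussian product.

    Parameters
    ----------
    factors : list of ``(power, d)`` where ``d = Q - C`` is the (batched)
        offset of the monomial center C from the Gaussian center Q.
    q : batched Gaussian exponent.

    Returns
    -------
    array ``(tmax + 1,) + batch`` of coefficients c_t.
    """
    q = np.asarray(q, dtype=float)
    batch = q.shape
    tmax = sum(p for p, _ in factors)
    c = np.zeros((tmax + 1,) + batch)
    c[0] = 1.0
    inv2q = 1.0 / (2.0 * q)
    top = 0
    for power, d in factors:
        d = np.asarray(d, dtype=float)
        for _ in range(power):
            new = np.zeros_like(c)
            new[1 : top + 2] += c[: top + 1] * inv2q
            for t in range(top + 1):
                new[t] += d * c[t]
                if t >= 1:
                    new[t - 1] += t * c[t]
            c = new
            top += 1
    return c


def hermite_R(tmax: tuple[int, int, int], q, PC):
    """Hermite Coulomb tensor R_tuv(q, PC) (the n = 0 slice).

    ``PC`` has shape ``batch + (3,)``; returns shape
    ``(tx+1, ty+1, tz+1) + batch``.
    """
    q = np.asarray(q, dtype=float)
    PC = np.asarray(PC, dtype=float)
    tx, ty, tz = tmax
    N = tx + ty + tz
    batch = q.shape
    T = q * (PC ** 2).sum(axis=-1)
    F = boys(N, T)  # (N+1,) + batch
    # Rn[n, t, u, v]
    Rn = np.zeros((N + 1, tx + 1, ty + 1, tz + 1) + batch)
    m2q = -2.0 * q
    pw = np.ones(batch)
    for n in range(N + 1):
        Rn[n, 0, 0, 0] = pw * F[n]
        pw = pw * m2q
    X, Y, Z = PC[..., 0], PC[..., 1], PC[..., 2]
    for t in range(1, tx + 1):
        for n in range(N - t + 1):
            val = X * Rn[n + 1, t - 1, 0, 0]
            if t >= 2:
                val += (t - 1) * Rn[n + 1, t - 2, 0, 0]
            Rn[n, t, 0, 0] = val
    for u in range(1, ty + 1):
        for t in range(tx + 1):
            for n in range(N - t - u + 1):
                val = Y * Rn[n + 1, t, u - 1, 0]
                if u >= 2:
                    val += (u - 1) * Rn[n + 1, t, u - 2, 0]
                Rn[n, t, u, 0] = val
    for v in range(1, tz + 1):
        for u in range(ty + 1):
            for t in range(tx + 1):
                if t + u + v > N:
                    continue
                for n in range(N - t - u - v + 1):
                    val = Z * Rn[n + 1, t, u, v - 1]
                    if v >= 2:
                        val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    return Rn[0]


class PairBatch:
    """Primitive-pair data for one shell pair, flattened over primitives."""

    def __init__(self, sh_i, sh_j):
        self.sh_i, self.sh_j = sh_i, sh_j
        a = np.repeat(sh_i.exps, len(sh_j.exps))
        b = np.tile(sh_j.exps, len(sh_i.exps))
        ca = np.repeat(sh_i.coefs, len(sh_j.coefs))
        cb = np.tile(sh_j.coefs, len(sh_i.coefs))
        self.a, self.b = a, b
        self.cc = ca * cb
        self.A, self.B = sh_i.center, sh_j.center
        self.p = a + b
        self.P = (a[:, None] * self.A + b[:, None] * self.B) / self.p[:, None]
        AB2 = float(((self.A - self.B) ** 2).sum())
        self.prefE = np.exp(-a * b / self.p * AB2)

    def with_damping_gaussian(self, k: float, R: np.ndarray):
        """Combine the pair Gaussian with an extra s-Gaussian exp(-k|r-R|^2).

        Returns ``(q, Q, pref)`` of the merged Gaussian, with ``pref``
        including the pair prefactor.
        """
        if k == 0.0:
            return self.p, self.P, self.prefE.copy()
        q = self.p + k
        Q = (self.p[:, None] * self.P + k * R[None, :]) / q[:, None]
        PR2 = ((self.P - R[None, :]) ** 2).sum(axis=1)
        pref = self.prefE * np.exp(-self.p * k / q * PR2)
        return q, Q, pref

    def coeffs(self, pa, pb, q=None, Q=None):
        """Per-dimension Hermite coefficient arrays for AO powers pa, pb.

        ``q, Q`` default to the plain pair Gaussian; pass merged values to
        include a damping Gaussian.
        """
        if q is None:
            q, Q = self.p, self.P
        out = []
        for d in range(3):
            factors = [(pa[d], Q[:, d] - self.A[d]), (pb[d], Q[:, d] - self.B[d])]
            out.append(hermite_coeffs_1d(factors, q))
        return out
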