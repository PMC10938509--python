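"""Boys function F_n(T) = int_0^1 t^(2n) exp(-T t^2) dt, vectorized over T."""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln


def boys(nmax: int, T: np.ndarray) -> np.ndarray:
    """All Boys functions F_0..F_nmax.

    Parameters
    ----------
    nmax : highest order required.
    T : array of non-negative arguments, any shape.

    Returns
    -------
    array of shape ``(nmax + 1,) + T.shape``.
    """
    T = np.asarray(T, dtype=float)
    out = np.empty((nmax + 1,) + T.shape)
    small = T < 1e-13
    Ts = np.where(small, 1.0, T)  # placeholder to avoid 0^negative
    for n in range(nmax + 1):
        a = n + 0.5
        # F_n(T) = gamma(a) P(a, T) / (2 T^a), with P the regularized lower
        # incomplete gamma function.
        val = np.exp(gammaln(a)) * gammainc(a, Ts) / (2.0 * Ts ** a)
        out[n] = np.where(small, 1.0 / (2 * n + 1) - T / (2 * n + 3), val)
    return out
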