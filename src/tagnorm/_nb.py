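"""Negative-binomial log-pmf and 1-D likelihood maximization helpers.

The NB parameterization used throughout is (mean, dispersion): a count Y
with mean m and dispersion phi has variance m + phi*m**2; phi = 0 is the
Poisson limit.  Equivalently size r = 1/phi and success probability
r/(r+m).  Counts may be fractional (equalized pseudo-counts); the gamma
function replaces factorials.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

PHI_MIN = 1e-6
PHI_MAX = 10.0
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden ratio conjugate


def nb_logpmf(y, mean, phi):
    """Log pmf of NB(mean, dispersion); Poisson where phi == 0.

    Broadcasts over all arguments.  mean == 0 gives log 1 at y == 0 and
    -inf otherwise.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    phi = np.asarray(phi, dtype=float)
    y, mean, phi = np.broadcast_arrays(y, mean, phi)
    out = np.full(y.shape, -np.inf)
    zero_m = mean <= 0
    out[zero_m & (y == 0)] = 0.0
    pois = (~zero_m) & (phi <= 0)
    if np.any(pois):
        m = mean[pois]
        out[pois] = -m + y[pois] * np.log(m) - gammaln(y[pois] + 1.0)
    nb = (~zero_m) & (phi > 0)
    if np.any(nb):
        r = 1.0 / phi[nb]
        m = mean[nb]
        yy = y[nb]
        out[nb] = (gammaln(yy + r) - gammaln(r) - gammaln(yy + 1.0)
                   + r * np.log(r / (r + m)) + yy * np.log(m / (r + m)))
    return out if out.shape else float(out)


def golden_max(f, lo: float, hi: float, tol: float = 1e-4, vec_shape=None):
    """Golden-section maximization of ``f`` on [lo, hi].

    When ``vec_shape`` is None, ``f`` is scalar-to-scalar.  Otherwise ``f``
    maps an array of shape ``vec_shape`` (one abscissa per element) to
    objectives of the same shape and each element is maximized independently
    over its own bracket.  Returns the bracket midpoint at convergence.
    """
    if vec_shape is None:
        a, b = float(lo), float(hi)
    else:
        a = np.full(vec_shape, float(lo))
        b = np.full(vec_shape, float(hi))
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    n_iter = max(int(np.ceil(np.log(tol / (hi - lo)) / np.log(_INVPHI))) + 1, 1)
    for _ in range(n_iter):
        if vec_shape is None:
            if fc >= fd:
                b, fd_keep = d, fc
                c_new = b - _INVPHI * (b - a)
                d = c
                fd = fd_keep
                c = c_new
                fc = f(c)
            else:
                a, fc_keep = c, fd
                d_new = a + _INVPHI * (b - a)
                c = d
                fc = fc_keep
                d = d_new
                fd = f(d)
        else:
            left = fc >= fd
            a = np.where(left, a, c)
            b = np.where(left, d, b)
            c = b - _INVPHI * (b - a)
            d = a + _INVPHI * (b - a)
            # if left: the reused interior point is the old c (now d), so
            # evaluate the new c; if right: reused point is old d (now c).
            x = np.where(left, c, d)
            fx = f(x)
            fc, fd = np.where(left, fx, fd), np.where(left, fc, fx)
    return 0.5 * (a + b)
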