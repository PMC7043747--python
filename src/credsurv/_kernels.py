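"""Numba kernels for the sampler and RMST hot loops.

These mirror the public numpy implementations (``grouped_log_likelihood`` and
the segmentwise RMST integration in :mod:`credsurv.pte`) exactly; tests assert
agreement between the two routes.  The kernels exist purely so that a full
simulation study (thousands of fits) runs in minutes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CLIP = 50.0


@njit(cache=True)
def clipped_exp(lp: np.ndarray, out: np.ndarray) -> int:
    """out = exp(clip(lp, -50, 50)); returns the number of clipped entries."""
    n_clipped = 0
    for i in range(lp.size):
        v = lp[i]
        if v > _CLIP:
            v = _CLIP
            n_clipped += 1
        elif v < -_CLIP:
            v = -_CLIP
            n_clipped += 1
        out[i] = np.exp(v)
    return n_clipped


@njit(cache=True)
def grouped_loglik(
    elp: np.ndarray,
    rows: np.ndarray,
    exit_idx: np.ndarray,
    is_event: np.ndarray,
    h: np.ndarray,
) -> float:
    """Grouped-data log likelihood for one stratum.

    Subject i (at risk through its exit interval j_i) contributes
    ``-e_i * (H(s_{j_i}) - [event] h_{j_i})`` to the survival factor and, if an
    event, ``log(1 - exp(-h_{j_i} e_i))`` to the failure factor.
    """
    J = h.size
    Hc = np.empty(J)
    acc = 0.0
    for j in range(J):
        acc += h[j]
        Hc[j] = acc
    ll = 0.0
    for i in range(rows.size):
        e = elp[rows[i]]
        j = exit_idx[i]
        if is_event[i]:
            ll -= e * (Hc[j] - h[j])
            u = h[j] * e
            if u <= 0.0:
                return -np.inf
            if u < 1e-8:
                ll += np.log(u)
            else:
                ll += np.log(-np.expm1(-u))
        else:
            ll -= e * Hc[j]
    return ll


@njit(cache=True)
def rmst_segments(
    h: np.ndarray,       # (M, J) increments
    edges: np.ndarray,   # (J+1,) interval edges starting at 0
    lo: np.ndarray,      # (J,) segment starts clipped to the window
    dt: np.ndarray,      # (J,) segment lengths inside the window
    E: np.ndarray,       # (M, G) hazard multipliers exp(linear predictor)
    out: np.ndarray,     # (M, G)
) -> None:
    """Exact RMST of piecewise-exponential curves, per draw and grid point."""
    M, J = h.shape
    G = E.shape[1]
    lam = np.empty(J)
    Hlo = np.empty(J)
    for m in range(M):
        Hc = 0.0
        for j in range(J):
            lam[j] = h[m, j] / (edges[j + 1] - edges[j])
            off = lo[j] - edges[j]
            if off < 0.0:
                off = 0.0
            Hlo[j] = Hc + lam[j] * off
            Hc += h[m, j]
        for g in range(G):
            e = E[m, g]
            s = 0.0
            for j in range(J):
                d = dt[j]
                if d <= 0.0:
                    continue
                a = e * Hlo[j]
                if a > 45.0:
                    break  # survival already ~0; later segments add < 1e-18
                x = e * lam[j]
                xd = x * d
                if xd > 1e-12:
                    s += np.exp(-a) * (-np.expm1(-xd)) / x
                else:
                    s += np.exp(-a) * d
            out[m, g] = s
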