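"""Optional numba-compiled kernels for the semi-discrete transport operator.

The vectorised numpy implementations in :mod:`foulsim.transport` are the
reference; these loop kernels compute exactly the same right-hand side and
banded Jacobian and are used automatically when numba is importable (a
test asserts their equivalence).  State layout and band storage are
documented in :mod:`foulsim.transport`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap(args[0]) if args and callable(args[0]) else wrap


# species indices in the canonical order (Na, K, H, Cl, OH, Cas, HCas0)
_IH, _IOH, _ICAS, _IH0 = 2, 4, 5, 6


@njit(cache=True)
def rhs_kernel(y, i_cur, N, inv_dx, D, z2D, zD, A, F,
               RT_over_F, k1, km1, kr, kd, a, b, c0dep, tH):
    dy = np.empty_like(y)
    alpha = y[0]
    j = np.empty((N - 1, 7))
    for f in range(N - 1):
        base = 1 + 7 * f
        S = 0.0
        G = i_cur / F
        for s in range(7):
            cl = y[base + s]
            cr = y[base + 7 + s]
            S += z2D[s] * 0.5 * (cl + cr)
            G += zD[s] * (cr - cl) * inv_dx
        dphi = -RT_over_F * G / S
        for s in range(7):
            cl = y[base + s]
            cr = y[base + 7 + s]
            j[f, s] = -D[s] * (cr - cl) * inv_dx - A[s] * 0.5 * (cl + cr) * dphi

    # interior nodes: flux divergence
    for k in range(1, N - 1):
        base = 1 + 7 * k
        for s in range(7):
            dy[base + s] = (j[k - 1, s] - j[k, s]) * inv_dx
    # surface node (half cell) with boundary fluxes
    two_inv = 2.0 * inv_dx
    surf_h0 = a * alpha * c0dep - b * y[1 + _IH0]
    for s in range(7):
        dy[1 + s] = -j[0, s] * two_inv
    dy[1 + _IH] += (i_cur * tH / F) * two_inv
    dy[1 + _IH0] += surf_h0 * two_inv
    # reactions on nodes 0..N-2
    for k in range(N - 1):
        base = 1 + 7 * k
        cH = y[base + _IH]
        r1 = -k1 * y[base + _IH0] + km1 * cH * y[base + _ICAS]
        r2 = kr * cH * y[base + _IOH] - kd
        dy[base + _IH] += -r1 - r2
        dy[base + _IOH] += -r2
        dy[base + _ICAS] += -r1
        dy[base + _IH0] += r1
    # Dirichlet bulk node
    for s in range(7):
        dy[1 + 7 * (N - 1) + s] = 0.0
    dy[0] = -a * alpha + b * y[1 + _IH0] / c0dep
    dy[-1] = j[N - 2, _ICAS] + j[N - 2, _IH0]
    return dy


@njit(cache=True)
def jac_kernel(y, i_cur, N, inv_dx, D, z2D, zD, A, F,
               RT_over_F, k1, km1, kr, kd, a, b, c0dep, tH):
    mu = 14
    n = 7 * N + 2
    band = np.zeros((2 * mu + 1, n))

    djL = np.empty((N - 1, 7, 7))
    djR = np.empty((N - 1, 7, 7))
    for f in range(N - 1):
        base = 1 + 7 * f
        S = 0.0
        G = i_cur / F
        for s in range(7):
            cl = y[base + s]
            cr = y[base + 7 + s]
            S += z2D[s] * 0.5 * (cl + cr)
            G += zD[s] * (cr - cl) * inv_dx
        dphi = -RT_over_F * G / S
        invS = 1.0 / S
        for sp in range(7):
            h = -dphi * 0.5 * z2D[sp] * invS
            dphiL = RT_over_F * zD[sp] * inv_dx * invS + h
            dphiR = -RT_over_F * zD[sp] * inv_dx * invS + h
            for s in range(7):
                cf = 0.5 * (y[base + s] + y[base + 7 + s])
                diag = D[s] * inv_dx if s == sp else 0.0
                mig = 0.5 * A[s] * dphi if s == sp else 0.0
                djL[f, s, sp] = diag - mig - A[s] * cf * dphiL
                djR[f, s, sp] = -diag - mig - A[s] * cf * dphiR

    # concentration rows
    for k in range(N - 1):
        ib = 1 + 7 * k
        # reaction Jacobian of node k
        cH = y[ib + _IH]
        dr1_H = km1 * y[ib + _ICAS]
        dr1_C = km1 * cH
        dr1_h = -k1
        dr2_H = kr * y[ib + _IOH]
        dr2_O = kr * cH
        vol = 2.0 * inv_dx if k == 0 else inv_dx
        for s in range(7):
            i = ib + s
            for sp in range(7):
                # same-node transport block
                v = -djL[k, s, sp] * vol
                if k > 0:
                    v += djR[k - 1, s, sp] * inv_dx
                band[mu + s - sp, ib + sp] += v
                # right neighbour
                band[mu + s - sp - 7, ib + 7 + sp] += -djR[k, s, sp] * vol
                # left neighbour
                if k > 0:
                    band[mu + s - sp + 7, ib - 7 + sp] += djL[k - 1, s, sp] * inv_dx
        # reaction terms (same-node)
        band[mu + _IH - _IH, ib + _IH] += -dr1_H - dr2_H
        band[mu + _IH - _ICAS, ib + _ICAS] += -dr1_C
        band[mu + _IH - _IH0, ib + _IH0] += -dr1_h
        band[mu + _IH - _IOH, ib + _IOH] += -dr2_O
        band[mu + _IOH - _IH, ib + _IH] += -dr2_H
        band[mu, ib + _IOH] += -dr2_O
        band[mu + _ICAS - _IH, ib + _IH] += -dr1_H
        band[mu, ib + _ICAS] += -dr1_C
        band[mu + _ICAS - _IH0, ib + _IH0] += -dr1_h
        band[mu + _IH0 - _IH, ib + _IH] += dr1_H
        band[mu + _IH0 - _ICAS, ib + _ICAS] += dr1_C
        band[mu, ib + _IH0] += dr1_h
    # surface-exchange extras on node 0
    band[mu, 1 + _IH0] += -b * 2.0 * inv_dx        # d f_{0,H0} / d c_{0,H0}
    band[mu + 1 + _IH0, 0] = a * c0dep * 2.0 * inv_dx   # d f_{0,H0} / d alpha
    # alpha row
    band[mu, 0] = -a
    band[mu - 1 - _IH0, 1 + _IH0] = b / c0dep
    # cumulative outflow row
    iJ = n - 1
    for sp in range(7):
        jL = 1 + 7 * (N - 2) + sp
        jR = 1 + 7 * (N - 1) + sp
        band[mu + iJ - jL, jL] = djL[N - 2, _ICAS, sp] + djL[N - 2, _IH0, sp]
        band[mu + iJ - jR, jR] = djR[N - 2, _ICAS, sp] + djR[N - 2, _IH0, sp]
    return band
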