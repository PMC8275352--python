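"""Numba kernels for the binding-configuration dynamic program.

Arrays are padded by k ghost cells on the left so the recursions can read
the empty-prefix boundary values (ZA = 0, ZB = 1) without branching:
padded index t corresponds to sequence position i = t - k.

Statistical weights are clipped at ``_CAP`` (overflow guard); the forward
kernel reports whether the cap was hit so callers can warn.  The clip is
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CAP = 1e280


@njit(cache=True)
def dp_forward(wA, wB, cB, k):  # pragma: no cover - exercised via thermo
    """Forward recursions.

    wA[i], wB[i]: Boltzmann factors e^{-E(window ending at i)} (0 for i<k-1
    or ambiguous windows).  cB[d]: effective concentration at spacer d.
    Returns (ZA_pad, ZB_pad, Z, capped).
    """
    L = wA.shape[0]
    ZA = np.zeros(L + k)
    ZB = np.ones(L + k)
    capped = False
    for i in range(k - 1, L):
        t = i + k
        sa = 0.0  # sum of ZA(j) for j <= i-k
        pb = 0.0  # sum of ZA(j) * cB(i-k-j)
        for j in range(0, i - k + 1):
            zaj = ZA[j + k]
            sa += zaj
            pb += zaj * cB[i - k - j]
        za = (ZB[i] + sa) * wA[i]
        zb = ZB[t - 1] + wB[i] * (pb + ZB[i])
        if za > _CAP:
            za = _CAP
            capped = True
        if zb > _CAP:
            zb = _CAP
            capped = True
        ZA[t] = za
        ZB[t] = zb
    z = ZB[L - 1 + k]
    for j in range(L):
        z += ZA[j + k]
    return ZA, ZB, z, capped


@njit(cache=True)
def dp_backward(wA, wB, cB, k, ZA, ZB, g):  # pragma: no cover
    """Adjoint (reverse-mode) sweep of :func:`dp_forward`.

    ``g`` is dF/dZ of the outer objective.  Returns (awA, awB, acB):
    dF/dwA[i], dF/dwB[i] and dF/dcB[d].
    """
    L = wA.shape[0]
    aZA = np.zeros(L + k)
    aZB = np.zeros(L + k)
    awA = np.zeros(L)
    awB = np.zeros(L)
    acB = np.zeros(L + 1)
    # Z = ZB[L-1+k] + sum_j ZA[j+k]
    aZB[L - 1 + k] += g
    for j in range(L):
        aZA[j + k] += g
    for i in range(L - 1, k - 2, -1):
        t = i + k
        # ZB[t] = ZB[t-1] + wB[i] * (pb + ZB[i])
        a = aZB[t]
        if a != 0.0:
            aZB[t - 1] += a
            pb = 0.0
            for j in range(0, i - k + 1):
                pb += ZA[j + k] * cB[i - k - j]
            awB[i] += a * (pb + ZB[i])
            aZB[i] += a * wB[i]
            awb = a * wB[i]
            if awb != 0.0:
                for j in range(0, i - k + 1):
                    aZA[j + k] += awb * cB[i - k - j]
                    acB[i - k - j] += awb * ZA[j + k]
        # ZA[t] = (ZB[i] + sa) * wA[i]
        b = aZA[t]
        if b != 0.0:
            sa = 0.0
            for j in range(0, i - k + 1):
                sa += ZA[j + k]
            awA[i] += b * (ZB[i] + sa)
            aZB[i] += b * wA[i]
            bwa = b * wA[i]
            if bwa != 0.0:
                for j in range(0, i - k + 1):
                    aZA[j + k] += bwa
    return awA, awB, acB
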