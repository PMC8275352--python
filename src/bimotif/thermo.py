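"""Partition sums over binding configurations of a two-domain protein.

A configuration is an ordered set of non-overlapping k-length placements on
the RNA, each by domain A or B.  Scanning left to right, an A placement at
free-protein concentration c_AB = 1 has statistical weight e^{-E_A(kmer)};
a B placement immediately preceded by an A is tethered to it and sees the
effective concentration c_B(d) (d = nucleotides strictly between the two
cores), weight c_B(d) * e^{-E_B(kmer)}; any other B placement is a free
protein, weight e^{-E_B(kmer)}.  The empty configuration has weight 1, so
Z(x) >= 1 and p(bound|x) = 1 - 1/Z(x).

``forward_partition`` evaluates Z by dynamic programming in O(L^2);
``enumerate_partition`` evaluates the same sum by exhaustive recursion over
configurations and serves as an independent oracle on short sequences.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import digamma, gammaln

from ._kernels import dp_backward, dp_forward
from .model import BmfModel, DpResult, SpacerParams
from .sequences import encode_windows, normalize_sequence

__all__ = [
    "effective_concentration",
    "nb_pmf",
    "forward_partition",
    "binding_probability",
    "enumerate_partition",
]

ENUMERATION_LIMIT = 16


def nb_pmf(d, r: float, p: float) -> np.ndarray:
    """Negative binomial pmf NB(d; r, p) = C(d+r-1, d) p^r (1-p)^d.

    Real-valued r is handled through the log-gamma generalization of the
    binomial coefficient.
    """
    d = np.asarray(d, dtype=np.float64)
    logpmf = (
        gammaln(d + r)
        - gammaln(d + 1.0)
        - gammaln(r)
        + r * np.log(p)
        + d * np.log1p(-p)
    )
    return np.exp(logpmf)


def nb_pmf_param_grad(d, r: float, p: float) -> tuple[np.ndarray, np.ndarray]:
    """(d NB/d r, d NB/d p) at integer spacers ``d``."""
    d = np.asarray(d, dtype=np.float64)
    pmf = nb_pmf(d, r, p)
    dr = pmf * (digamma(d + r) - digamma(r) + np.log(p))
    dp = pmf * (r / p - d / (1.0 - p))
    return dr, dp


def effective_concentration(d, spacer: SpacerParams):
    """c_B(d) = c_AB + S * NB(d; r, p) for spacer length d >= 0."""
    d_arr = np.asarray(d)
    if np.any(d_arr < 0):
        raise ValueError("spacer length d must be >= 0")
    S = spacer.scale
    if S == 0.0:
        out = np.full(d_arr.shape, SpacerParams.CAB)
    else:
        out = SpacerParams.CAB + S * nb_pmf(d_arr, spacer.r, spacer.p)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def concentration_profile(model: BmfModel, max_d: int) -> np.ndarray:
    """c_B(d) for d = 0..max_d as an array (DP lookup table)."""
    if max_d < 0:
        return np.empty(0)
    return np.atleast_1d(
        effective_concentration(np.arange(max_d + 1), model.spacer)
    ).astype(np.float64)


def position_weights(seq: str, model: BmfModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position Boltzmann factors (wA, wB) and window k-mer indices.

    wA[i] = e^{-E_A(window ending at i)}; zero for i < k-1 and for windows
    containing an ambiguous base (infinite-energy convention).
    """
    k = model.k
    L = len(seq)
    idx = encode_windows(seq, k)
    wA = np.zeros(L)
    wB = np.zeros(L)
    if idx.size:
        valid = idx >= 0
        ends = np.arange(k - 1, L)
        wA[ends[valid]] = np.exp(-model.core_a.energies[idx[valid]])
        wB[ends[valid]] = np.exp(-model.core_b.energies[idx[valid]])
    return wA, wB, idx


def forward_partition(seq: str, model: BmfModel) -> DpResult:
    """Partition sum Z(seq) and the per-position sums ZA, ZB by DP."""
    seq = normalize_sequence(seq)
    k = model.k
    L = len(seq)
    if L == 0:
        return DpResult(Z=1.0, ZA=np.empty(0), ZB=np.empty(0))
    wA, wB, _ = position_weights(seq, model)
    cB = concentration_profile(model, L)
    ZApad, ZBpad, z, capped = dp_forward(wA, wB, cB, k)
    if capped:
        warnings.warn(
            "statistical-weight cap hit during the partition-sum recursion; "
            "Z is a clipped lower bound",
            RuntimeWarning,
            stacklevel=2,
        )
    return DpResult(Z=float(z), ZA=ZApad[k:], ZB=ZBpad[k:], capped=bool(capped))


def binding_probability(seq: str, model: BmfModel) -> float:
    """p(bound | seq) = 1 - 1/Z(seq), in [0, 1)."""
    return 1.0 - 1.0 / forward_partition(seq, model).Z


def enumerate_partition(seq: str, model: BmfModel, limit: int = ENUMERATION_LIMIT) -> float:
    """Z(seq) by brute-force enumeration of every binding configuration.

    Exponential in L; refuses sequences longer than ``limit``.  Kept free of
    the ZA/ZB recursions so it can serve as an independent check of
    :func:`forward_partition`.
    """
    seq = normalize_sequence(seq)
    L = len(seq)
    if L > limit:
        raise ValueError(
            f"sequence of length {L} exceeds the enumeration limit of {limit}"
        )
    k = model.k
    idx = encode_windows(seq, k)  # index of window starting at s is idx[s]
    eA = model.core_a.energies
    eB = model.core_b.energies

    def weight_a(start: int) -> float:
        m = idx[start]
        return 0.0 if m < 0 else SpacerParams.CAB * float(np.exp(-eA[m]))

    def weight_b(start: int, prev_label: str | None, prev_end: int) -> float:
        m = idx[start]
        if m < 0:
            return 0.0
        boltz = float(np.exp(-eB[m]))
        if prev_label == "A":
            d = start - prev_end - 1
            return float(effective_concentration(d, model.spacer)) * boltz
        return SpacerParams.CAB * boltz

    def extend(start: int, prev_label: str | None, prev_end: int) -> float:
        # Sum of weights of all configuration suffixes placed at >= start.
        total = 1.0  # place nothing more
        for s in range(start, L - k + 1):
            wa = weight_a(s)
            if wa != 0.0:
                total += wa * extend(s + k, "A", s + k - 1)
            wb = weight_b(s, prev_label, prev_end)
            if wb != 0.0:
                total += wb * extend(s + k, "B", s + k - 1)
        return total

    # The "immediately preceding placement" for a B is simply the last one
    # placed, whatever the gap, so prev_label/prev_end thread through as-is.
    return extend(0, None, -1)
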