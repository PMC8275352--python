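"""Enrichment likelihood for selection experiments and its analytic gradient.

The generative story for one round of selection (SELEX-style): a read x
appears in the enriched set if it was present in the input library
(empirical fraction p_bg(x)) and was then bound, with p(bound|x) =
1 - 1/Z(x).  By Bayes,

    p(x | bound) = p(bound|x) p_bg(x) / sum_x' p(bound|x') p_bg(x'),

and the log-likelihood of the enriched set X+ is

    LL = sum_{x in X+} [ ln p_bg(x) + ln(1 - 1/Z(x)) ]
         - N+ * ln sum_{x' in Xbg} p_bg(x') (1 - 1/Z(x')).

The ln p_bg(x) term is constant in the model parameters; gradients are
unaffected by it, and :func:`log_likelihood` can drop it (training does,
since enriched reads need not occur in the background library).

Gradients are obtained by one adjoint sweep of the partition-sum dynamic
program per sequence — every energy entry and the three spacer parameters
in a single backward pass — rather than by numerical differentiation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._kernels import dp_backward, dp_forward
from .model import BmfModel
from .sequences import normalize_sequence
from .thermo import concentration_profile, nb_pmf, nb_pmf_param_grad, position_weights

__all__ = [
    "Dataset",
    "background_weights",
    "collapse_duplicates",
    "empirical_fractions",
    "log_likelihood",
    "model_gradient",
]


def background_weights(background: list[str]) -> np.ndarray:
    """Per-read background weights p_bg: each of the M reads carries 1/M.

    Duplicate reads may equivalently be collapsed to one entry carrying
    multiplicity/M (:func:`collapse_duplicates`); both give identical
    likelihoods.
    """
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    return np.full(len(background), 1.0 / len(background))


def collapse_duplicates(background: list[str]) -> tuple[list[str], np.ndarray]:
    """Unique background reads with weights multiplicity / total."""
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    counts = Counter(background)
    seqs = list(counts)
    w = np.array([counts[s] for s in seqs], dtype=np.float64)
    return seqs, w / w.sum()


def empirical_fractions(background: list[str]) -> dict[str, float]:
    """Map read -> fraction of the background library it makes up."""
    counts = Counter(background)
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}


@dataclass
class Dataset:
    """Enriched set X+ and background (input-library) set Xbg with per-read
    background weights summing to 1."""

    enriched: list[str]
    background: list[str]
    background_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.enriched) == 0:
            raise ValueError("enriched set must be non-empty")
        if len(self.background) == 0:
            raise ValueError("background set must be non-empty")
        self.enriched = [normalize_sequence(s) for s in self.enriched]
        self.background = [normalize_sequence(s) for s in self.background]
        if self.background_weights is None:
            self.background_weights = background_weights(self.background)
        self.background_weights = np.asarray(self.background_weights, dtype=np.float64)
        if self.background_weights.shape != (len(self.background),):
            raise ValueError("background_weights must align with the background set")
        if np.any(self.background_weights <= 0):
            raise ValueError("background weights must be positive")
        if abs(self.background_weights.sum() - 1.0) > 1e-12:
            raise ValueError("background weights must sum to 1")

    @property
    def n_enriched(self) -> int:
        return len(self.enriched)


def _forward_all(seqs: list[str], model: BmfModel, cB: np.ndarray):
    """Forward DP over a list of sequences; returns per-sequence
    (wA, wB, idx, ZApad, ZBpad, Z)."""
    out = []
    k = model.k
    for seq in seqs:
        if len(seq) == 0:
            out.append(None)
            continue
        wA, wB, idx = position_weights(seq, model)
        ZApad, ZBpad, z, _ = dp_forward(wA, wB, cB[: len(seq)], k)
        out.append((wA, wB, idx, ZApad, ZBpad, z))
    return out


def _partition_values(seqs: list[str], model: BmfModel, cB: np.ndarray) -> np.ndarray:
    zs = np.empty(len(seqs))
    for i, rec in enumerate(_forward_all(seqs, model, cB)):
        zs[i] = 1.0 if rec is None else rec[5]
    return zs


def log_likelihood(
    dataset: Dataset,
    model: BmfModel,
    include_background_fraction: bool = True,
) -> float:
    """Log-likelihood of the enriched set given the model.

    ``include_background_fraction`` controls the parameter-independent
    sum of ln p_bg(x) over enriched reads (their empirical fraction in the
    background library).  Training drops it; with it included, an enriched
    read absent from the background contributes -inf.
    """
    max_len = max(len(s) for s in dataset.enriched + dataset.background)
    cB = concentration_profile(model, max_len)
    z_plus = _partition_values(dataset.enriched, model, cB)
    if np.any(z_plus <= 1.0):
        bad = int(np.argmax(z_plus <= 1.0))
        raise ValueError(
            f"enriched sequence #{bad} ({dataset.enriched[bad]!r}) has Z = 1 "
            "(no window with positive binding weight); the log-likelihood "
            "is -inf"
        )
    z_bg = _partition_values(dataset.background, model, cB)
    ll = float(np.sum(np.log1p(-1.0 / z_plus)))
    denom = float(np.sum(dataset.background_weights * (1.0 - 1.0 / z_bg)))
    ll -= dataset.n_enriched * np.log(denom)
    if include_background_fraction:
        frac = empirical_fractions(dataset.background)
        ll += float(
            np.sum([np.log(frac.get(x, 0.0)) for x in dataset.enriched])
        )
    return ll


def model_gradient(dataset: Dataset, model: BmfModel) -> np.ndarray:
    """d LL / d theta over [E_A, E_B, rho, pi, scale_param].

    The constant ln p_bg term plays no role.  Deterministic for a fixed
    dataset; computed via the adjoint recursions of the forward DP.
    """
    k = model.k
    n = 4**k
    max_len = max(len(s) for s in dataset.enriched + dataset.background)
    cB = concentration_profile(model, max_len)

    fwd_plus = _forward_all(dataset.enriched, model, cB)
    fwd_bg = _forward_all(dataset.background, model, cB)

    z_plus = np.array([1.0 if r is None else r[5] for r in fwd_plus])
    if np.any(z_plus <= 1.0):
        bad = int(np.argmax(z_plus <= 1.0))
        raise ValueError(
            f"enriched sequence #{bad} has Z = 1; the likelihood gradient "
            "is undefined (-inf objective)"
        )
    z_bg = np.array([1.0 if r is None else r[5] for r in fwd_bg])
    denom = float(np.sum(dataset.background_weights * (1.0 - 1.0 / z_bg)))

    # dLL/dZ for each sequence.
    g_plus = 1.0 / (z_plus * z_plus - z_plus)
    g_bg = -dataset.n_enriched * dataset.background_weights / (z_bg * z_bg) / denom

    grad = np.zeros(2 * n + 3)
    acB_total = np.zeros(max_len + 1)

    def accumulate(seq: str, rec, g: float) -> None:
        if rec is None or g == 0.0:
            return
        wA, wB, idx, ZApad, ZBpad, _ = rec
        awA, awB, acB = dp_backward(wA, wB, cB[: len(seq)], k, ZApad, ZBpad, g)
        ends = np.arange(k - 1, len(seq))
        valid = idx >= 0
        # dw/dE = -w
        np.add.at(grad[:n], idx[valid], -awA[ends[valid]] * wA[ends[valid]])
        np.add.at(grad[n : 2 * n], idx[valid], -awB[ends[valid]] * wB[ends[valid]])
        acB_total[: acB.shape[0]] += acB

    for seq, rec, g in zip(dataset.enriched, fwd_plus, g_plus):
        accumulate(seq, rec, float(g))
    for seq, rec, g in zip(dataset.background, fwd_bg, g_bg):
        accumulate(seq, rec, float(g))

    # Chain rule through c_B(d) = 1 + S * NB(d; r, p) with r = e^rho,
    # p = sigmoid(pi), S = e^scale_param.
    S = model.spacer.scale
    if S > 0.0:
        r, p = model.spacer.r, model.spacer.p
        d = np.arange(acB_total.shape[0])
        pmf = nb_pmf(d, r, p)
        dr, dp = nb_pmf_param_grad(d, r, p)
        grad[-3] = float(np.sum(acB_total * S * dr) * r)
        grad[-2] = float(np.sum(acB_total * S * dp) * p * (1.0 - p))
        grad[-1] = float(np.sum(acB_total * S * pmf))
    return grad
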