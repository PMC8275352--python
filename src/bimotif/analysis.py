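"""Post-hoc statistics of trained models.

Energies become motif probabilities through Boltzmann's law,
p(m) = e^{-E(m)} / sum_m' e^{-E(m')}.  On top of that this module computes
the learned spacer distribution and a bipartite/adjacent call, the Pearson
similarity of the two cores, the mean positional entropy (sequence
complexity, bits in [0, 2]) and a repetitiveness score (affinity mass
compatible with mono-/di-nucleotide repeats), plus randomized-model
baselines for the latter two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BmfModel, EnergyTable, SpacerParams
from .sequences import ALPHABET, all_kmers, index_to_kmer
from .thermo import nb_pmf

__all__ = [
    "MotifSummary",
    "boltzmann_probs",
    "top_kmers",
    "spacer_distribution",
    "classify_bipartite",
    "core_similarity",
    "motif_entropy",
    "repetitiveness",
    "random_model_baseline",
    "summarize_model",
    "summary_table",
    "render_motif_text",
]

DEFAULT_TAIL_MASS = 1e-6
_MIN_DMAX = 100


def boltzmann_probs(table: EnergyTable) -> np.ndarray:
    """k-mer probabilities p(m) ~ e^{-E(m)}, normalized to 1 (energies are
    shifted by their minimum before exponentiating for stability)."""
    e = table.energies
    w = np.exp(-(e - e.min()))
    return w / w.sum()


def top_kmers(table: EnergyTable, n: int = 5) -> list[tuple[str, float]]:
    """The n most probable k-mers with probabilities renormalized to sum to
    1 over the selection; ties broken lexicographically."""
    if not 1 <= n <= 4**table.k:
        raise ValueError(f"n must be in [1, {4 ** table.k}]")
    probs = boltzmann_probs(table)
    # sort by descending probability, then lexicographic k-mer index
    order = np.lexsort((np.arange(probs.size), -probs))[:n]
    sel = probs[order]
    sel = sel / sel.sum()
    return [(index_to_kmer(int(i), table.k), float(p)) for i, p in zip(order, sel)]


def default_d_max(spacer: SpacerParams, tail_mass: float = DEFAULT_TAIL_MASS) -> int:
    """Smallest d_max (floored at 100) whose NB tail mass is < tail_mass."""
    from scipy.stats import nbinom

    d = int(nbinom.isf(tail_mass, spacer.r, spacer.p))
    return max(_MIN_DMAX, d)


def spacer_distribution(
    spacer: SpacerParams, d_max: int | None = None
) -> tuple[np.ndarray, float]:
    """(pmf of the spacer length over 0..d_max, P(d > 0)).

    The pmf is the normalized NB component of the effective-concentration
    law; the constant free-protein term is a concentration, not a spacer
    length, and is excluded.  P(d>0) = 1 - p^r.
    """
    if d_max is None:
        d_max = default_d_max(spacer)
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    pmf = nb_pmf(np.arange(d_max + 1), spacer.r, spacer.p)
    p_gt0 = 1.0 - spacer.p**spacer.r
    return pmf, float(p_gt0)


def classify_bipartite(model: BmfModel, threshold: float = 0.5) -> str:
    """'bipartite' iff P(spacer > 0) exceeds ``threshold``, else 'adjacent'."""
    _, p_gt0 = spacer_distribution(model.spacer, d_max=0)
    return "bipartite" if p_gt0 > threshold else "adjacent"


def core_similarity(model: BmfModel) -> float:
    """Pearson correlation between the Boltzmann k-mer probabilities of the
    two cores; NaN when either vector is constant (zero variance)."""
    pa = boltzmann_probs(model.core_a)
    pb = boltzmann_probs(model.core_b)
    if np.ptp(pa) == 0.0 or np.ptp(pb) == 0.0:
        return float("nan")
    return float(np.corrcoef(pa, pb)[0, 1])


def _positional_marginals(table: EnergyTable) -> np.ndarray:
    """(k, 4) nucleotide distributions from marginalized k-mer probabilities."""
    k = table.k
    probs = boltzmann_probs(table).reshape((4,) * k)
    out = np.empty((k, 4))
    for pos in range(k):
        axes = tuple(a for a in range(k) if a != pos)
        out[pos] = probs.sum(axis=axes)
    return out


def motif_entropy(model: BmfModel) -> float:
    """Mean per-position Shannon entropy (bits) over the 2k core positions;
    2 for uniform motifs, 0 for a single deterministic k-mer per core."""
    ents = []
    for table in (model.core_a, model.core_b):
        for dist in _positional_marginals(table):
            nz = dist[dist > 0]
            ents.append(float(-(nz * np.log2(nz)).sum()))
    return float(np.mean(ents))


def _repeat_units() -> list[str]:
    mono = list(ALPHABET)
    di = [a + b for a in ALPHABET for b in ALPHABET if a != b]
    return mono + di


def _repeat_compatible_mask(unit: str, k: int) -> np.ndarray:
    """Boolean mask over 4^k k-mers that occur in the infinite repeat of
    ``unit``."""
    tiled = unit * (k // len(unit) + 2)
    members = {tiled[s : s + k] for s in range(len(unit))}
    kmers = all_kmers(k)
    return np.array([m in members for m in kmers])


def repetitiveness(model: BmfModel) -> float:
    """max over the 16 mono/di repeat units u of sqrt(q_A(u) * q_B(u)),
    where q(u) is the Boltzmann mass on k-mers compatible with u; in [0, 1],
    1 when both cores sit entirely on the same repeat."""
    k = model.k
    pa = boltzmann_probs(model.core_a)
    pb = boltzmann_probs(model.core_b)
    best = 0.0
    for unit in _repeat_units():
        mask = _repeat_compatible_mask(unit, k)
        score = float(np.sqrt(pa[mask].sum() * pb[mask].sum()))
        best = max(best, score)
    return best


def random_model_baseline(
    k: int, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Entropy and repetitiveness of ``n_samples`` randomly initialized
    models (the null against which trained models are compared)."""
    from .training import initialize_model

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sub_seeds = np.random.SeedSequence(seed).spawn(n_samples)
    ent = np.empty(n_samples)
    rep = np.empty(n_samples)
    for i, s in enumerate(sub_seeds):
        m = initialize_model(k, s)
        ent[i] = motif_entropy(m)
        rep[i] = repetitiveness(m)
    return ent, rep


@dataclass
class MotifSummary:
    """One model's headline statistics."""

    top_a: list[tuple[str, float]]
    top_b: list[tuple[str, float]]
    spacer_pmf: np.ndarray
    spacer_tail_mass: float
    p_spacer_gt0: float
    classification: str
    core_similarity: float
    entropy: float
    repetitiveness: float


def summarize_model(model: BmfModel, n_top: int = 5, d_max: int | None = None) -> MotifSummary:
    pmf, p_gt0 = spacer_distribution(model.spacer, d_max)
    return MotifSummary(
        top_a=top_kmers(model.core_a, n_top),
        top_b=top_kmers(model.core_b, n_top),
        spacer_pmf=pmf,
        spacer_tail_mass=float(max(0.0, 1.0 - pmf.sum())),
        p_spacer_gt0=p_gt0,
        classification=classify_bipartite(model),
        core_similarity=core_similarity(model),
        entropy=motif_entropy(model),
        repetitiveness=repetitiveness(model),
    )


def summary_table(summary: MotifSummary) -> pd.DataFrame:
    """Scalar statistics as a one-row table (TSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "p_spacer_gt0": summary.p_spacer_gt0,
                "classification": summary.classification,
                "core_similarity": summary.core_similarity,
                "entropy_bits": summary.entropy,
                "repetitiveness": summary.repetitiveness,
                "spacer_tail_mass": summary.spacer_tail_mass,
            }
        ]
    )


def render_motif_text(summary: MotifSummary, max_spacer_rows: int = 15) -> str:
    """Plain-text rendering: top-5 k-mers per core, spacer pmf head and
    scalar statistics."""
    lines = []
    for name, top in (("core A", summary.top_a), ("core B", summary.top_b)):
        lines.append(f"{name} (top {len(top)} k-mers, probabilities renormalized to 1):")
        for kmer, prob in top:
            bar = "#" * max(1, int(round(prob * 40)))
            lines.append(f"  {kmer}  {prob:6.3f}  {bar}")
    lines.append(f"P(spacer > 0) = {summary.p_spacer_gt0:.4f}  -> {summary.classification}")
    lines.append(f"core similarity (Pearson) = {summary.core_similarity:.4f}")
    lines.append(f"motif entropy = {summary.entropy:.4f} bits/position")
    lines.append(f"repetitiveness = {summary.repetitiveness:.4f}")
    lines.append("spacer length pmf:")
    for d, q in enumerate(summary.spacer_pmf[:max_spacer_rows]):
        bar = "#" * int(round(q * 40))
        lines.append(f"  d={d:<3d} {q:8.4f}  {bar}")
    if summary.spacer_pmf.size > max_spacer_rows:
        lines.append(
            f"  ... ({summary.spacer_pmf.size - max_spacer_rows} more rows, "
            f"tail mass {summary.spacer_tail_mass:.2e})"
        )
    return "\n".join(lines)
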