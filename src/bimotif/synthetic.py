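"""Synthetic benchmark: random background plus implanted bipartite motifs.

Emulates a one-round selection experiment on a random oligomer library:
a background set of i.i.d. random sequences, and an enriched set in which
every sequence carries core A, a stochastic linker gap, then core B, at a
uniformly random feasible position.  Defaults — 2000 sequences per set,
40-nt oligomers, cores AAA/CCC, negative-binomial linker NB(r=4, p=0.4)
(mode 4, mean 6) — define the standard benchmark the trainer is expected
to recover.

The linker law is negative binomial by default, matching the spacer model
being recovered; a plain binomial is available as an option.  Implantation
overwrites letters, so sequence lengths never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import Dataset
from .sequences import ALPHABET, normalize_sequence

__all__ = [
    "SyntheticConfig",
    "sample_background",
    "implant_motifs",
    "make_benchmark",
]

_MAX_GAP_RETRIES = 1000


@dataclass
class SyntheticConfig:
    """Benchmark parameters; defaults are the standard study conditions."""

    n_enriched: int = 2000
    n_background: int = 2000
    sequence_length: int = 40
    core_a: str = "AAA"
    core_b: str = "CCC"
    core_a_variants: list[str] | None = None  # sampled uniformly if given
    core_b_variants: list[str] | None = None
    linker_family: str = "nbinom"  # or "binomial"
    linker_r: float = 4.0
    linker_p: float = 0.4
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched < 1 or self.n_background < 1:
            raise ValueError("set sizes must be >= 1")
        self.core_a = normalize_sequence(self.core_a)
        self.core_b = normalize_sequence(self.core_b)
        for core in (self.core_a, self.core_b):
            if not core or any(c not in ALPHABET for c in core):
                raise ValueError(f"core {core!r} must be non-empty over ACGU")
        if self.linker_family not in ("nbinom", "binomial"):
            raise ValueError("linker_family must be 'nbinom' or 'binomial'")
        if len(self.core_a) + len(self.core_b) >= self.sequence_length:
            raise ValueError("cores do not fit in the sequence length")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load from a flat ``key = value`` text file ('#' comments allowed).

        Keys match the field names; ``composition`` is four comma-separated
        weights, ``core_a_variants``/``core_b_variants`` comma-separated
        lists.
        """
        kwargs: dict = {}
        casts = {
            "n_enriched": int, "n_background": int, "sequence_length": int,
            "core_a": str, "core_b": str, "linker_family": str,
            "linker_r": float, "linker_p": float, "rng_seed": int,
        }
        with open(path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key in casts:
                    kwargs[key] = casts[key](value)
                elif key == "composition":
                    kwargs[key] = tuple(float(v) for v in value.split(","))
                elif key in ("core_a_variants", "core_b_variants"):
                    kwargs[key] = [v.strip() for v in value.split(",")]
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)


def _validate_composition(composition) -> np.ndarray:
    comp = np.asarray(
        composition if composition is not None else [0.25] * 4, dtype=np.float64
    )
    if comp.shape != (4,) or np.any(comp < 0) or comp.sum() <= 0:
        raise ValueError("composition must be 4 non-negative weights with positive sum")
    return comp / comp.sum()


def sample_background(n: int, L: int, composition=None, seed=0) -> list[str]:
    """n i.i.d. sequences of length L, positions i.i.d. from ``composition``
    over (A, C, G, U)."""
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    comp = _validate_composition(composition)
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET))
    draws = rng.choice(4, size=(n, L), p=comp)
    return ["".join(row) for row in letters[draws]]


def _draw_gap(rng: np.random.Generator, family: str, r: float, p: float, max_gap: int) -> int:
    for _ in range(_MAX_GAP_RETRIES):
        if family == "nbinom":
            gap = int(rng.negative_binomial(r, p))
        else:
            gap = int(rng.binomial(int(round(r)), p))
        if gap <= max_gap:
            return gap
    raise ValueError(
        f"could not draw a linker gap <= {max_gap} in {_MAX_GAP_RETRIES} tries; "
        "linker law mass lies beyond the sequence length"
    )


def implant_motifs(
    sequences: list[str],
    core_a: str | list[str],
    core_b: str | list[str],
    linker_family: str = "nbinom",
    linker_r: float = 4.0,
    linker_p: float = 0.4,
    seed=0,
) -> list[str]:
    """Overwrite each sequence with core_a, an untouched gap of sampled
    length, then core_b, at a uniformly chosen feasible start.

    ``core_a``/``core_b`` may be lists of variants sampled uniformly
    (degenerate-motif scenarios).  Output lengths equal input lengths; core
    A is always upstream of core B.
    """
    rng = np.random.default_rng(seed)
    variants_a = [core_a] if isinstance(core_a, str) else list(core_a)
    variants_b = [core_b] if isinstance(core_b, str) else list(core_b)
    out = []
    for seq in sequences:
        a = variants_a[rng.integers(len(variants_a))]
        b = variants_b[rng.integers(len(variants_b))]
        max_gap = len(seq) - len(a) - len(b)
        if max_gap < 0:
            raise ValueError(
                f"sequence of length {len(seq)} cannot host cores "
                f"{a!r} + {b!r}"
            )
        gap = _draw_gap(rng, linker_family, linker_r, linker_p, max_gap)
        block = len(a) + gap + len(b)
        start = int(rng.integers(len(seq) - block + 1))
        out.append(
            seq[:start]
            + a
            + seq[start + len(a) : start + len(a) + gap]
            + b
            + seq[start + block :]
        )
    return out


def make_benchmark(config: SyntheticConfig | None = None) -> Dataset:
    """Full benchmark dataset: independent background and enriched draws
    (disjoint seed streams), motifs implanted into the enriched set."""
    config = config or SyntheticConfig()
    bg_seed, enr_seed, implant_seed = np.random.SeedSequence(config.rng_seed).spawn(3)
    background = sample_background(
        config.n_background, config.sequence_length, config.composition, bg_seed
    )
    enriched_raw = sample_background(
        config.n_enriched, config.sequence_length, config.composition, enr_seed
    )
    enriched = implant_motifs(
        enriched_raw,
        config.core_a_variants or config.core_a,
        config.core_b_variants or config.core_b,
        linker_family=config.linker_family,
        linker_r=config.linker_r,
        linker_p=config.linker_p,
        seed=implant_seed,
    )
    return Dataset(enriched=enriched, background=background)
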