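"""Model containers: k-mer energy tables, spacer parameters, full model.

Energies are in units of k_B*T (k_B*T = 1 throughout).  The spacer between
the two cores follows a negative binomial NB(d; r, p); the unconstrained
parameterization r = e^rho, p = sigmoid(pi), S = e^scale_param keeps all
three within bounds during gradient optimization.  The free-protein
concentration c_AB is fixed to 1: only the ratio S / c_AB matters for the
binding dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import ClassVar

import numpy as np

__all__ = [
    "EnergyTable",
    "SpacerParams",
    "BmfModel",
    "DpResult",
    "pack_params",
    "unpack_params",
]


@dataclass
class EnergyTable:
    """Binding energies (k_B*T) of one domain for all 4^k k-mers,
    lexicographic order A<C<G<U."""

    k: int
    energies: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("core length k must be >= 1")
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.energies.shape != (4**self.k,):
            raise ValueError(
                f"energy table for k={self.k} must have length {4 ** self.k}, "
                f"got shape {self.energies.shape}"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energy table entries must be finite")

    def copy(self) -> "EnergyTable":
        return EnergyTable(self.k, self.energies.copy())


@dataclass
class SpacerParams:
    """Unconstrained spacer-law parameters.

    rho, pi, scale_param encode r = e^rho > 0, p = 1/(1+e^-pi) in (0,1) and
    S = e^scale_param >= 0 (scale_param = -inf encodes S = 0 exactly).
    """

    rho: float = 0.0
    pi: float = 0.0
    scale_param: float = -math.inf

    CAB: ClassVar[float] = 1.0  # free-protein concentration, fixed

    @property
    def r(self) -> float:
        return math.exp(self.rho)

    @property
    def p(self) -> float:
        return 1.0 / (1.0 + math.exp(-self.pi))

    @property
    def scale(self) -> float:
        return math.exp(self.scale_param)

    @classmethod
    def from_natural(cls, r: float, p: float, scale: float) -> "SpacerParams":
        """Build from natural-scale (r, p, S)."""
        if r <= 0:
            raise ValueError("r must be > 0")
        if not 0.0 < p < 1.0:
            raise ValueError("p must be in (0, 1)")
        if scale < 0:
            raise ValueError("S must be >= 0")
        return cls(
            rho=math.log(r),
            pi=math.log(p / (1.0 - p)),
            scale_param=math.log(scale) if scale > 0 else -math.inf,
        )

    def copy(self) -> "SpacerParams":
        return SpacerParams(self.rho, self.pi, self.scale_param)


@dataclass
class BmfModel:
    """Two-core bipartite binding model: energy tables of domains A and B
    plus the spacer law between them."""

    core_a: EnergyTable
    core_b: EnergyTable
    spacer: SpacerParams

    def __post_init__(self) -> None:
        if self.core_a.k != self.core_b.k:
            raise ValueError("both cores must share the same core length k")

    @property
    def k(self) -> int:
        return self.core_a.k

    def copy(self) -> "BmfModel":
        return BmfModel(self.core_a.copy(), self.core_b.copy(), self.spacer.copy())


@dataclass
class DpResult:
    """Partition sum and per-position statistical-weight sums.

    Z >= 1 always: the unbound configuration contributes weight 1.
    ``ZA[i]`` sums configurations with domain A bound ending exactly at i;
    ``ZB[i]`` sums configurations with no domain bound, or B bound with
    right edge at or upstream of i.  ``capped`` reports that the overflow
    guard clipped a statistical weight (Z is then a deterministic lower
    bound, not exact).
    """

    Z: float
    ZA: np.ndarray
    ZB: np.ndarray
    capped: bool = False


def pack_params(model: BmfModel) -> np.ndarray:
    """Flatten a model into the optimization vector
    [E_A (4^k), E_B (4^k), rho, pi, scale_param]."""
    return np.concatenate(
        [
            model.core_a.energies,
            model.core_b.energies,
            [model.spacer.rho, model.spacer.pi, model.spacer.scale_param],
        ]
    )


def unpack_params(vec: np.ndarray, k: int) -> BmfModel:
    """Inverse of :func:`pack_params`."""
    n = 4**k
    if vec.shape != (2 * n + 3,):
        raise ValueError(f"parameter vector must have length {2 * n + 3}")
    return BmfModel(
        core_a=EnergyTable(k, vec[:n].copy()),
        core_b=EnergyTable(k, vec[n : 2 * n].copy()),
        spacer=SpacerParams(rho=float(vec[-3]), pi=float(vec[-2]), scale_param=float(vec[-1])),
    )
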