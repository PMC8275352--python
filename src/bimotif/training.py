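"""Maximum-likelihood training with ADAM on minibatches.

Optimization ascends the enrichment log-likelihood (without its
parameter-free ln p_bg constant) over the unconstrained parameter vector
[E_A, E_B, rho, pi, scale_param].  Minibatches of enriched and background
reads are drawn without replacement within an epoch and reshuffled each
epoch; the Eq-normalizer over the background is evaluated on the background
minibatch.  Training stops when the relative variation of four tracked
statistics — the energy of the currently best-bound k-mer of each core, r
and p — stays below a threshold over a 5-iteration window, or after a hard
iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import Dataset, log_likelihood, model_gradient
from .model import BmfModel, EnergyTable, SpacerParams, pack_params, unpack_params

__all__ = [
    "TrainConfig",
    "AdamState",
    "TrainTrace",
    "initialize_model",
    "adam_update",
    "has_converged",
    "train",
]

# Initialization constants: mean/sd of the energy prior (k_B*T), spacer
# scale, and the ranges the NB parameters are drawn from.
INIT_ENERGY_MEAN = 12.0
INIT_ENERGY_SD = 1.0
INIT_SCALE = 1.0e4
INIT_R_RANGE = (1.0, 5.0)
INIT_P_RANGE = (0.0, 0.5)


@dataclass
class TrainConfig:
    """ADAM and stopping hyperparameters (defaults are the method's)."""

    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    minibatch_size: int = 512
    max_iterations: int = 1000
    variation_threshold: float = 0.03
    variation_window: int = 5
    convergence_check_every: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "learning_rate",
            "beta1",
            "beta2",
            "epsilon",
            "minibatch_size",
            "max_iterations",
            "variation_threshold",
            "convergence_check_every",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variation_window < 2:
            raise ValueError("variation_window must be >= 2")


@dataclass
class AdamState:
    """First/second-moment accumulators and step counter."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n_params: int) -> "AdamState":
        return cls(m=np.zeros(n_params), v=np.zeros(n_params), t=0)


@dataclass
class TrainTrace:
    """Per-iteration diagnostics recorded during training."""

    log_likelihood: list[float] = field(default_factory=list)
    best_energy_a: list[float] = field(default_factory=list)
    best_energy_b: list[float] = field(default_factory=list)
    r: list[float] = field(default_factory=list)
    p: list[float] = field(default_factory=list)
    n_iterations: int = 0
    termination_reason: str = "max_iterations"

    def record(self, ll: float, model: BmfModel) -> None:
        self.log_likelihood.append(ll)
        self.best_energy_a.append(float(model.core_a.energies.min()))
        self.best_energy_b.append(float(model.core_b.energies.min()))
        self.r.append(model.spacer.r)
        self.p.append(model.spacer.p)
        self.n_iterations = len(self.log_likelihood)

    def tracked_statistics(self) -> dict[str, list[float]]:
        return {
            "best_energy_a": self.best_energy_a,
            "best_energy_b": self.best_energy_b,
            "r": self.r,
            "p": self.p,
        }


def initialize_model(k: int, seed: int) -> BmfModel:
    """Random starting model.

    All 2*4^k energies i.i.d. Normal(12, 1) k_B*T (high enough that initial
    Boltzmann factors are small and the linear-space DP cannot overflow);
    S = 1e4; r ~ Uniform(1, 5); p ~ Uniform(0, 0.5).  Deterministic given
    the seed.
    """
    if k < 1:
        raise ValueError("core length k must be >= 1")
    rng = np.random.default_rng(seed)
    n = 4**k
    energies = rng.normal(INIT_ENERGY_MEAN, INIT_ENERGY_SD, size=2 * n)
    r = rng.uniform(*INIT_R_RANGE)
    p = rng.uniform(*INIT_P_RANGE)
    while p <= 0.0:  # keep p strictly inside (0, 0.5)
        p = rng.uniform(*INIT_P_RANGE)
    return BmfModel(
        core_a=EnergyTable(k, energies[:n]),
        core_b=EnergyTable(k, energies[n:]),
        spacer=SpacerParams.from_natural(r=r, p=p, scale=INIT_SCALE),
    )


def adam_update(
    params: np.ndarray,
    gradient: np.ndarray,
    state: AdamState,
    config: TrainConfig,
) -> tuple[np.ndarray, AdamState]:
    """One bias-corrected ADAM step, ascending the objective.

    params_{t+1} = params_t + alpha * m_hat / (sqrt(v_hat) + eps).
    """
    if params.shape != gradient.shape or params.shape != state.m.shape:
        raise ValueError("parameter, gradient and state shapes must agree")
    t = state.t + 1
    m = config.beta1 * state.m + (1.0 - config.beta1) * gradient
    v = config.beta2 * state.v + (1.0 - config.beta2) * gradient**2
    m_hat = m / (1.0 - config.beta1**t)
    v_hat = v / (1.0 - config.beta2**t)
    new_params = params + config.learning_rate * m_hat / (np.sqrt(v_hat) + config.epsilon)
    return new_params, AdamState(m=m, v=v, t=t)


def _variation(history: list[float], window: int) -> float:
    """v = (max - min) / last over the trailing window."""
    tail = history[-window:]
    hi, lo = max(tail), min(tail)
    if hi == lo:
        return 0.0
    last = tail[-1]
    if last == 0.0:
        return np.inf
    return (hi - lo) / last


def has_converged(trace: TrainTrace, config: TrainConfig) -> bool:
    """True iff every tracked statistic has relative variation below the
    threshold over the last ``variation_window`` iterations."""
    stats = trace.tracked_statistics()
    if any(len(h) < config.variation_window for h in stats.values()):
        return False
    return all(
        _variation(h, config.variation_window) < config.variation_threshold
        for h in stats.values()
    )


class _EpochSampler:
    """Without-replacement minibatches, reshuffled each epoch."""

    def __init__(self, n: int, batch: int, rng: np.random.Generator):
        self.n = n
        self.batch = min(batch, n)
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos + self.batch > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        out = self._order[self._pos : self._pos + self.batch]
        self._pos += self.batch
        return out


def train(
    dataset: Dataset,
    k: int,
    config: TrainConfig | None = None,
) -> tuple[BmfModel, TrainTrace]:
    """Fit a bipartite model to enriched/background reads.

    Fully reproducible from ``config.rng_seed`` (initialization and batch
    order both derive from it).  Returns the final model and the training
    trace; the recorded log-likelihoods are minibatch values without the
    constant ln p_bg term.
    """
    config = config or TrainConfig()
    seed_seq = np.random.SeedSequence(config.rng_seed)
    init_seed, batch_seed = seed_seq.spawn(2)
    model = initialize_model(k, init_seed)
    params = pack_params(model)
    state = AdamState.zeros(params.shape[0])
    trace = TrainTrace()

    rng = np.random.default_rng(batch_seed)
    enriched = dataset.enriched
    background = dataset.background
    sampler_plus = _EpochSampler(len(enriched), config.minibatch_size, rng)
    sampler_bg = _EpochSampler(len(background), config.minibatch_size, rng)

    # Convergence is judged on statistics sampled every
    # ``convergence_check_every`` iterations: per-iteration ADAM steps are
    # bounded by the learning rate, so consecutive-iteration variation is
    # tiny even while the optimizer is moving steadily; checkpoint spacing
    # makes the 5-value window span real progress.
    checkpoints = TrainTrace()
    for it in range(1, config.max_iterations + 1):
        idx_plus = sampler_plus.next_batch()
        idx_bg = sampler_bg.next_batch()
        batch = Dataset(
            enriched=[enriched[i] for i in idx_plus],
            background=[background[i] for i in idx_bg],
        )
        grad = model_gradient(batch, model)
        params, state = adam_update(params, grad, state, config)
        model = unpack_params(params, k)
        ll = log_likelihood(batch, model, include_background_fraction=False)
        trace.record(ll, model)
        if it % config.convergence_check_every == 0:
            checkpoints.record(ll, model)
            if has_converged(checkpoints, config):
                trace.termination_reason = "converged"
                break
    else:
        trace.termination_reason = "max_iterations"
    return model, trace
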