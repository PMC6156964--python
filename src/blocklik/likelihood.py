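"""Monte-Carlo approximation of the composite likelihood of a bSFS table.

Given a demographic model, the probability of a block configuration ``k``
conditional on one sampled ARG with class-length vector ``t`` is a product of
independent Poissons, one per mutation class:

    p(k | t) = prod_i Poisson(k_i ; theta_block * t_i)

with two conventions closing the space:

* a zero-length class contributes 1 when ``k_i = 0`` and kills the product
  when ``k_i > 0``;
* a lumped tail entry ``k_i > k_max`` takes the complementary Poisson mass
  ``1 - sum_{k<=k_max} Poisson(k; theta*t_i)`` (computed via the complemented
  regularized incomplete gamma function for stability).

The model probability is the arithmetic mean over ``M`` sampled ARGs,

    p_hat(k | Theta) = (1/M) * sum_d p(k | t_d),

and the composite log-likelihood of a table is
``sum_k n_k * ln p_hat(k)``.  Every sampled ARG contributes to every
configuration; configurations left with zero Monte-Carlo mass are floored
(default ``1/(10*M)``) and counted, so an optimizer sees a strong but finite
penalty rather than ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .arg_sampler import ArgSummary, sample_class_matrix
from .bsfs import (
    LUMPED,
    BlockConfiguration,
    BsfsTable,
    LumpingSpec,
    enumerate_configurations,
)
from .classes import ClassIndex, SampleLayout
from .demography import DemographicModel, block_rates

__all__ = [
    "LikelihoodSettings",
    "LikelihoodResult",
    "config_prob_given_lengths",
    "config_probs_from_draws",
    "table_loglik",
    "approximate_config_probs",
    "exhaustive_lumped_probs",
]

_CHUNK = 512  # draws per vectorized block; bounds peak memory at n_configs*_CHUNK


@dataclass
class LikelihoodSettings:
    """Monte-Carlo evaluation settings.

    ``num_args`` is the number of ARGs sampled per evaluation (the reference
    schedules use 5e4/5e5/1e6; desk-scale runs scale this down).  ``floor``
    defaults to ``1/(10*num_args)``.  With ``reuse_draws`` the same seed (and
    hence common random numbers) is used across evaluations.
    """

    num_args: int = 1000
    seed: int = 0
    reuse_draws: bool = False
    floor: float | None = None
    single_tree: bool = False

    def __post_init__(self) -> None:
        if self.num_args < 1:
            raise ValueError("num_args must be >= 1")
        if self.floor is not None and not 0.0 < self.floor < 1.0:
            raise ValueError("floor must lie in (0, 1)")

    @property
    def effective_floor(self) -> float:
        return self.floor if self.floor is not None else 1.0 / (10.0 * self.num_args)


@dataclass
class LikelihoodResult:
    loglik: float
    per_config: dict[BlockConfiguration, float]
    zero_mass_configs: int
    args_used: int
    floored: bool = field(default=False)


def _as_length_matrix(t) -> np.ndarray:
    if isinstance(t, ArgSummary):
        t = t.class_lengths
    t = np.asarray(t, dtype=float)
    return np.atleast_2d(t)


def _config_arrays(
    configs: Sequence[BlockConfiguration],
) -> tuple[np.ndarray, np.ndarray]:
    K = np.asarray(configs, dtype=np.int64).reshape(len(configs), -1)
    mask = K == LUMPED
    return np.where(mask, 0, K), mask


def _prob_chunk(
    K: np.ndarray,
    mask: np.ndarray,
    lam: np.ndarray,
    k_max: int | None,
) -> np.ndarray:
    """p(k | t_d) for every configuration and draw in the chunk.

    ``K``/``mask``: (n, C) exact counts and tail flags; ``lam``: (M, C)
    Poisson rates.  Returns (n, M).  The zero-rate convention (``t_i = 0``)
    falls out of the pmf recurrence: pmf(0)=1, pmf(k>0)=0, tail mass 0.
    """
    M, C = lam.shape
    kmax_needed = int(K.max(initial=0))
    cube = np.empty((kmax_needed + 1, M, C))
    cube[0] = np.exp(-lam)
    for k in range(1, kmax_needed + 1):
        cube[k] = cube[k - 1] * lam / k
    tail = None
    if mask.any():
        if k_max is None:
            raise ValueError("lumped entries present but no k_max given")
        tail = poisson.sf(k_max, lam)  # (M, C); complemented incomplete gamma
    P = np.ones((K.shape[0], M))
    for c in range(C):
        vals = cube[K[:, c], :, c]  # fancy index -> copy, (n, M)
        if tail is not None and mask[:, c].any():
            vals[mask[:, c], :] = tail[:, c]
        P *= vals
    return P


def config_probs_from_draws(
    configs: Sequence[BlockConfiguration],
    draws: np.ndarray,
    theta_block: float,
    k_max: int | None = None,
) -> np.ndarray:
    """Monte-Carlo mean probability per configuration over a draw matrix,
    chunked over draws to bound memory."""
    if theta_block < 0:
        raise ValueError("theta_block must be >= 0")
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    K, mask = _config_arrays(configs)
    if K.shape[1] != draws.shape[1]:
        raise ValueError(
            f"configurations have {K.shape[1]} classes but draws have "
            f"{draws.shape[1]}"
        )
    M = draws.shape[0]
    acc = np.zeros(K.shape[0])
    for start in range(0, M, _CHUNK):
        lam = theta_block * draws[start : start + _CHUNK]
        acc += _prob_chunk(K, mask, lam, k_max).sum(axis=1)
    return acc / M


def config_prob_given_lengths(
    k: BlockConfiguration,
    t,
    theta_block: float,
    k_max: int | None = None,
) -> float:
    """Probability of one configuration conditional on one ARG's class-length
    vector (``t`` may be an :class:`ArgSummary` or an array)."""
    draws = _as_length_matrix(t)
    return float(config_probs_from_draws([tuple(k)], draws, theta_block, k_max)[0])


def table_loglik(
    table: BsfsTable,
    draws: np.ndarray,
    theta_block: float,
    floor: float,
) -> LikelihoodResult:
    """Composite log-likelihood of a table against a fixed draw matrix."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    configs = table.configs_sorted()
    k_max = table.lumping.k_max if table.lumping is not None else None
    phat = config_probs_from_draws(configs, draws, theta_block, k_max)
    n = np.array([table.entries[c] for c in configs], dtype=float)
    zero = phat <= 0.0
    nz = int(zero.sum())
    safe = np.where(zero, floor, phat)
    loglik = float(np.dot(n, np.log(safe)))
    return LikelihoodResult(
        loglik=loglik,
        per_config=dict(zip(configs, phat.tolist())),
        zero_mass_configs=nz,
        args_used=draws.shape[0],
        floored=nz > 0,
    )


def approximate_config_probs(
    table: BsfsTable,
    model: DemographicModel,
    settings: LikelihoodSettings,
    draws: np.ndarray | None = None,
) -> LikelihoodResult:
    """Sample ``num_args`` blockwise ARGs under the model and average the
    per-ARG configuration probabilities into the composite likelihood.

    A precomputed ``draws`` matrix (from :func:`arg_sampler.sample_class_matrix`)
    may be supplied to reuse common random numbers across evaluations.
    """
    layout = table.layout
    _check_layout(table.layout, model)
    theta_block, _ = block_rates(model, layout)
    if draws is None:
        draws = sample_class_matrix(
            model,
            layout,
            settings.num_args,
            settings.seed,
            single_tree=settings.single_tree or model.recombination_rate == 0,
        )
    return table_loglik(table, draws, theta_block, settings.effective_floor)


def _check_layout(layout: SampleLayout, model: DemographicModel) -> None:
    if layout.num_populations > len(model.populations):
        raise ValueError(
            f"table layout has {layout.num_populations} populations but the "
            f"model defines {len(model.populations)}"
        )


def exhaustive_lumped_probs(
    model: DemographicModel,
    layout: SampleLayout,
    lumping: LumpingSpec,
    settings: LikelihoodSettings,
    no_recombination: bool = False,
    draws: np.ndarray | None = None,
) -> Mapping[BlockConfiguration, float]:
    """Approximate probabilities over the *complete* lumped configuration
    space; for each single ARG (and hence the average) these sum to exactly
    one — the normalization contract of the lumping tail."""
    configs = enumerate_configurations(layout, lumping, no_recombination)
    _check_layout(layout, model)
    theta_block, _ = block_rates(model, layout)
    if draws is None:
        draws = sample_class_matrix(
            model,
            layout,
            settings.num_args,
            settings.seed,
            single_tree=settings.single_tree or model.recombination_rate == 0,
        )
    phat = config_probs_from_draws(configs, draws, theta_block, lumping.k_max)
    return dict(zip(configs, phat.tolist()))
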