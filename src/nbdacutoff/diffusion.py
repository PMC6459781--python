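"""Simulate the spread of a novel behavior through a weighted network.

The transmission model is the standard NBDA one: a naive individual i's
learning rate given the currently informed set is

    R_i = s * (sum of a_ij over informed j) + 1,

where s is the social-learning parameter (strength of social transmission
per unit association, relative to a baseline asocial rate of 1).  The
probability that i is the next learner is R_i / sum over naive j of R_j.
The innovator is drawn uniformly, and acquisition continues until a fixed
number of individuals have learned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .network import AssociationNetwork

__all__ = [
    "Diffusion",
    "learning_rates",
    "acquisition_probabilities",
    "simulate_diffusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Diffusion:
    """An order-of-acquisition record: who learned, in what order.

    ``order[0]`` is the innovator; ``s_true`` is the social-learning
    parameter the diffusion was generated under (0 for purely asocial).
    """

    order: tuple[str, ...]
    s_true: float
    network_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        order = tuple(str(i) for i in self.order)
        universe = tuple(str(i) for i in self.network_ids)
        if len(order) < 1:
            raise ValidationError("diffusion order must be non-empty")
        if len(set(order)) != len(order):
            raise ValidationError("diffusion order contains duplicates")
        missing = set(order) - set(universe)
        if missing:
            raise ValidationError(f"learners not in network: {sorted(missing)}")
        if self.s_true < 0:
            raise ValidationError("s_true must be non-negative")
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "network_ids", universe)

    @property
    def n_learners(self) -> int:
        return len(self.order)


def learning_rates(
    net: AssociationNetwork, informed: Iterable[str], s: float
) -> dict[str, float]:
    """Per-naive-individual learning rates R_i = s * sum_j a_ij + 1.

    The sum runs over informed j; individuals with no connection to any
    informed individual fall back to the asocial baseline rate of 1.
    """
    if s < 0:
        raise ValidationError("social learning parameter s must be >= 0")
    informed_set = set(informed)
    informed_idx = [net.index_of(i) for i in informed_set]
    totals = net.weights[:, informed_idx].sum(axis=1) if informed_idx else np.zeros(
        net.n_individuals
    )
    return {
        ind: 1.0 + s * float(totals[k])
        for k, ind in enumerate(net.individual_ids)
        if ind not in informed_set
    }


def acquisition_probabilities(rates: Mapping[str, float]) -> dict[str, float]:
    """Normalize rates into next-learner probabilities R_i / sum_j R_j."""
    if not rates:
        raise ValidationError("no naive individuals left to learn")
    total = float(sum(rates.values()))
    return {ind: r / total for ind, r in rates.items()}


def simulate_diffusion(
    net: AssociationNetwork,
    s: float,
    n_learners: int = 20,
    rng: np.random.Generator | None = None,
) -> Diffusion:
    """Simulate one diffusion of `n_learners` acquisition events.

    The innovator is uniform over the network; each later learner is drawn
    from the naive set with probability proportional to its current rate.
    Reproducible under a fixed `rng`.
    """
    if s < 0:
        raise ValidationError("social learning parameter s must be >= 0")
    n = net.n_individuals
    if not 1 <= n_learners <= n:
        raise ValidationError(
            f"n_learners must be in [1, {n}], got {n_learners}"
        )
    if rng is None:
        rng = np.random.default_rng()

    w = net.weights
    naive = np.ones(n, dtype=bool)
    assoc_to_informed = np.zeros(n)

    first = int(rng.integers(n))
    order = [first]
    naive[first] = False
    for _ in range(1, n_learners):
        assoc_to_informed += w[:, order[-1]]
        idx = np.flatnonzero(naive)
        rates = 1.0 + s * assoc_to_informed[idx]
        nxt = int(rng.choice(idx, p=rates / rates.sum()))
        order.append(nxt)
        naive[nxt] = False

    ids = net.individual_ids
    return Diffusion(
        tuple(ids[i] for i in order), s_true=float(s), network_ids=ids
    )
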