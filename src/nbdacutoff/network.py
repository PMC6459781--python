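"""Association networks from observation data, with principled noise.

Association strength between two individuals is estimated with the simple
ratio index (SRI): the proportion of sampling periods in which the dyad was
seen together, out of all periods in which at least one of the two was
identified,

    SRI = x / (y_a + y_b + y_ab + x),

where x counts periods together and the y terms count periods where only
one (or both, but not associated) was identified.  Under the
group-by-individual representation, presence in the same row *is*
association, so y_ab is identically zero and the failures reduce to
y_a + y_b.

Because the SRI estimates a proportion from n = x + failures Bernoulli
trials, uncertainty about the true association is naturally expressed as a
Beta posterior: with a Beta(a, b) prior,

    a_ij | data ~ Beta(a + x, b + (n - x)).

Sampling one network from these per-dyad posteriors injects exactly the
amount of observational noise the sampling effort warrants: well-sampled
dyads reproduce their SRI closely, poorly sampled dyads vary widely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .obsdata import ObservationMatrix

__all__ = [
    "DyadCounts",
    "AssociationNetwork",
    "NoisePrior",
    "dyad_counts",
    "sri_matrix",
    "sample_noisy_network",
    "read_network",
    "write_network",
    "subnetwork",
]

logger = logging.getLogger(__name__)


def _check_symmetric(name: str, m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diagonal(m), 0):
        raise ValidationError(f"{name} must have a zero diagonal")


@dataclass(frozen=True)
class DyadCounts:
    """Per-dyad association tallies.

    ``together[i, j]`` is the number of sampling periods i and j were
    observed associated (x); ``apart[i, j]`` the number of periods exactly
    one of the two was identified (the failures).  Their sum is the dyad's
    effective sample size n.
    """

    individual_ids: tuple[str, ...]
    together: np.ndarray
    apart: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.individual_ids)
        tog = np.asarray(self.together, dtype=np.int64)
        ap = np.asarray(self.apart, dtype=np.int64)
        for name, m in (("together", tog), ("apart", ap)):
            _check_symmetric(name, m)
            if (m < 0).any():
                raise ValidationError(f"{name} counts must be non-negative")
        if tog.shape != ap.shape or tog.shape[0] != len(ids):
            raise ValidationError("together/apart/id dimensions disagree")
        tog.setflags(write=False)
        ap.setflags(write=False)
        object.__setattr__(self, "individual_ids", ids)
        object.__setattr__(self, "together", tog)
        object.__setattr__(self, "apart", ap)

    @property
    def n_dyad(self) -> np.ndarray:
        """Per-dyad sample size n = together + apart."""
        return self.together + self.apart


@dataclass(frozen=True)
class AssociationNetwork:
    """Symmetric weighted network with edge weights a_ij in [0, 1]."""

    individual_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.individual_ids)
        w = np.asarray(self.weights, dtype=float)
        _check_symmetric("weights", w)
        if w.shape[0] != len(ids):
            raise ValidationError("weights/id dimensions disagree")
        if (w < 0).any() or (w > 1).any():
            raise ValidationError("association weights must lie in [0, 1]")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "individual_ids", ids)
        object.__setattr__(self, "weights", w)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def index_of(self, individual: str) -> int:
        try:
            return self.individual_ids.index(individual)
        except ValueError:
            raise ValidationError(
                f"individual {individual!r} not in network"
            ) from None


@dataclass(frozen=True)
class NoisePrior:
    """Beta(alpha, beta) prior on each dyad's true association proportion.

    The default Beta(1, 1) is uniform on [0, 1]: with no data, any
    association strength is considered equally plausible.
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("Beta prior parameters must be positive")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def dyad_counts(obs: ObservationMatrix) -> DyadCounts:
    """Tally per-dyad together/apart counts from the observation matrix."""
    x = obs.presence.astype(np.int64)
    together = x.T @ x
    np.fill_diagonal(together, 0)
    per_ind = x.sum(axis=0)
    # periods with exactly one of the dyad present
    apart = per_ind[:, None] + per_ind[None, :] - 2 * together
    np.fill_diagonal(apart, 0)
    return DyadCounts(obs.individual_ids, together, apart)


def sri_matrix(counts: DyadCounts) -> AssociationNetwork:
    """Point-estimate network of simple ratio indices.

    Never-sampled dyads (together = apart = 0) get SRI 0 by convention so
    the error-free network is defined everywhere; the noise model, by
    contrast, assigns such dyads their full uniform posterior.
    """
    denom = (counts.together + counts.apart).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, counts.together / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationNetwork(counts.individual_ids, w)


def sample_noisy_network(
    counts: DyadCounts,
    prior: NoisePrior = NoisePrior(),
    rng: np.random.Generator | None = None,
) -> AssociationNetwork:
    """Draw one network from the per-dyad Beta posteriors.

    One independent draw per unordered dyad from
    Beta(alpha + together, beta + apart), mirrored to both triangles (the
    network is undirected).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(counts.individual_ids)
    iu = np.triu_indices(n, k=1)
    a = prior.alpha + counts.together[iu]
    b = prior.beta + counts.apart[iu]
    draws = rng.beta(a, b)
    w = np.zeros((n, n))
    w[iu] = draws
    w += w.T
    return AssociationNetwork(counts.individual_ids, w)


# ---------------------------------------------------------------------------
# Square-matrix CSV dialect (header row and first column = ids)
# ---------------------------------------------------------------------------


def write_network(net: AssociationNetwork, path: str | Path) -> None:
    ids = list(net.individual_ids)
    pd.DataFrame(net.weights, index=ids, columns=ids).to_csv(path)


def read_network(path: str | Path) -> AssociationNetwork:
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != ids:
        raise ValidationError(f"{path}: row and column ids disagree")
    return AssociationNetwork(tuple(ids), df.to_numpy(dtype=float))


def subnetwork(net: AssociationNetwork, keep: list[str]) -> AssociationNetwork:
    """Restrict the network to `keep` (order follows the original network)."""
    keep_set = set(keep)
    idx = [i for i, ind in enumerate(net.individual_ids) if ind in keep_set]
    if not idx:
        raise ValidationError("subnetwork would be empty")
    sel = np.ix_(idx, idx)
    return AssociationNetwork(
        tuple(net.individual_ids[i] for i in idx), net.weights[sel]
    )
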