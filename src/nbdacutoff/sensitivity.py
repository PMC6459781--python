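"""Monte-Carlo sensitivity of NBDA to the sighting cut-off point.

The headline procedure: for each candidate cut-off N, repeat many times

    1. simulate a diffusion on the error-free SRI network at the chosen
       social-learning parameter s (s > 0 for a power run, s = 0 for a
       false-positive run);
    2. draw one noisy network from the per-dyad Beta posteriors;
    3. drop every individual seen fewer than N times (optionally retaining
       learners regardless of sightings) from the network and the order;
    4. fit social and asocial OADA models and compare them by AICc,

then summarize, per cut-off: the proportion of conclusive model
comparisons, the proportion of those won by the social model (the power
when s > 0, the false-positive rate when s = 0), the mean and SD of the s
estimates, 95% CI coverage of the true s, and the over/under-estimation
split.  The cut-off maximizing power — subject to an acceptable
false-positive rate — is the recommended inclusion threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffusion import Diffusion, simulate_diffusion
from .errors import ConfigError, DegenerateCutoffError, DegenerateFitError
from .network import (
    AssociationNetwork,
    NoisePrior,
    dyad_counts,
    sample_noisy_network,
    sri_matrix,
    subnetwork,
)
from .oada import S_MAX_DEFAULT, compare_models, fit_oada
from .obsdata import ObservationMatrix, sighting_counts

__all__ = [
    "RunConfig",
    "CutoffSummary",
    "DEFAULT_CUTOFFS",
    "apply_cutoff",
    "run_replicate",
    "run_sweep",
    "summaries_to_frame",
    "write_summary_csv",
]

logger = logging.getLogger(__name__)

#: Default grid of sighting cut-off points swept by the tool.
DEFAULT_CUTOFFS: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 7, 8, 10, 11, 13, 14, 15, 16, 17, 18, 19, 21, 22, 24,
    26, 27,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one sensitivity sweep.

    ``s_true`` is the generating social-learning parameter: a power run
    uses a value > 0 chosen (by trial and error on the data set) to put
    power in a discriminating range; a false-positive run uses 0.
    """

    s_true: float = 8.0
    n_learners: int = 20
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    n_reps: int = 10_000
    retain_learners: bool = False
    delta_threshold: float = 2.0
    noise_prior: NoisePrior = field(default_factory=NoisePrior)
    resimulate_diffusion_each_rep: bool = True
    base_seed: int = 0
    s_max: float = S_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.s_true < 0:
            raise ConfigError("s_true must be >= 0")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.n_learners < 2:
            raise ConfigError("n_learners must be >= 2")
        cutoffs = tuple(int(c) for c in self.cutoffs)
        if not cutoffs or any(c < 1 for c in cutoffs):
            raise ConfigError("cutoffs must be positive integers")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ConfigError("cutoffs must be strictly increasing")
        if self.delta_threshold <= 0:
            raise ConfigError("delta_threshold must be positive")
        object.__setattr__(self, "cutoffs", cutoffs)

    def asocial(self) -> "RunConfig":
        """The matching false-positive configuration (s_true = 0)."""
        return replace(self, s_true=0.0)


@dataclass(frozen=True)
class CutoffSummary:
    """Per-cut-off summary over Monte-Carlo replicates.

    Proportions are computed over conclusive replicates (those where
    |delta AICc| exceeded the selection threshold); degenerate replicates
    (too few individuals or learners surviving the cut-off) are excluded
    from every denominator and reported in ``n_degenerate``.
    ``power_or_fpr`` is statistical power when the run's s_true > 0 and
    the false-positive rate when s_true = 0.  ``power_all_reps`` is the
    same count normalized by all non-degenerate replicates.
    """

    cutoff: int
    n_included: int
    n_reps: int
    n_conclusive: int
    prop_conclusive: float
    power_or_fpr: float
    mean_s_hat: float
    sd_s_hat: float
    ci_coverage: float
    prop_overestimate: float
    prop_underestimate: float
    n_degenerate: int
    power_all_reps: float


# ---------------------------------------------------------------------------
# Cut-off application
# ---------------------------------------------------------------------------


def apply_cutoff(
    counts: Mapping[str, int],
    net: AssociationNetwork,
    diff: Diffusion,
    cutoff: int,
    retain_learners: bool = False,
) -> tuple[AssociationNetwork, tuple[str, ...]]:
    """Drop under-sighted individuals from the network and the order.

    Keeps every individual seen at least ``cutoff`` times; with
    ``retain_learners`` the learners stay regardless of sightings and only
    naive individuals are dropped.  Dropped learners disappear entirely:
    they are not treated as informed when the reduced order is analyzed.
    Raises :class:`DegenerateCutoffError` when nothing (or fewer than two
    learners) survives.
    """
    learners = set(diff.order) if retain_learners else set()
    kept = [
        ind
        for ind in net.individual_ids
        if counts.get(ind, 0) >= cutoff or ind in learners
    ]
    if not kept:
        raise DegenerateCutoffError(f"cut-off {cutoff} removes every individual")
    kept_set = set(kept)
    reduced_order = tuple(i for i in diff.order if i in kept_set)
    if len(reduced_order) < 2:
        raise DegenerateCutoffError(
            f"cut-off {cutoff} leaves {len(reduced_order)} learner(s)"
        )
    return subnetwork(net, kept), reduced_order


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def _replicate(
    true_net: AssociationNetwork,
    counts: Mapping[str, int],
    dyads,
    cfg: RunConfig,
    cutoff: int,
    rng: np.random.Generator,
    diff: Diffusion | None = None,
) -> dict:
    """One pass of the simulate/noise/cut-off/fit loop; returns a record."""
    if diff is None:
        diff = simulate_diffusion(true_net, cfg.s_true, cfg.n_learners, rng)
    noisy = sample_noisy_network(dyads, cfg.noise_prior, rng)
    record: dict = {"cutoff": cutoff, "degenerate": False}
    try:
        red_net, red_order = apply_cutoff(
            counts, noisy, diff, cutoff, cfg.retain_learners
        )
        fit = fit_oada(red_net, red_order, s_max=cfg.s_max)
    except (DegenerateCutoffError, DegenerateFitError) as exc:
        record["degenerate"] = True
        record["reason"] = str(exc)
        return record

    comparison = compare_models(fit, cfg.delta_threshold)
    record.update(fit.to_record())
    record["conclusive"] = comparison.conclusive
    record["winner"] = comparison.winner
    record["covered"] = fit.ci_lower <= cfg.s_true <= fit.ci_upper
    record["overestimate"] = cfg.s_true < fit.ci_lower
    record["underestimate"] = cfg.s_true > fit.ci_upper
    return record


def run_replicate(
    obs: ObservationMatrix,
    true_net: AssociationNetwork,
    cfg: RunConfig,
    cutoff: int,
    rng: np.random.Generator,
) -> dict:
    """Public single-replicate entry point (derives counts from `obs`)."""
    return _replicate(
        true_net, sighting_counts(obs), dyad_counts(obs), cfg, cutoff, rng
    )


def _replicate_rng(base_seed: int, cutoff_index: int, rep: int) -> np.random.Generator:
    # independent, order-insensitive streams per (cutoff, replicate)
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), cutoff_index, rep])
    )


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------


def run_sweep(obs: ObservationMatrix, cfg: RunConfig) -> list[CutoffSummary]:
    """Sweep all configured cut-offs and summarize each.

    The diffusion is re-simulated every replicate by default (the noisy
    network always is); set ``resimulate_diffusion_each_rep=False`` to
    analyze one fixed diffusion — the situation of a researcher holding a
    single observed diffusion — under noise alone.
    """
    counts = sighting_counts(obs)
    dyads = dyad_counts(obs)
    true_net = sri_matrix(dyads)

    fixed_diff: Diffusion | None = None
    if not cfg.resimulate_diffusion_each_rep:
        fixed_rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.base_seed), 0x5EED])
        )
        fixed_diff = simulate_diffusion(
            true_net, cfg.s_true, cfg.n_learners, fixed_rng
        )

    summaries = []
    for ci, cutoff in enumerate(cfg.cutoffs):
        n_included = sum(1 for c in counts.values() if c >= cutoff)
        records = [
            _replicate(
                true_net,
                counts,
                dyads,
                cfg,
                cutoff,
                _replicate_rng(cfg.base_seed, ci, rep),
                diff=fixed_diff,
            )
            for rep in range(cfg.n_reps)
        ]
        summaries.append(_summarize(cutoff, n_included, cfg, records))
        logger.info(
            "cutoff %d: %d included, power/fpr %.3f",
            cutoff, n_included, summaries[-1].power_or_fpr,
        )
    return summaries


def _summarize(
    cutoff: int, n_included: int, cfg: RunConfig, records: list[dict]
) -> CutoffSummary:
    n_reps = len(records)
    usable = [r for r in records if not r["degenerate"]]
    n_degenerate = n_reps - len(usable)
    conclusive = [r for r in usable if r["conclusive"]]
    n_conclusive = len(conclusive)
    social_wins = sum(1 for r in conclusive if r["winner"] == "social")

    def _prop(num: int, den: int) -> float:
        return num / den if den else math.nan

    if conclusive:
        s_hats = np.array([r["s_hat"] for r in conclusive])
        mean_s = float(s_hats.mean())
        sd_s = float(s_hats.std(ddof=1)) if len(s_hats) > 1 else math.nan
        coverage = _prop(sum(r["covered"] for r in conclusive), n_conclusive)
        over = _prop(sum(r["overestimate"] for r in conclusive), n_conclusive)
        under = _prop(sum(r["underestimate"] for r in conclusive), n_conclusive)
    else:
        mean_s = sd_s = coverage = over = under = math.nan

    return CutoffSummary(
        cutoff=cutoff,
        n_included=n_included,
        n_reps=n_reps,
        n_conclusive=n_conclusive,
        prop_conclusive=_prop(n_conclusive, len(usable)),
        power_or_fpr=_prop(social_wins, n_conclusive),
        mean_s_hat=mean_s,
        sd_s_hat=sd_s,
        ci_coverage=coverage,
        prop_overestimate=over,
        prop_underestimate=under,
        n_degenerate=n_degenerate,
        power_all_reps=_prop(social_wins, len(usable)),
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "cutoff",
    "n_included",
    "n_reps",
    "n_conclusive",
    "prop_conclusive",
    "power",
    "mean_s_hat",
    "sd_s_hat",
    "ci_coverage",
    "prop_overestimate",
    "prop_underestimate",
    "n_degenerate",
    "power_all_reps",
]


def summaries_to_frame(summaries: list[CutoffSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "cutoff": s.cutoff,
                "n_included": s.n_included,
                "n_reps": s.n_reps,
                "n_conclusive": s.n_conclusive,
                "prop_conclusive": s.prop_conclusive,
                "power": s.power_or_fpr,
                "mean_s_hat": s.mean_s_hat,
                "sd_s_hat": s.sd_s_hat,
                "ci_coverage": s.ci_coverage,
                "prop_overestimate": s.prop_overestimate,
                "prop_underestimate": s.prop_underestimate,
                "n_degenerate": s.n_degenerate,
                "power_all_reps": s.power_all_reps,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_summary_csv(summaries: list[CutoffSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)
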