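"""Execution of a single adaptive trial and of replicate batches.

A trial recruits ``first_look_per_arm`` participants per arm (1:1,
outcomes observed immediately), analyses, then keeps adding
``batch_per_arm`` per arm between looks.  At every look the posterior of
the risk difference Delta = p_B − p_A is computed and the rules applied in
this order:

1. **equivalence** — stop if Pr(|Delta| < delta) >= E, winner ``none``
   (equivalence takes precedence if both rules fire simultaneously);
2. **efficacy** — stop if max(Pr(B>A), Pr(A>B)) >= S, winner = arm with the
   higher posterior mean success probability;
3. otherwise continue; when the cap ``max_total_n`` is reached a final
   analysis is run there and, if no rule fires, the trial is inconclusive
   (``max_n``).

Each interim analysis estimates the decision probabilities from
``design.decision_draws`` independent posterior draws — by default 40% of
``posterior_draws``, emulating the effective sample size of a
10,000-iteration Gibbs analysis of this model.  The Monte-Carlo wobble of
these estimates is part of the design's operating characteristics: a rule
fires when the *estimated* probability crosses its threshold, so a noisier
analysis engine stops slightly more often, and the simulator reproduces
that behaviour rather than idealising it away (``mc_efficiency=1`` gives
the idealised i.i.d. variant).

Reproducibility: a trial is a pure function of (design, scenario, seed).
Outcome generation and the posterior draws of interim ``k`` use independent
streams derived from the trial seed via ``numpy.random.SeedSequence`` spawn
keys, so replicates are bit-reproducible given a master seed and results do
not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .design import DesignSpec, ScenarioSpec
from .posterior import (
    ArmCounts,
    PosteriorSummary,
    _approx_prob_draws,
    _mcmc_prob_draws,
    _summarize,
)

__all__ = ["StopReason", "Winner", "TrialResult", "simulate_trial", "run_replicates", "results_to_frame"]

logger = logging.getLogger(__name__)


class StopReason(str, Enum):
    EFFICACY = "efficacy"
    EQUIVALENCE = "equivalence"
    MAX_N = "max_n"


class Winner(str, Enum):
    A = "A"
    B = "B"
    NONE = "none"


@dataclass(frozen=True)
class TrialResult:
    """Everything recorded about one simulated trial."""

    stop_reason: StopReason
    winner: Winner
    counts_A: ArmCounts
    counts_B: ArmCounts
    total_n: int
    n_interims: int
    final_posterior: PosteriorSummary
    observed_diff: float
    replicate_id: int
    seed: int
    both_rules_met: bool = False


def simulate_trial(
    design: DesignSpec,
    scenario: ScenarioSpec,
    seed: int,
    backend: str = "approx",
    replicate_id: int = 0,
) -> TrialResult:
    """Run one adaptive trial to completion under the given true rates."""
    outcome_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    cap_per_arm = design.max_total_n // 2
    delta = design.indifference_halfwidth
    S = design.efficacy_threshold_S
    E = design.equivalence_threshold_E
    draws_fn = _approx_prob_draws if backend == "approx" else _mcmc_prob_draws
    if backend not in ("approx", "sample"):
        raise ValueError(f"unknown backend {backend!r}; expected 'approx' or 'sample'")

    xA = xB = 0
    n_per_arm = 0
    next_per_arm = min(design.first_look_per_arm, cap_per_arm)
    interim = 0
    while True:
        batch = next_per_arm - n_per_arm
        xA += int(outcome_rng.binomial(batch, scenario.p_A_true))
        xB += int(outcome_rng.binomial(batch, scenario.p_B_true))
        n_per_arm = next_per_arm
        interim += 1

        post_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, interim))
        )
        pA_d, pB_d = draws_fn(xA, n_per_arm, xB, n_per_arm, design.priors,
                              design.decision_draws, post_rng)
        d = pB_d - pA_d
        pr_within = float(np.mean(np.abs(d) < delta))
        pr_b = float(np.mean(d > 0.0))
        equiv_fires = pr_within >= E
        effic_fires = max(pr_b, 1.0 - pr_b) >= S

        if equiv_fires:
            stop, winner = StopReason.EQUIVALENCE, Winner.NONE
        elif effic_fires:
            stop = StopReason.EFFICACY
            mean_a, mean_b = float(pA_d.mean()), float(pB_d.mean())
            if mean_a == mean_b:  # measure-zero tie; break toward A
                logger.warning("posterior-mean tie at interim %d; declaring arm A", interim)
                winner = Winner.A
            else:
                winner = Winner.B if mean_b > mean_a else Winner.A
        elif n_per_arm >= cap_per_arm:
            stop, winner = StopReason.MAX_N, Winner.NONE
        else:
            next_per_arm = min(n_per_arm + design.batch_per_arm, cap_per_arm)
            continue

        summary = _summarize(pA_d, pB_d, delta)
        return TrialResult(
            stop_reason=stop,
            winner=winner,
            counts_A=ArmCounts(xA, n_per_arm),
            counts_B=ArmCounts(xB, n_per_arm),
            total_n=2 * n_per_arm,
            n_interims=interim,
            final_posterior=summary,
            observed_diff=xB / n_per_arm - xA / n_per_arm,
            replicate_id=replicate_id,
            seed=seed,
            both_rules_met=equiv_fires and effic_fires,
        )


def replicate_seed(master_seed: int, replicate_id: int) -> int:
    """Deterministic per-replicate seed (31-bit) derived from the master seed."""
    ss = np.random.SeedSequence((master_seed, replicate_id))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def run_replicates(
    design: DesignSpec,
    scenario: ScenarioSpec,
    n_reps: int,
    master_seed: int,
    backend: str = "approx",
) -> list[TrialResult]:
    """n_reps independent trials with per-replicate seeds derived from master_seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    return [
        simulate_trial(design, scenario, replicate_seed(master_seed, i), backend, replicate_id=i)
        for i in range(n_reps)
    ]


def results_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Flat results table, one row per trial (stable CSV schema)."""
    rows = []
    for r in results:
        p = r.final_posterior
        rows.append(
            {
                "replicate_id": r.replicate_id,
                "seed": r.seed,
                "stop_reason": r.stop_reason.value,
                "winner": r.winner.value,
                "successes_A": r.counts_A.successes,
                "n_A": r.counts_A.n,
                "successes_B": r.counts_B.successes,
                "n_B": r.counts_B.n,
                "total_n": r.total_n,
                "n_interims": r.n_interims,
                "observed_diff": r.observed_diff,
                "pr_B_gt_A": p.pr_B_gt_A,
                "pr_A_gt_B": p.pr_A_gt_B,
                "pr_within_delta": p.pr_within_delta,
                "mean_p_A": p.mean_p_A,
                "mean_p_B": p.mean_p_B,
                "mean_diff": p.mean_diff,
                "cri_lower": p.cri_lower,
                "cri_upper": p.cri_upper,
                "n_draws": p.n_draws,
                "both_rules_met": r.both_rules_met,
            }
        )
    return pd.DataFrame(rows)
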