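"""Fixed-size RCT comparator: adoption of the superior arm by point estimate.

The comparator enrols a fixed total sample split 1:1, runs no interim
analyses and uses no prior: at the end the arm with the higher observed
success proportion is adopted regardless of statistical significance, and
exact ties are split by a fair coin.  Its single output is the fraction of
replicates adopting the truly superior arm, for head-to-head comparison
with the adaptive designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ScenarioSpec

__all__ = ["FixedRCTSpec", "simulate_fixed_rct", "fixed_rct_results_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixedRCTSpec:
    """A conventional two-arm RCT with a fixed, evenly split total size."""

    total_n: int
    n_reps: int

    def __post_init__(self) -> None:
        if self.total_n < 2 or self.total_n % 2:
            raise ValueError("total_n must be a positive even integer (1:1 split)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")


def _simulate_counts(
    spec: FixedRCTSpec, scenario: ScenarioSpec, master_seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replicate success counts and tie-breaking coin flips."""
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    n_arm = spec.total_n // 2
    xA = rng.binomial(n_arm, scenario.p_A_true, size=spec.n_reps)
    xB = rng.binomial(n_arm, scenario.p_B_true, size=spec.n_reps)
    coins = rng.random(spec.n_reps) < 0.5  # True -> tie resolved toward arm B
    return xA, xB, coins


def simulate_fixed_rct(spec: FixedRCTSpec, scenario: ScenarioSpec, master_seed: int) -> float:
    """Probability of adopting the truly superior arm in a fixed-size RCT."""
    if scenario.delta_true == 0.0:
        raise ValueError("no superior arm exists when Delta_true = 0")
    xA, xB, coins = _simulate_counts(spec, scenario, master_seed)
    ties = xA == xB
    n_ties = int(ties.sum())
    if n_ties:
        logger.debug("%d of %d replicates tied; split by fair coin", n_ties, spec.n_reps)
    b_adopted = np.where(ties, coins, xB > xA)
    correct = b_adopted if scenario.delta_true > 0 else ~b_adopted
    return float(correct.mean())


def fixed_rct_results_frame(
    spec: FixedRCTSpec, scenario: ScenarioSpec, master_seed: int
) -> pd.DataFrame:
    """Trial-level table in the adaptive results schema (stop_reason 'fixed_n')."""
    xA, xB, coins = _simulate_counts(spec, scenario, master_seed)
    n_arm = spec.total_n // 2
    ties = xA == xB
    b_adopted = np.where(ties, coins, xB > xA)
    return pd.DataFrame(
        {
            "replicate_id": np.arange(spec.n_reps),
            "seed": master_seed,
            "stop_reason": "fixed_n",
            "winner": np.where(b_adopted, "B", "A"),
            "successes_A": xA,
            "n_A": n_arm,
            "successes_B": xB,
            "n_B": n_arm,
            "total_n": spec.total_n,
            "n_interims": 0,
            "observed_diff": xB / n_arm - xA / n_arm,
        }
    )
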