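"""Outcome classification and operating characteristics.

Each finished trial is judged against the truth of its scenario.  With the
indifference half-width ``delta`` (1 percentage point by default), the arms
"perform equally" when |Delta_true| < delta and one arm is truly superior
otherwise.  The six-way taxonomy:

===================  ====================  ==========================
truth                 trial stopped for     class
===================  ====================  ==========================
|Delta_true| < delta  equivalence           true_equivalence
|Delta_true| < delta  efficacy              partial_efficacy
|Delta_true| >= delta efficacy, sup. arm    true_efficacy
|Delta_true| >= delta efficacy, inf. arm    false_efficacy
|Delta_true| >= delta equivalence           spurious_equivalence
any                   cap reached           inconclusive
===================  ====================  ==========================

``partial_efficacy`` plays the role of a type-I error and
``false_efficacy`` + ``spurious_equivalence`` together resemble a type-II
error, but the classes are kept separate because their programmatic
consequences differ: false efficacy adopts the inferior variant, spurious
equivalence merely leaves the choice to a coin that might still land well.

Aggregation over replicates yields class rates with Monte Carlo standard
errors, the distribution of final sample sizes, frequentist coverage of the
final 95% credible interval, mean bias of the effect estimate (with the
prior, via the posterior mean, or without it, via raw proportions), and the
probability that the truly superior arm would be adopted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .design import ScenarioSpec
from .trial import StopReason, TrialResult, Winner

__all__ = [
    "OutcomeClass",
    "OCReport",
    "classify_outcome",
    "operating_characteristics",
    "coverage",
    "bias_summary",
    "adoption_probability",
    "mc_error",
]


class OutcomeClass(str, Enum):
    TRUE_EQUIVALENCE = "true_equivalence"
    PARTIAL_EFFICACY = "partial_efficacy"
    TRUE_EFFICACY = "true_efficacy"
    FALSE_EFFICACY = "false_efficacy"
    SPURIOUS_EQUIVALENCE = "spurious_equivalence"
    INCONCLUSIVE = "inconclusive"


def classify_outcome(result: TrialResult, scenario: ScenarioSpec, delta: float) -> OutcomeClass:
    """Classify one trial result against the scenario truth (see module docs).

    The boundary convention is strict: |Delta_true| < delta counts as
    "perform equally", |Delta_true| >= delta as a real difference.
    """
    if result.stop_reason is StopReason.MAX_N:
        return OutcomeClass.INCONCLUSIVE
    d_true = scenario.delta_true
    if abs(d_true) < delta:
        if result.stop_reason is StopReason.EQUIVALENCE:
            return OutcomeClass.TRUE_EQUIVALENCE
        return OutcomeClass.PARTIAL_EFFICACY
    if result.stop_reason is StopReason.EQUIVALENCE:
        return OutcomeClass.SPURIOUS_EQUIVALENCE
    superior = Winner.B if d_true > 0 else Winner.A
    return OutcomeClass.TRUE_EFFICACY if result.winner is superior else OutcomeClass.FALSE_EFFICACY


def mc_error(p: float, n: int) -> float:
    """Binomial Monte Carlo standard error sqrt(p(1-p)/n) of a simulated rate."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    return math.sqrt(p * (1.0 - p) / n)


def coverage(results: list[TrialResult], scenario: ScenarioSpec) -> float:
    """Fraction of trials whose final credible interval contains Delta_true."""
    if not results:
        raise ValueError("coverage requires at least one result")
    d = scenario.delta_true
    hits = sum(
        1 for r in results if r.final_posterior.cri_lower <= d <= r.final_posterior.cri_upper
    )
    return hits / len(results)


def bias_summary(
    results: list[TrialResult],
    scenario: ScenarioSpec,
    mode: str = "with_prior",
) -> tuple[float, pd.DataFrame]:
    """Mean bias of the final effect estimate, plus a view binned by sample size.

    ``with_prior`` uses the posterior mean of Delta (prior included);
    ``observed_only`` uses the raw difference of observed proportions, a
    frequentist-style estimate applied after the same adaptive stopping.
    """
    if not results:
        raise ValueError("bias_summary requires at least one result")
    if mode == "with_prior":
        est = np.array([r.final_posterior.mean_diff for r in results])
    elif mode == "observed_only":
        est = np.array([r.observed_diff for r in results])
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'with_prior' or 'observed_only'")
    bias = est - scenario.delta_true
    sizes = np.array([r.total_n for r in results])
    frame = pd.DataFrame({"total_n": sizes, "bias": bias})
    n_bins = min(4, frame["total_n"].nunique())
    frame["size_bin"] = pd.qcut(frame["total_n"], q=n_bins, duplicates="drop")
    by_size = (
        frame.groupby("size_bin", observed=True)["bias"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_bias", "count": "n_trials"})
    )
    return float(bias.mean()), by_size


def _adopted_superior(r: TrialResult, superior: Winner, mode: str) -> float:
    """1 if the adopted arm is the truly superior one, 0.5 on an exact tie."""
    if mode == "bayes":
        a, b = r.final_posterior.mean_p_A, r.final_posterior.mean_p_B
    elif mode == "observed":
        a = r.counts_A.successes / r.counts_A.n
        b = r.counts_B.successes / r.counts_B.n
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'bayes' or 'observed'")
    if a == b:
        return 0.5  # tie: either arm equally likely to be implemented
    adopted = Winner.B if b > a else Winner.A
    return 1.0 if adopted is superior else 0.0


def adoption_probability(
    results: list[TrialResult], scenario: ScenarioSpec, mode: str = "bayes"
) -> float:
    """Probability that the truly superior arm is the one implemented.

    Every trial adopts an arm — equivalence and inconclusive trials included
    — by the final posterior means (``bayes``) or the final observed
    proportions (``observed``).  Undefined when the scenario has no superior
    arm.
    """
    if not results:
        raise ValueError("adoption_probability requires at least one result")
    d = scenario.delta_true
    if d == 0.0:
        raise ValueError("adoption probability is undefined when Delta_true = 0")
    superior = Winner.B if d > 0 else Winner.A
    return sum(_adopted_superior(r, superior, mode) for r in results) / len(results)


@dataclass(frozen=True)
class OCReport:
    """Aggregated operating characteristics of one (design, scenario) cell."""

    rates: dict[str, float]
    mc_error_per_rate: dict[str, float]
    n_reps: int
    sample_size_median: float
    sample_size_q1: float
    sample_size_q3: float
    sample_size_min: int
    sample_size_max: int
    coverage: float
    mean_bias_with_prior: float
    mean_bias_observed: float
    adoption_correct_bayes: float | None
    adoption_correct_observed: float | None
    both_rules_met_count: int = 0

    def to_row(self) -> dict[str, float]:
        """Flatten to a single mapping suitable for a CSV row."""
        row: dict[str, float] = {f"rate_{k}": v for k, v in self.rates.items()}
        row.update({f"mc_error_{k}": v for k, v in self.mc_error_per_rate.items()})
        row.update(
            n_reps=self.n_reps,
            sample_size_median=self.sample_size_median,
            sample_size_q1=self.sample_size_q1,
            sample_size_q3=self.sample_size_q3,
            sample_size_min=self.sample_size_min,
            sample_size_max=self.sample_size_max,
            coverage=self.coverage,
            mean_bias_with_prior=self.mean_bias_with_prior,
            mean_bias_observed=self.mean_bias_observed,
            adoption_correct_bayes=self.adoption_correct_bayes,
            adoption_correct_observed=self.adoption_correct_observed,
            both_rules_met_count=self.both_rules_met_count,
        )
        return row


def operating_characteristics(
    results: list[TrialResult], scenario: ScenarioSpec, delta: float
) -> OCReport:
    """Classify and aggregate a replicate collection into an OCReport."""
    if not results:
        raise ValueError("operating_characteristics requires at least one result")
    n = len(results)
    counts = {cls.value: 0 for cls in OutcomeClass}
    for r in results:
        counts[classify_outcome(r, scenario, delta).value] += 1
    rates = {k: v / n for k, v in counts.items()}
    errors = {k: mc_error(v, n) for k, v in rates.items()}
    sizes = np.array([r.total_n for r in results])
    bias_prior, _ = bias_summary(results, scenario, "with_prior")
    bias_obs, _ = bias_summary(results, scenario, "observed_only")
    has_superior = scenario.delta_true != 0.0
    return OCReport(
        rates=rates,
        mc_error_per_rate=errors,
        n_reps=n,
        sample_size_median=float(np.median(sizes)),
        sample_size_q1=float(np.quantile(sizes, 0.25)),
        sample_size_q3=float(np.quantile(sizes, 0.75)),
        sample_size_min=int(sizes.min()),
        sample_size_max=int(sizes.max()),
        coverage=coverage(results, scenario),
        mean_bias_with_prior=bias_prior,
        mean_bias_observed=bias_obs,
        adoption_correct_bayes=(
            adoption_probability(results, scenario, "bayes") if has_superior else None
        ),
        adoption_correct_observed=(
            adoption_probability(results, scenario, "observed") if has_superior else None
        ),
        both_rules_met_count=sum(1 for r in results if r.both_rules_met),
    )
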