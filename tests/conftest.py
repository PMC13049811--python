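"""Shared fixtures: named priors, a dense 2-D quadrature oracle for the
posterior, and a builder for hand-crafted trial results."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from adaptrial.design import PriorSet, prior_by_label
from adaptrial.posterior import ArmCounts, PosteriorSummary, _laplace_fit
from adaptrial.trial import StopReason, TrialResult, Winner


@pytest.fixture(scope="session")
def priors() -> dict[str, PriorSet]:
    return {
        name: prior_by_label(name)
        for name in ("neutral", "moderate_sceptical", "extreme_sceptical")
    }


def posterior_quadrature(
    xA: int, nA: int, xB: int, nB: int, prior: PriorSet,
    delta: float = 0.01, ngrid: int = 601, nbeta: int = 6001, span: float = 8.0,
) -> dict[str, float]:
    """Independent oracle: dense 2-D grid integration of the unnormalised
    posterior of (logit(p_A), log(OR)).  Only the Laplace *location/scale*
    is borrowed to place the grid; all probabilities come from the exact
    (unnormalised) density itself.  The log-OR axis is much finer than the
    baseline axis because the indifference band |Delta| < delta is a thin
    ribbon in that direction."""
    th0, be0, l11, l21, l22 = _laplace_fit(xA, nA, xB, nB, prior)
    sd_t, sd_b = l11, float(np.hypot(l21, l22))
    th = np.linspace(th0 - span * sd_t, th0 + span * sd_t, ngrid)
    be = np.linspace(be0 - span * sd_b, be0 + span * sd_b, nbeta)
    T, B = np.meshgrid(th, be, indexing="ij")
    pa, pb = expit(T), expit(T + B)
    lp = (
        xA * np.log(pa) + (nA - xA) * np.log1p(-pa)
        + xB * np.log(pb) + (nB - xB) * np.log1p(-pb)
        - 0.5 * (T - prior.logit_pA_mean) ** 2 / prior.logit_pA_sd**2
        - 0.5 * (B - prior.logOR_mean) ** 2 / prior.logOR_sd**2
    )
    w = np.exp(lp - lp.max())
    w /= w.sum()
    d = pb - pa
    return {
        # grid lines falling exactly on d == 0 (symmetric counts) get half weight
        "pr_B_gt_A": float((w * (d > 0)).sum() + 0.5 * (w * (d == 0)).sum()),
        "pr_within_delta": float((w * (np.abs(d) < delta)).sum()),
        "mean_p_A": float((w * pa).sum()),
        "mean_p_B": float((w * pb).sum()),
        "mean_diff": float((w * d).sum()),
    }


@pytest.fixture(scope="session")
def quad_oracle():
    return posterior_quadrature


def make_result(
    stop: StopReason,
    winner: Winner,
    total_n: int = 1000,
    mean_diff: float = 0.0,
    cri: tuple[float, float] = (-0.05, 0.05),
    mean_p_A: float = 0.5,
    mean_p_B: float = 0.5,
    observed_diff: float = 0.0,
    replicate_id: int = 0,
) -> TrialResult:
    """Hand-built trial result for taxonomy/aggregation tests."""
    n_arm = total_n // 2
    pr_b = 0.5 + np.sign(mean_diff) * 0.4
    summary = PosteriorSummary(
        pr_B_gt_A=pr_b,
        pr_A_gt_B=1.0 - pr_b,
        pr_within_delta=0.5,
        mean_p_A=mean_p_A,
        mean_p_B=mean_p_B,
        mean_diff=mean_diff,
        cri_lower=cri[0],
        cri_upper=cri[1],
        n_draws=10_000,
    )
    sA = n_arm // 2
    sB = min(n_arm, sA + round(observed_diff * n_arm))
    return TrialResult(
        stop_reason=stop,
        winner=winner,
        counts_A=ArmCounts(sA, n_arm),
        counts_B=ArmCounts(sB, n_arm),
        total_n=total_n,
        n_interims=max(1, total_n // 100),
        final_posterior=summary,
        observed_diff=observed_diff,
        replicate_id=replicate_id,
        seed=replicate_id,
    )


@pytest.fixture
def result_builder():
    return make_result
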