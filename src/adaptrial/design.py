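"""Declarative trial designs, scenarios, and priors.

A two-arm adaptive trial for a binary endpoint is described here by three
immutable specifications:

* :class:`PriorSet` — independent normal priors on ``logit(p_A)`` (the
  baseline log-odds of success) and on ``log(OR)`` (the log odds ratio of
  arm B versus arm A).  These are the model's only free beliefs; the arm-B
  success probability is always derived as a function of the two parameters
  and never receives its own prior.
* :class:`ScenarioSpec` — the true success probabilities used to generate
  outcome data in simulation.
* :class:`DesignSpec` — the interim-analysis schedule (first look and batch
  size per arm), the posterior-probability thresholds ``S`` (efficacy) and
  ``E`` (equivalence), the half-width of the indifference zone on the
  risk-difference scale, and the total sample-size cap.

Three named priors are provided.  The *neutral* prior places a 95% credible
interval of [1/30, 30] on the odds ratio, wide enough that the posterior is
driven by the data.  The *sceptical* priors concentrate the odds ratio near
1 — ``moderate_sceptical`` (95% CI 0.82–1.22, i.e. an absolute difference
unlikely to exceed ~5 points at a 50% baseline) and ``extreme_sceptical``
(0.92–1.08, ~2 points) — encoding the belief that low-risk programmatic
changes yield modest improvements.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml
from scipy.stats import norm

__all__ = [
    "PriorSet",
    "ScenarioSpec",
    "DesignSpec",
    "make_logit_pA_prior",
    "make_neutral_prior",
    "make_sceptical_prior",
    "prior_by_label",
    "or_to_risk",
    "design_preset",
    "reference_design",
    "paper_scenarios",
    "design_to_dict",
    "design_from_dict",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_config",
    "save_config",
]

# Precision of the normal prior on logit(p_A).  A uniform(0,1) prior on p_A
# maps to a logistic distribution on the logit scale with variance pi^2/3
# ~ 3.29, i.e. precision ~ 0.304; the prior is stated as precision 0.3.
_LOGIT_PA_PRECISION = 0.3

#: Odds-ratio 95%-interval upper bounds of the named priors.
_NEUTRAL_OR_UPPER = 30.0
_MODERATE_OR_UPPER = 1.22
_EXTREME_OR_UPPER = 1.08


def _z(level: float) -> float:
    """Two-sided standard-normal quantile for a central credible level."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"credible level must be in (0,1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class PriorSet:
    """Normal priors on logit(p_A) and log(OR)."""

    logit_pA_mean: float
    logit_pA_sd: float
    logOR_mean: float
    logOR_sd: float
    label: str

    def __post_init__(self) -> None:
        for name in ("logit_pA_sd", "logOR_sd"):
            sd = getattr(self, name)
            if not (math.isfinite(sd) and sd > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {sd}")
        for name in ("logit_pA_mean", "logOR_mean"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.label:
            raise ValueError("prior label must be nonempty")

    def or_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval of the prior on the odds-ratio scale."""
        half = _z(level) * self.logOR_sd
        return (math.exp(self.logOR_mean - half), math.exp(self.logOR_mean + half))


def make_logit_pA_prior() -> tuple[float, float]:
    """Mean and sd of the baseline prior: logit(p_A) ~ N(0, precision 0.3).

    The sd is ``1/sqrt(0.3) ~ 1.826``; the implied distribution approximates
    the logit transform of a uniform(0,1) prior on p_A (variance pi^2/3).
    """
    return 0.0, 1.0 / math.sqrt(_LOGIT_PA_PRECISION)


def make_neutral_prior(level: float = 0.95) -> PriorSet:
    """Neutral prior: OR centred at 1 with central interval [1/30, 30]."""
    mean, sd = make_logit_pA_prior()
    return PriorSet(
        logit_pA_mean=mean,
        logit_pA_sd=sd,
        logOR_mean=0.0,
        logOR_sd=math.log(_NEUTRAL_OR_UPPER) / _z(level),
        label="neutral",
    )


def make_sceptical_prior(or_upper: float, label: str, level: float = 0.95) -> PriorSet:
    """Sceptical prior on log(OR): centred at 0 with upper OR bound `or_upper`.

    Parameters
    ----------
    or_upper
        Upper endpoint of the central credible interval on the OR scale;
        must exceed 1 (the interval is symmetric on the log scale, so the
        lower endpoint is ``1/or_upper``).
    label
        Human-readable identifier stored on the prior.
    level
        Credible level of the interval, default 0.95.
    """
    if not or_upper > 1.0:
        raise ValueError(f"or_upper must exceed 1, got {or_upper}")
    mean, sd = make_logit_pA_prior()
    return PriorSet(
        logit_pA_mean=mean,
        logit_pA_sd=sd,
        logOR_mean=0.0,
        logOR_sd=math.log(or_upper) / _z(level),
        label=label,
    )


def prior_by_label(label: str, level: float = 0.95) -> PriorSet:
    """Construct one of the named priors: neutral, moderate_sceptical, extreme_sceptical."""
    if label == "neutral":
        return make_neutral_prior(level)
    if label == "moderate_sceptical":
        return make_sceptical_prior(_MODERATE_OR_UPPER, "moderate_sceptical", level)
    if label == "extreme_sceptical":
        return make_sceptical_prior(_EXTREME_OR_UPPER, "extreme_sceptical", level)
    raise ValueError(
        f"unknown prior label {label!r}; expected one of "
        "'neutral', 'moderate_sceptical', 'extreme_sceptical'"
    )


def or_to_risk(p_A: float, odds_ratio: float) -> float:
    """Arm-B success probability implied by a baseline risk and an odds ratio.

    ``p_B = OR * odds_A / (1 + OR * odds_A)`` with ``odds_A = p_A / (1 - p_A)``.
    """
    if not 0.0 < p_A < 1.0:
        raise ValueError(f"p_A must be in (0,1), got {p_A}")
    if not odds_ratio > 0.0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    odds = odds_ratio * p_A / (1.0 - p_A)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class ScenarioSpec:
    """True per-arm success probabilities of a data-generating scenario."""

    p_A_true: float
    p_B_true: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("p_A_true", "p_B_true"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {p}")
        if not self.label:
            object.__setattr__(
                self, "label", f"dA{self.p_A_true:g}_dB{self.p_B_true:g}"
            )

    @property
    def delta_true(self) -> float:
        """True risk difference p_B − p_A."""
        return self.p_B_true - self.p_A_true


def paper_scenarios(p_A: float = 0.50) -> list[ScenarioSpec]:
    """The six study scenarios: absolute effect differences 0–5% at a 50% baseline."""
    return [
        ScenarioSpec(p_A, round(p_A + d / 100.0, 10), label=f"delta_{d}pct")
        for d in range(6)
    ]


@dataclass(frozen=True)
class DesignSpec:
    """An adaptive two-arm design: schedule, stopping thresholds, prior, cap."""

    first_look_per_arm: int
    batch_per_arm: int
    efficacy_threshold_S: float
    equivalence_threshold_E: float
    indifference_halfwidth: float
    max_total_n: int
    priors: PriorSet
    posterior_draws: int = 10_000
    mc_efficiency: float = 0.4
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.first_look_per_arm < 1:
            raise ValueError("first_look_per_arm must be a positive integer")
        if self.batch_per_arm < 1:
            raise ValueError("batch_per_arm must be a positive integer")
        if self.posterior_draws < 1:
            raise ValueError("posterior_draws must be a positive integer")
        if self.max_total_n < 2 or self.max_total_n % 2:
            raise ValueError("max_total_n must be a positive even integer (1:1 allocation)")
        if 2 * self.first_look_per_arm > self.max_total_n:
            raise ValueError("first look must fit inside max_total_n")
        for name in ("efficacy_threshold_S", "equivalence_threshold_E"):
            t = getattr(self, name)
            if not (0.5 < t <= 1.0):
                raise ValueError(f"{name} must lie in (0.5, 1.0], got {t}")
        if not self.indifference_halfwidth > 0:
            raise ValueError("indifference_halfwidth must be positive")
        if not 0.0 < self.mc_efficiency <= 1.0:
            raise ValueError("mc_efficiency must lie in (0, 1]")

    @property
    def decision_draws(self) -> int:
        """Effective number of independent draws behind each interim decision.

        ``posterior_draws`` counts Monte-Carlo iterations per analysis;
        ``mc_efficiency`` is the fraction of them that are effectively
        independent.  The default 0.4 emulates a 10,000-iteration Gibbs
        analysis of this model, whose autocorrelation leaves an effective
        sample size of roughly 4,000 (measured); set it to 1.0 for fully
        independent draws.
        """
        return max(100, round(self.posterior_draws * self.mc_efficiency))

    def replace(self, **changes: Any) -> "DesignSpec":
        """A copy of this design with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def reference_design(max_total_n: int = 100_000) -> DesignSpec:
    """The reference design: neutral prior, first look and batches of 50/arm,
    S = 95%, E = 95%, ±1% indifference zone, cap 100,000."""
    return DesignSpec(
        first_look_per_arm=50,
        batch_per_arm=50,
        efficacy_threshold_S=0.95,
        equivalence_threshold_E=0.95,
        indifference_halfwidth=0.01,
        max_total_n=max_total_n,
        priors=make_neutral_prior(),
        label="reference",
    )


# Candidate designs: schedules are stored per arm (a first look of 100
# across both arms is 50 per arm).  All candidates share the reference
# schedule and S = 95%; they vary the prior and relax E to 80%.
_PRESET_TABLE: dict[str, tuple[str, float]] = {
    "reference": ("neutral", 0.95),
    "I": ("neutral", 0.80),
    "II": ("moderate_sceptical", 0.80),
    "III": ("extreme_sceptical", 0.80),
}


def design_preset(name: str, max_total_n: int = 100_000) -> DesignSpec:
    """Named candidate designs: 'reference', 'I', 'II', 'III'."""
    if name not in _PRESET_TABLE:
        raise ValueError(
            f"unknown design preset {name!r}; expected one of {sorted(_PRESET_TABLE)}"
        )
    prior_label, E = _PRESET_TABLE[name]
    return reference_design(max_total_n).replace(
        priors=prior_by_label(prior_label),
        equivalence_threshold_E=E,
        label=name,
    )


# ---------------------------------------------------------------------------
# Flat config (YAML/JSON) serialisation


def _prior_to_config(p: PriorSet) -> Any:
    try:
        if p == prior_by_label(p.label):
            return p.label
    except ValueError:
        pass
    return {
        "logit_pA_mean": p.logit_pA_mean,
        "logit_pA_sd": p.logit_pA_sd,
        "logOR_mean": p.logOR_mean,
        "logOR_sd": p.logOR_sd,
        "label": p.label,
    }


def _prior_from_config(cfg: Any) -> PriorSet:
    if isinstance(cfg, str):
        return prior_by_label(cfg)
    if isinstance(cfg, Mapping):
        return PriorSet(**cfg)
    raise ValueError(f"prior config must be a label or mapping, got {cfg!r}")


def design_to_dict(design: DesignSpec) -> dict[str, Any]:
    """Flat-config mapping for a design (inverse of :func:`design_from_dict`)."""
    return {
        "first_look_per_arm": design.first_look_per_arm,
        "batch_per_arm": design.batch_per_arm,
        "S": design.efficacy_threshold_S,
        "E": design.equivalence_threshold_E,
        "delta": design.indifference_halfwidth,
        "max_total_n": design.max_total_n,
        "prior": _prior_to_config(design.priors),
        "posterior_draws": design.posterior_draws,
        "mc_efficiency": design.mc_efficiency,
        "label": design.label,
    }


def design_from_dict(cfg: Mapping[str, Any]) -> DesignSpec:
    """Build a design from the flat config mapping.

    Required keys: ``first_look_per_arm, batch_per_arm, S, E, delta,
    max_total_n, prior``; optional: ``posterior_draws, label``.  A bare
    string is accepted and resolved as a preset name.
    """
    required = {"first_look_per_arm", "batch_per_arm", "S", "E", "delta", "max_total_n", "prior"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"design config missing keys: {sorted(missing)}")
    return DesignSpec(
        first_look_per_arm=int(cfg["first_look_per_arm"]),
        batch_per_arm=int(cfg["batch_per_arm"]),
        efficacy_threshold_S=float(cfg["S"]),
        equivalence_threshold_E=float(cfg["E"]),
        indifference_halfwidth=float(cfg["delta"]),
        max_total_n=int(cfg["max_total_n"]),
        priors=_prior_from_config(cfg["prior"]),
        posterior_draws=int(cfg.get("posterior_draws", 10_000)),
        mc_efficiency=float(cfg.get("mc_efficiency", 0.4)),
        label=str(cfg.get("label", "custom")),
    )


def scenario_to_dict(s: ScenarioSpec) -> dict[str, Any]:
    return {"p_A": s.p_A_true, "p_B": s.p_B_true, "label": s.label}


def scenario_from_dict(cfg: Mapping[str, Any]) -> ScenarioSpec:
    if not {"p_A", "p_B"} <= set(cfg):
        raise ValueError("scenario config requires keys 'p_A' and 'p_B'")
    return ScenarioSpec(float(cfg["p_A"]), float(cfg["p_B"]), str(cfg.get("label", "")))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON config with optional 'design' and 'scenario' sections.

    Returns a dict with parsed ``DesignSpec``/``ScenarioSpec`` under the same
    keys; unknown top-level keys are passed through untouched.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML superset also parses JSON
    if not isinstance(raw, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    out: dict[str, Any] = dict(raw)
    if "design" in raw:
        d = raw["design"]
        out["design"] = design_preset(d) if isinstance(d, str) else design_from_dict(d)
    if "scenario" in raw:
        out["scenario"] = scenario_from_dict(raw["scenario"])
    return out


def save_config(design: DesignSpec, scenario: ScenarioSpec, path: str | Path) -> None:
    """Write a design + scenario pair as a flat YAML (or JSON) config."""
    payload = {"design": design_to_dict(design), "scenario": scenario_to_dict(scenario)}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
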