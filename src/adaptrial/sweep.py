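"""Scenario-grid sweeps and reporting.

``run_sweep`` executes every (design, scenario) combination of a
:class:`SweepSpec`, writing one trial-level CSV per combination, a single
aggregated operating-characteristics CSV, and a JSON manifest recording the
master seed, per-combination seeds, package version and wall-clock time.
Given the same spec and master seed, the trial-level CSVs are
byte-identical across runs.

``report`` turns a completed sweep directory into a per-design summary
table (winner rates, equivalence/inconclusive rates, median [IQR] and range
of final sample sizes) and generic stacked-bar / point-range plots.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .design import DesignSpec, ScenarioSpec, design_to_dict, scenario_to_dict
from .outcomes import operating_characteristics
from .trial import results_to_frame, run_replicates

__all__ = ["SweepSpec", "run_sweep", "report"]

logger = logging.getLogger(__name__)

OC_FILENAME = "operating_characteristics.csv"
MANIFEST_FILENAME = "manifest.json"


@dataclass(frozen=True)
class SweepSpec:
    """A grid of designs x scenarios to simulate."""

    designs: list[DesignSpec]
    scenarios: list[ScenarioSpec]
    n_reps: int
    master_seed: int
    output_dir: Path
    backend: str = "approx"

    def __post_init__(self) -> None:
        if not self.designs or not self.scenarios:
            raise ValueError("sweep needs at least one design and one scenario")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        object.__setattr__(self, "output_dir", Path(self.output_dir))


def _combo_seed(master_seed: int, design_idx: int, scenario_idx: int) -> int:
    """Per-combination master seed; replicate seeds derive from it in turn."""
    import numpy as np

    ss = np.random.SeedSequence((master_seed, design_idx, scenario_idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep, write results under ``spec.output_dir``, return the OC table."""
    out = spec.output_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    oc_rows = []
    manifest_combos = []
    for di, design in enumerate(spec.designs):
        for si, scenario in enumerate(spec.scenarios):
            seed = _combo_seed(spec.master_seed, di, si)
            results = run_replicates(design, scenario, spec.n_reps, seed, spec.backend)
            name = f"trials_{design.label}_{scenario.label}.csv"
            results_to_frame(results).to_csv(out / name, index=False)
            oc = operating_characteristics(results, scenario, design.indifference_halfwidth)
            row = {"design": design.label, "scenario": scenario.label,
                   "delta_true": scenario.delta_true}
            row.update(oc.to_row())
            oc_rows.append(row)
            manifest_combos.append(
                {"design": design.label, "scenario": scenario.label,
                 "trials_csv": name, "combo_master_seed": seed}
            )
            logger.info(
                "design=%s scenario=%s: median n=%d, rates=%s",
                design.label, scenario.label, int(oc.sample_size_median),
                {k: round(v, 3) for k, v in oc.rates.items() if v},
            )
    oc_frame = pd.DataFrame(oc_rows)
    oc_frame.to_csv(out / OC_FILENAME, index=False)
    manifest = {
        "adaptrial_version": __version__,
        "master_seed": spec.master_seed,
        "n_reps": spec.n_reps,
        "backend": spec.backend,
        "seed_rule": "combo seed = SeedSequence((master_seed, design_idx, scenario_idx))"
                     ".generate_state(1, uint32)[0] >> 1; replicate seed = "
                     "SeedSequence((combo_seed, replicate_id)) likewise",
        "designs": [design_to_dict(d) for d in spec.designs],
        "scenarios": [scenario_to_dict(s) for s in spec.scenarios],
        "combinations": manifest_combos,
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    (out / MANIFEST_FILENAME).write_text(json.dumps(manifest, indent=2))
    return oc_frame


# ---------------------------------------------------------------------------
# Reporting


_CLASS_ORDER = [
    "rate_true_equivalence",
    "rate_partial_efficacy",
    "rate_true_efficacy",
    "rate_false_efficacy",
    "rate_spurious_equivalence",
    "rate_inconclusive",
]


def summary_table(oc: pd.DataFrame) -> pd.DataFrame:
    """Per-(design, scenario) table: winner rates, equivalence, median [IQR], range."""
    table = pd.DataFrame(
        {
            "design": oc["design"],
            "scenario": oc["scenario"],
            "delta_true": oc["delta_true"],
            "winner_A": oc["rate_partial_efficacy"].where(oc["delta_true"].abs() < 1e-12, other=pd.NA),
            "equivalence": oc["rate_true_equivalence"] + oc["rate_spurious_equivalence"],
            "true_efficacy": oc["rate_true_efficacy"],
            "false_efficacy": oc["rate_false_efficacy"],
            "partial_efficacy": oc["rate_partial_efficacy"],
            "inconclusive": oc["rate_inconclusive"],
            "median_iqr": [
                f"{int(m):,} ({int(q1):,}; {int(q3):,})"
                for m, q1, q3 in zip(
                    oc["sample_size_median"], oc["sample_size_q1"], oc["sample_size_q3"]
                )
            ],
            "minimum": oc["sample_size_min"],
            "maximum": oc["sample_size_max"],
        }
    )
    return table.drop(columns=["winner_A"])


def report(results_dir: str | Path, plots: bool = True) -> pd.DataFrame:
    """Summarise a completed sweep directory; returns the summary table.

    Writes ``summary_table.csv`` and, unless ``plots`` is disabled,
    ``outcome_rates.png`` (stacked bars of the outcome classes per scenario,
    one panel per design) and ``sample_sizes.png`` (median with IQR bars).
    """
    results_dir = Path(results_dir)
    oc_path = results_dir / OC_FILENAME
    if not oc_path.exists():
        raise FileNotFoundError(
            f"no completed sweep found: missing {oc_path} (run a sweep first)"
        )
    oc = pd.read_csv(oc_path)
    table = summary_table(oc)
    table.to_csv(results_dir / "summary_table.csv", index=False)
    if plots:
        _plot_outcome_rates(oc, results_dir / "outcome_rates.png")
        _plot_sample_sizes(oc, results_dir / "sample_sizes.png")
    return table


def _plot_outcome_rates(oc: pd.DataFrame, path: Path) -> None:
    designs = oc["design"].unique()
    fig, axes = plt.subplots(
        1, len(designs), figsize=(4 * len(designs), 4), squeeze=False, sharey=True
    )
    for ax, design in zip(axes[0], designs):
        sub = oc[oc["design"] == design].sort_values("delta_true")
        bottom = None
        x = sub["scenario"]
        for col in _CLASS_ORDER:
            ax.bar(x, sub[col], bottom=bottom, label=col.removeprefix("rate_"))
            bottom = sub[col].to_numpy() if bottom is None else bottom + sub[col].to_numpy()
        ax.set_title(f"design {design}")
        ax.set_ylabel("proportion of trials")
        ax.tick_params(axis="x", rotation=45)
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sample_sizes(oc: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for design in oc["design"].unique():
        sub = oc[oc["design"] == design].sort_values("delta_true")
        med = sub["sample_size_median"].to_numpy()
        err = [med - sub["sample_size_q1"].to_numpy(),
               sub["sample_size_q3"].to_numpy() - med]
        ax.errorbar(
            sub["delta_true"].to_numpy() * 100, med, yerr=err,
            marker="o", capsize=3, label=f"design {design}",
        )
    ax.set_xlabel("true effect difference (%)")
    ax.set_ylabel("final total sample size (median, IQR)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
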