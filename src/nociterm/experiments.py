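"""The structural-plasticity experiment matrix.

Runs the 2 x 4 design — {generic, peptidergic} x {control, branching,
elongation, combined} — that asks whether inflammation-style structural
changes of the terminal tree (added Na(v)less branches, elongated endings)
are by themselves sufficient to increase action-potential output at the
central terminal under a capsaicin-like stimulus. Branching adds +100%
(generic) or +200% (peptidergic) de novo branches; elongation takes the
endings from 32 to 46 um (generic) or 26 to 44.6 um (peptidergic).

The headline readout is ordinal: spike counts at the central terminal must
be nondecreasing along control -> single manipulation -> combined, with
combined strictly above control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cable import SimulationResult, detect_spikes, discretize
from .channels import CapsaicinStimulus
from .morphology import build_terminal_tree
from .protocols import ProtocolSpec, run_capsaicin_protocol

__all__ = [
    "ExperimentConfig",
    "ConditionResult",
    "run_condition",
    "run_matrix",
    "firing_pattern_summary",
    "calibrate_drive",
    "CONDITIONS",
    "ELONGATION_TARGET",
    "BRANCH_INCREASE_PCT",
    "ExperimentError",
]

CONDITIONS = ("control", "branching", "elongation", "combined")

#: Elongated ending length per class (um): 32 -> 46 generic, 26 -> 44.6
#: peptidergic.
ELONGATION_TARGET = {"generic": 46.0, "peptidergic": 44.6}

#: De novo branching increase per class (%): +100 generic, +200 peptidergic.
BRANCH_INCREASE_PCT = {"generic": 100.0, "peptidergic": 200.0}


class ExperimentError(ValueError):
    """Invalid class or condition name."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one matrix run."""

    classes: tuple[str, ...] = ("generic", "peptidergic")
    n_endings: int | None = None  # None: class default (14 / 7)
    stimulus: CapsaicinStimulus = field(default_factory=CapsaicinStimulus)
    t_stop: float = 4000.0  # ms after settling
    settle: float = 500.0  # ms
    dt: float = 0.025  # ms
    scale_propagation: bool = True
    spike_threshold: float = 0.0  # mV
    refractory: float = 2.0  # ms


@dataclass
class ConditionResult:
    """Spike statistics for one (class, condition) cell of the matrix."""

    neuron_class: str
    condition: str
    spike_count: int
    spike_times: np.ndarray  # ms
    first_spike_latency: float  # ms from stimulus onset; nan if no spikes
    isi_series: np.ndarray  # ms
    trace_ref: SimulationResult

    def __post_init__(self) -> None:
        assert self.spike_count == self.spike_times.size


def build_condition_tree(
    neuron_class: str, condition: str, config: ExperimentConfig | None = None
):
    """The morphology for one matrix cell."""
    config = config or ExperimentConfig()
    if neuron_class not in ELONGATION_TARGET:
        raise ExperimentError(f"unknown neuron class {neuron_class!r}")
    if condition not in CONDITIONS:
        raise ExperimentError(f"unknown condition {condition!r}")
    branch = BRANCH_INCREASE_PCT[neuron_class] if condition in ("branching", "combined") else 0.0
    elong = ELONGATION_TARGET[neuron_class] if condition in ("elongation", "combined") else None
    return build_terminal_tree(
        neuron_class,
        n_endings=config.n_endings,
        branch_increase_pct=branch,
        elongation_target=elong,
        scale_propagation=config.scale_propagation,
    )


def run_condition(
    neuron_class: str,
    condition: str,
    config: ExperimentConfig | None = None,
) -> ConditionResult:
    """Build, stimulate, and integrate one matrix cell; deterministic."""
    config = config or ExperimentConfig()
    tree = build_condition_tree(neuron_class, condition, config)
    cable = discretize(tree)
    protocol = ProtocolSpec(
        stimulus=config.stimulus, t_stop=config.t_stop, settle=config.settle
    )
    result = run_capsaicin_protocol(cable, protocol, dt=config.dt)
    train = detect_spikes(
        result, "central_terminal", config.spike_threshold, config.refractory
    )
    onset_abs = config.settle + config.stimulus.t_onset
    latency = float(train.times[0] - onset_abs) if train.count else float("nan")
    return ConditionResult(
        neuron_class=neuron_class,
        condition=condition,
        spike_count=train.count,
        spike_times=train.times,
        first_spike_latency=latency,
        isi_series=train.isis,
        trace_ref=result,
    )


def run_matrix(
    config: ExperimentConfig | None = None,
    *,
    output_dir: str | Path | None = None,
    plot: bool = False,
) -> pd.DataFrame:
    """All class x condition cells; returns the summary table.

    With ``output_dir`` set, writes ``fig5_summary.csv``, one voltage-trace
    CSV per cell, and (with ``plot``) rendered trace figures.
    """
    config = config or ExperimentConfig()
    rows = []
    results: list[ConditionResult] = []
    for cls in config.classes:
        for cond in CONDITIONS:
            try:
                r = run_condition(cls, cond, config)
            except Exception as exc:  # noqa: BLE001 - name the failing cell
                raise ExperimentError(f"condition ({cls}, {cond}) failed: {exc}") from exc
            results.append(r)
            pattern = firing_pattern_summary(r)
            rows.append(
                {
                    "neuron_class": cls,
                    "condition": cond,
                    "spike_count": r.spike_count,
                    "first_spike_latency_ms": r.first_spike_latency,
                    "isi_mean_ms": pattern["isi_mean"],
                    "isi_cv": pattern["isi_cv"],
                }
            )
    table = pd.DataFrame(rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "fig5_summary.csv", index=False)
        for r in results:
            trace = pd.DataFrame(
                {"time_ms": r.trace_ref.time, **r.trace_ref.voltages}
            )
            trace.to_csv(out / f"trace_{r.neuron_class}_{r.condition}.csv", index=False)
        if plot:
            _plot_matrix(results, out)
    return table


def firing_pattern_summary(result: ConditionResult, rate_bin_ms: float = 250.0) -> dict:
    """ISI statistics and a binned instantaneous firing-rate trajectory.

    ISI metrics require at least two spikes and are NaN (with
    ``isi_defined=False``) otherwise.
    """
    isis = result.isi_series
    defined = isis.size >= 1
    out = {
        "isi_defined": bool(defined),
        "isi_mean": float(isis.mean()) if defined else float("nan"),
        "isi_cv": float(isis.std() / isis.mean()) if defined and isis.mean() > 0 else (0.0 if defined else float("nan")),
    }
    t = result.trace_ref.time
    edges = np.arange(t[0], t[-1] + rate_bin_ms, rate_bin_ms)
    hist, _ = np.histogram(result.spike_times, bins=edges)
    out["rate_bin_ms"] = rate_bin_ms
    out["rate_hz"] = hist / (rate_bin_ms / 1000.0)
    out["rate_bin_edges_ms"] = edges
    return out


def calibrate_drive(
    neuron_class: str,
    config: ExperimentConfig | None = None,
    *,
    target_band: tuple[int, int] = (3, 10),
    grid: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.35, 0.5, 0.7, 1.0),
) -> float:
    """Find a gate amplitude placing the control spike count in the band.

    Scans ``alpha_max`` over the grid and returns the first value whose
    control-condition count lies inside ``target_band``; raises if none
    does. The shipped default (0.25) was fixed with this procedure.
    """
    config = config or ExperimentConfig()
    for amax in grid:
        cfg = replace(config, stimulus=replace(config.stimulus, alpha_max=amax))
        count = run_condition(neuron_class, "control", cfg).spike_count
        if target_band[0] <= count <= target_band[1]:
            return amax
    raise ExperimentError(
        f"no alpha_max in {grid} yields {target_band} control spikes for {neuron_class}"
    )


def _plot_matrix(results: list[ConditionResult], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted({r.neuron_class for r in results})
    fig, axes = plt.subplots(
        len(classes), 1, figsize=(9, 3 * len(classes)), squeeze=False
    )
    colors = {"control": "k", "branching": "tab:orange", "elongation": "tab:blue", "combined": "tab:green"}
    for ax, cls in zip(axes[:, 0], classes):
        for r in results:
            if r.neuron_class != cls:
                continue
            v = r.trace_ref.voltages["central_terminal"]
            ax.plot(r.trace_ref.time, v, lw=0.6, color=colors[r.condition],
                    label=f"{r.condition} ({r.spike_count} APs)")
        ax.set_title(f"{cls}: central-terminal voltage")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("V (mV)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "fig5_traces.png", dpi=150)
    plt.close(fig)
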