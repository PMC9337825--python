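"""Synthetic inputs for the pipeline: morphometry samples and GCaMP6s traces.

Two generators, both seeded and fully deterministic:

* terminal-fiber morphometry (main-fiber length, branches per fiber) drawn
  from condition-dependent distributions spanning the control vs. inflamed
  ranges, mapped onto buildable terminal-tree specs;
* GCaMP6s-like fluorescence traces with known event times and amplitudes,
  difference-of-exponentials transients, optional baseline drift, white
  noise, and an independent background channel.

The morphometry distribution families and parameters exist to exercise the
pipeline over realistic geometry ranges; they are configuration, not
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium import CaTrace
from .morphology import (
    BASELINE_ENDING_LENGTH,
    TerminalTreeSpec,
    build_terminal_tree,
    validate_tree,
)

__all__ = [
    "MorphometrySample",
    "TraceGroundTruth",
    "sample_morphometry",
    "trees_from_morphometry",
    "generate_ca_trace",
    "transient_peak_value",
    "SyntheticError",
]


class SyntheticError(ValueError):
    """Invalid generator parameters."""


#: default morphometry parameters per condition (generic class scale):
#: log-normal ending length (um) and Poisson branches per fiber
MORPHOMETRY_DEFAULTS = {
    "control": {"length_mean": 32.0, "length_cv": 0.25, "branch_rate": 1.0},
    "inflamed": {"length_mean": 46.0, "length_cv": 0.25, "branch_rate": 2.0},
}


@dataclass(frozen=True)
class MorphometrySample:
    """One measured-fiber emulation: length and branch count."""

    condition: str
    main_fiber_length: float  # um
    branches_per_fiber: int
    seed: int

    def __post_init__(self) -> None:
        if self.main_fiber_length <= 0:
            raise SyntheticError("main_fiber_length must be positive")
        if self.branches_per_fiber < 0:
            raise SyntheticError("branches_per_fiber must be >= 0")


@dataclass(frozen=True)
class TraceGroundTruth:
    """Known content of a generated fluorescence trace."""

    event_times: tuple[float, ...] = ()  # s
    event_amplitudes: tuple[float, ...] = ()  # dF/F0 units
    noise_sigma: float = 0.0  # a.u.
    f0_true: float = 50.0  # a.u.
    rise_tau: float = 0.2  # s (GCaMP6s-like onset)
    decay_tau: float = 1.8  # s (GCaMP6s-like decay)
    drift_amplitude: float = 0.0  # a.u., slow sinusoidal baseline drift

    def __post_init__(self) -> None:
        if len(self.event_times) != len(self.event_amplitudes):
            raise SyntheticError("event times and amplitudes must pair up")
        if any(a < 0 for a in self.event_amplitudes):
            raise SyntheticError("event amplitudes must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= self.rise_tau:
            raise SyntheticError("need 0 < rise_tau < decay_tau")
        if self.noise_sigma < 0:
            raise SyntheticError("noise_sigma must be >= 0")


def sample_morphometry(
    condition: str,
    n: int,
    seed: int,
    params: dict | None = None,
) -> list[MorphometrySample]:
    """Draw ``n`` fiber morphometries for one condition.

    Lengths are log-normal around the condition mean with the given CV;
    branch counts are Poisson with the condition rate. Deterministic per
    seed.
    """
    if condition not in MORPHOMETRY_DEFAULTS:
        raise SyntheticError(f"unknown condition {condition!r}")
    if n < 1:
        raise SyntheticError("n must be >= 1")
    p = dict(MORPHOMETRY_DEFAULTS[condition])
    if params:
        p.update(params)
    if p["length_mean"] <= 0 or p["length_cv"] < 0 or p["branch_rate"] < 0:
        raise SyntheticError("invalid morphometry parameters")
    rng = np.random.default_rng(seed)
    cv = p["length_cv"]
    if cv == 0:
        lengths = np.full(n, p["length_mean"])
    else:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        mu = np.log(p["length_mean"]) - sigma**2 / 2.0
        lengths = rng.lognormal(mu, sigma, size=n)
    branches = rng.poisson(p["branch_rate"], size=n)
    return [
        MorphometrySample(condition, float(l), int(b), seed)
        for l, b in zip(lengths, branches)
    ]


def trees_from_morphometry(
    samples: list[MorphometrySample],
    neuron_class: str = "generic",
    n_endings: int | None = None,
) -> list[TerminalTreeSpec]:
    """Map morphometry samples to valid terminal-tree specs.

    The sampled main-fiber length becomes the tree's free-ending length
    (elongation relative to the class baseline when longer) and the branch
    count becomes the per-ending de novo branching percentage.
    """
    trees = []
    base = BASELINE_ENDING_LENGTH[neuron_class]
    for s in samples:
        pct = 100.0 * s.branches_per_fiber
        if s.main_fiber_length >= base:
            tree = build_terminal_tree(
                neuron_class,
                n_endings=n_endings,
                branch_increase_pct=pct,
                elongation_target=s.main_fiber_length,
            )
        else:
            tree = build_terminal_tree(
                neuron_class,
                n_endings=n_endings,
                branch_increase_pct=pct,
                ending_length=s.main_fiber_length,
            )
        validate_tree(tree)
        trees.append(tree)
    return trees


def _transient(t: np.ndarray, t0: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak."""
    rel = np.clip(t - t0, 0.0, None)
    shape = np.exp(-rel / decay) - np.exp(-rel / rise)
    shape[t < t0] = 0.0
    # analytic peak of exp(-t/d) - exp(-t/r)
    tpk = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    return shape / peak


def transient_peak_value(
    truth: TraceGroundTruth, amplitude: float, smoothing_window: float = 0.0
) -> float:
    """Analytic maximum (dF/F0 units) of one normalized event transient,
    optionally after a centered moving average of the given window (s).

    Uses the closed-form antiderivative of the difference of exponentials;
    the windowed mean is maximized on a fine grid.
    """
    r, d = truth.rise_tau, truth.decay_tau
    tpk = r * d / (d - r) * np.log(d / r)
    norm = np.exp(-tpk / d) - np.exp(-tpk / r)
    if smoothing_window <= 0:
        return amplitude
    w = smoothing_window

    def integral(t):  # int_0^t of the unnormalized shape, zero for t < 0
        t = np.clip(t, 0.0, None)
        return d * (1.0 - np.exp(-t / d)) - r * (1.0 - np.exp(-t / r))

    t = np.linspace(0.0, 10.0 * d, 20000)
    smoothed = (integral(t + w / 2.0) - integral(t - w / 2.0)) / w / norm
    return amplitude * float(smoothed.max())


def generate_ca_trace(
    duration: float,
    frame_rate: float,
    truth: TraceGroundTruth,
    seed: int,
    *,
    stim_onset: float = 12.0,
    stim_end: float = 16.0,
    background_level: float = 10.0,
) -> tuple[CaTrace, TraceGroundTruth]:
    """Synthesize one ROI trace (raw + background) from ground truth.

    The raw channel is background_level + f0_true * (1 + sum of event
    transients in dF/F0 units) plus optional slow drift and white noise;
    the background channel is an independent noisy constant at
    background_level, so after background subtraction the dF/F0 of the
    trace equals the event signal and detection results compare directly
    against truth.
    """
    if duration < 4.0:
        raise SyntheticError("duration must be >= 4 s")
    if frame_rate <= 0:
        raise SyntheticError("frame_rate must be positive")
    for et in truth.event_times:
        if not 0.0 <= et < duration:
            raise SyntheticError(f"event at {et} s lies outside the trace")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    signal = np.zeros(n)
    for et, amp in zip(truth.event_times, truth.event_amplitudes):
        signal += amp * _transient(t, et, truth.rise_tau, truth.decay_tau)
    raw = background_level + truth.f0_true * (1.0 + signal)
    if truth.drift_amplitude:
        raw = raw + truth.drift_amplitude * np.sin(2.0 * np.pi * t / duration)
    raw = raw + rng.normal(0.0, truth.noise_sigma, size=n)
    background = background_level + rng.normal(0.0, truth.noise_sigma / 4.0, size=n)
    trace = CaTrace(
        frame_rate=frame_rate,
        raw=raw,
        background=background,
        stim_onset=stim_onset,
        stim_end=stim_end,
    )
    return trace, truth
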