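"""Fluorescence-trace processing and automated calcium-response detection.

Implements the in vivo GCaMP6s ROI-trace pipeline: background-ROI
subtraction, 1-s moving-average smoothing, dF/F0 with a baseline-clamped
denominator, and threshold-based response detection during a stimulation
window. The detection threshold is F_b + (F_b_max - F_b) * k, where F_b and
F_b_max are the mean and maximum dF/F0 over the pre-stimulus baseline
window and k lies in [2, 3]; suprathreshold excursions shorter than 0.5 s
are rejected (GCaMP6s decays slowly, so briefer events are artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaTrace",
    "DetectionResult",
    "subtract_background",
    "smooth",
    "compute_dff",
    "detect_response",
    "process_trace",
    "summarize_neuron",
    "detect_table",
    "CalciumError",
    "MIN_RESPONSE_DURATION_S",
]

#: suprathreshold runs shorter than this are excluded (s)
MIN_RESPONSE_DURATION_S = 0.5

#: baseline window margins: starts 1 s into the recording, ends 1 s before
#: stimulus onset
BASELINE_START_S = 1.0
BASELINE_MARGIN_S = 1.0

#: F0 values below this are clamped in the dF/F0 denominator (a.u.)
F0_CLAMP = 1.0


class CalciumError(ValueError):
    """Invalid trace geometry or detection window."""


@dataclass
class CaTrace:
    """One ROI fluorescence time series with its background channel."""

    frame_rate: float  # Hz
    raw: np.ndarray  # a.u. per frame
    background: np.ndarray  # background-ROI mean per frame
    stim_onset: float  # s
    stim_end: float  # s

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frame_rate <= 0:
            raise CalciumError("frame_rate must be positive")
        if self.raw.shape != self.background.shape:
            raise CalciumError("raw and background must have equal length")
        if self.stim_onset < 2.0:
            raise CalciumError("stim_onset must be >= 2 s (baseline needs 2 s)")
        if self.stim_end <= self.stim_onset:
            raise CalciumError("stim_end must exceed stim_onset")
        if self.stim_end > self.raw.size / self.frame_rate:
            raise CalciumError("stimulation window extends past the trace")

    @property
    def duration(self) -> float:
        return self.raw.size / self.frame_rate


@dataclass
class DetectionResult:
    """Outcome of response detection on one dF/F0 trace."""

    dff: np.ndarray
    f0: float
    f_b: float
    f_b_max: float
    threshold_multiplier_k: float
    threshold: float
    is_positive: bool
    peak_amplitude: float | None  # dF/F0 units, defined only when positive
    response_duration: float  # s, longest contiguous suprathreshold run


def subtract_background(trace: CaTrace) -> np.ndarray:
    """Elementwise raw minus background-ROI mean."""
    if trace.raw.shape != trace.background.shape:
        raise CalciumError("raw and background must have equal length")
    return trace.raw - trace.background


def smooth(series, window: float = 1.0, frame_rate: float = 32.0) -> np.ndarray:
    """Centered moving average over ``round(window * frame_rate)`` frames.

    Edges are truncated (shorter one-sided windows), so constant series are
    exactly preserved. A window shorter than one frame is the identity.
    """
    if window <= 0:
        raise CalciumError("window must be positive")
    series = np.asarray(series, dtype=float)
    n = int(round(window * frame_rate))
    if n <= 1:
        return series.copy()
    half_lo = (n - 1) // 2
    half_hi = n // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    idx = np.arange(series.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, series.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_dff(series, frame_rate: float) -> tuple[np.ndarray, float]:
    """dF/F0 with F0 = mean of the first 2 s; denominator clamped at 1.

    The numerator always uses the true F0; only the denominator is clamped,
    which prevents aberrant amplification for dim neurons.
    """
    series = np.asarray(series, dtype=float)
    n0 = int(round(2.0 * frame_rate))
    if series.size < n0:
        raise CalciumError("trace must be at least 2 s long to define F0")
    f0 = float(series[:n0].mean())
    dff = (series - f0) / max(f0, F0_CLAMP)
    return dff, f0


def detect_response(
    dff,
    frame_rate: float,
    stim_onset: float,
    stim_end: float,
    k: float = 2.5,
    *,
    f0: float = np.nan,
) -> DetectionResult:
    """Classify a dF/F0 trace as responding or not during the stimulus window.

    The baseline spans [1 s, stim_onset - 1 s]. A response is positive when
    the dF/F0 peak inside [stim_onset, stim_end] exceeds
    f_b + (f_b_max - f_b) * k and stays above it contiguously for at least
    0.5 s.
    """
    if not 2.0 <= k <= 3.0:
        raise CalciumError("threshold multiplier k must lie in [2, 3]")
    dff = np.asarray(dff, dtype=float)
    b0 = int(round(BASELINE_START_S * frame_rate))
    b1 = int(round((stim_onset - BASELINE_MARGIN_S) * frame_rate))
    if b1 <= b0:
        raise CalciumError("baseline window is empty")
    base = dff[b0:b1]
    f_b = float(base.mean())
    f_b_max = float(base.max())
    threshold = f_b + (f_b_max - f_b) * k

    s0 = int(round(stim_onset * frame_rate))
    s1 = min(int(round(stim_end * frame_rate)) + 1, dff.size)
    win = dff[s0:s1]
    above = win > threshold
    # longest contiguous suprathreshold run
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    duration = best / frame_rate
    positive = bool(win.size and win.max() > threshold and duration >= MIN_RESPONSE_DURATION_S)
    peak = float(win.max()) if positive else None
    return DetectionResult(
        dff=dff,
        f0=f0,
        f_b=f_b,
        f_b_max=f_b_max,
        threshold_multiplier_k=k,
        threshold=threshold,
        is_positive=positive,
        peak_amplitude=peak,
        response_duration=duration,
    )


def process_trace(trace: CaTrace, k: float = 2.5, smooth_window: float = 1.0) -> DetectionResult:
    """Full pipeline: background subtraction, smoothing, dF/F0, detection."""
    corrected = subtract_background(trace)
    smoothed = smooth(corrected, smooth_window, trace.frame_rate)
    dff, f0 = compute_dff(smoothed, trace.frame_rate)
    return detect_response(
        dff, trace.frame_rate, trace.stim_onset, trace.stim_end, k, f0=f0
    )


def summarize_neuron(results: list[DetectionResult]) -> dict:
    """Per-neuron summary over repeated trials.

    Mean peak amplitude over positive trials (NaN when none) and the
    fraction of positive trials.
    """
    if not results:
        raise CalciumError("at least one trial is required")
    peaks = [r.peak_amplitude for r in results if r.is_positive]
    return {
        "n_trials": len(results),
        "n_positive": len(peaks),
        "fraction_positive": len(peaks) / len(results),
        "mean_peak_amplitude": float(np.mean(peaks)) if peaks else float("nan"),
    }


def detect_table(
    df: pd.DataFrame,
    frame_rate: float,
    stim_onset: float,
    stim_end: float,
    k: float = 2.5,
    *,
    background_column: str = "background",
) -> pd.DataFrame:
    """Run the pipeline on a columnar trace table.

    ``df`` holds one column per ROI plus a background column (a ``time_s``
    column is ignored). Returns one row per ROI with detection fields.
    """
    if background_column not in df.columns:
        raise CalciumError(f"missing background column {background_column!r}")
    rows = []
    for col in df.columns:
        if col in (background_column, "time_s"):
            continue
        trace = CaTrace(
            frame_rate=frame_rate,
            raw=df[col].to_numpy(),
            background=df[background_column].to_numpy(),
            stim_onset=stim_onset,
            stim_end=stim_end,
        )
        r = process_trace(trace, k=k)
        rows.append(
            {
                "roi": col,
                "positive": r.is_positive,
                "peak": r.peak_amplitude if r.is_positive else np.nan,
                "duration_s": r.response_duration,
                "f_b": r.f_b,
                "f_b_max": r.f_b_max,
                "threshold": r.threshold,
                "f0": r.f0,
            }
        )
    return pd.DataFrame(rows)
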