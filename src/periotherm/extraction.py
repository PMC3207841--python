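"""Mean-temperature series extraction from a tracked region.

Per frame, the region's temperature is summarised by the upper-50% trimmed
mean — the mean of the warmest half of the pixels — which is robust to the
cool border pixels that enter and leave the box as the tracked position
wanders by a few pixels.  The per-trial series is then low-pass filtered
with a causal second-order Butterworth at 2 Hz (filter state initialised to
the steady state of the first sample to suppress the startup transient),
and 2-second pre/post-stimulus windows are cut around the stimulus time.

At the study rate of 15 Hz a 2 s window holds 31 samples (both endpoints
inclusive; the sample at the stimulus instant lies on the boundary of both
windows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import signal

from .phantom import ThermalFrameStack
from .tracking import RegionTrack


class ExtractionError(ValueError):
    """Raised when a series cannot be extracted (e.g. from a failed track)."""

    def __init__(self, msg: str, failure_frame: Optional[int] = None):
        super().__init__(msg)
        self.failure_frame = failure_frame


@dataclass
class TemperatureSeries:
    """Mean-temperature time series of one region of one trial (Kelvin)."""

    values: np.ndarray
    fs: float
    side: Optional[str] = None
    trial_key: Optional[tuple] = None
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs

    def plot(self, ax=None, **kwargs):
        """Plot the series against time (seconds)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", "filtered" if self.filtered else "raw")
        ax.plot(self.times(), self.values, label=label, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("temperature (K)")
        return ax


@dataclass
class WindowPair:
    """Pre- and post-stimulus segments of equal length abutting t_stim."""

    pre: np.ndarray
    post: np.ndarray
    t_stim: float
    n_samples: int

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.float64)
        self.post = np.asarray(self.post, dtype=np.float64)
        if len(self.pre) != len(self.post):
            raise ValueError("pre and post windows must have equal length")
        if len(self.pre) != self.n_samples:
            raise ValueError("window length does not match n_samples")


def trimmed_mean_upper(pixels, fraction: float = 0.5) -> float:
    """Mean of the warmest ``ceil(N * fraction)`` pixel temperatures."""
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty pixel collection")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(x.size * fraction)
    if k >= x.size:
        return float(x.mean())
    return float(np.partition(x, x.size - k)[x.size - k :].mean())


def series_from_track(
    stack: ThermalFrameStack,
    track: RegionTrack,
    fraction: float = 0.5,
) -> TemperatureSeries:
    """Per-frame upper trimmed mean of the pixels inside the tracked ROI.

    ``fraction=1.0`` gives the untrimmed mean (debug/illustration only).
    """
    if track.failed:
        raise ExtractionError(
            f"track failed at frame {track.failure_frame}; series not extracted",
            failure_frame=track.failure_frame,
        )
    frames = stack.frames
    values = np.empty(len(track))
    for j, roi in enumerate(track.rois):
        values[j] = trimmed_mean_upper(roi.extract(frames[track.start_frame + j]), fraction)
    return TemperatureSeries(values=values, fs=stack.fs, side=track.side, filtered=False)


def butter_lowpass(fs: float, order: int = 2, cutoff: float = 2.0):
    """Design the causal digital Butterworth used throughout (-3 dB at cutoff)."""
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    return signal.butter(order, cutoff, btype="low", fs=fs)


def lowpass_values(
    values: np.ndarray, fs: float, order: int = 2, cutoff: float = 2.0
) -> np.ndarray:
    """Single-pass causal Butterworth low-pass of a raw array.

    The initial filter state is the steady-state response to the first
    sample, so a constant input passes through unchanged from sample 0.
    """
    b, a = butter_lowpass(fs, order, cutoff)
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def lowpass(
    series: Union[TemperatureSeries, np.ndarray],
    fs: Optional[float] = None,
    order: int = 2,
    cutoff: float = 2.0,
):
    """Low-pass a :class:`TemperatureSeries` (or raw array with ``fs`` given)."""
    if isinstance(series, TemperatureSeries):
        y = lowpass_values(series.values, series.fs, order, cutoff)
        return replace(series, values=y, filtered=True)
    if fs is None:
        raise ValueError("fs is required when filtering a raw array")
    return lowpass_values(series, fs, order, cutoff)


def extract_windows(
    series: TemperatureSeries, t_stim: float, width: float = 2.0
) -> WindowPair:
    """Cut the pre [t_stim - width, t_stim] and post [t_stim, t_stim + width]
    windows (endpoints inclusive; the t_stim sample sits on both windows'
    boundary)."""
    n = len(series)
    i = int(round(t_stim * series.fs))
    nw = int(round(width * series.fs))
    if i - nw < 0 or i + nw > n - 1:
        raise ValueError(
            f"stimulus at {t_stim} s too close to the trial edge for {width} s windows"
        )
    return WindowPair(
        pre=series.values[i - nw : i + 1].copy(),
        post=series.values[i : i + nw + 1].copy(),
        t_stim=t_stim,
        n_samples=nw + 1,
    )
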