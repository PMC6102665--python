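"""Filtering, heel-strike detection, 30 m window selection, stride cutting
and time normalization.

Processing order: the continuous signal is low-pass filtered (zero-phase,
so event timing is preserved), heel strikes are detected on the filtered
signal (or taken from an annotation file), the first and last walkway-length
windows of the walk are selected, strides are cut at heel strikes and each
is resampled onto a common m-point phase grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .exceptions import (ComputationError, ConfigurationError, DetectionError,
                         WindowError)
from .signal_io import AccelerationTimeSeries, EventList, SessionManifest


@dataclass
class StrideCycle:
    """Raw 3D samples of one stride (heel strike to next ipsilateral one)."""

    samples: np.ndarray  # (n_i, 3)
    foot: str
    condition: str  # "B" or "E"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] < 4:
            raise ComputationError("a stride needs at least 4 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ComputationError("stride samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class NormalizedCycle:
    """One stride resampled to m phase points, first point at heel strike."""

    samples: np.ndarray  # (m, 3)
    foot: str
    condition: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def m(self) -> int:
        return self.samples.shape[0]


@dataclass
class ConditionWindow:
    """One analysis window (beginning B or end E of the walk)."""

    condition: str  # "B" or "E"
    stride_start: int  # index into the event list; strides [start, stop)
    stride_stop: int
    elapsed_s: float
    distance_m: float
    average_speed: float  # = distance_m / elapsed_s

    def __post_init__(self):
        if self.average_speed <= 0:
            raise WindowError("window average speed must be positive")

    @property
    def n_strides(self) -> int:
        return self.stride_stop - self.stride_start


def lowpass_filter(ts: AccelerationTimeSeries, cutoff: float = 4.5,
                   order: int = 4) -> AccelerationTimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass, per axis.

    The default 4.5 Hz / 4th-order setting keeps stride-rate harmonics of
    normal walking while removing heel-strike transients and sensor noise.
    Zero-phase filtering doubles the effective attenuation but introduces
    no group delay, so detected events stay aligned with the raw signal.
    """
    nyquist = ts.rate / 2.0
    if cutoff >= nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz")
    if cutoff <= 0 or order < 1:
        raise ConfigurationError("cutoff must be positive and order >= 1")
    b, a = butter(order, cutoff, btype="low", fs=ts.rate)
    filtered = filtfilt(b, a, ts.samples, axis=0)
    return AccelerationTimeSeries(samples=filtered, rate=ts.rate, foot=ts.foot,
                                  units_in=ts.units_in)


def detect_heel_strikes(ts: AccelerationTimeSeries,
                        min_period_s: float = 0.5,
                        max_period_s: float = 2.5,
                        peak_separation: float = 0.7,
                        search_back: float = 0.25,
                        min_prominence_frac: float = 0.1) -> EventList:
    """Accelerometer-only heel-strike detector on a filtered recording.

    Algorithm (fixed):

    1. estimate the dominant stride period from the autocorrelation peak of
       the acceleration-magnitude signal, searching lags in
       ``[min_period_s, max_period_s]``;
    2. find local maxima of the magnitude with minimum separation
       ``peak_separation``·period and prominence of at least
       ``min_prominence_frac`` of the signal's magnitude range (guards
       against ripples around quiet standing phases);
    3. for each maximum, the event is the closest preceding local minimum
       within ``search_back``·period.

    During stance the foot is nearly stationary, so the magnitude minimum
    just before the swing-phase acceleration burst marks initial contact.

    Raises :class:`DetectionError` when no periodicity is found in the lag
    range (e.g. a constant signal), so callers can fall back to an
    annotation file.
    """
    mag = np.linalg.norm(ts.samples, axis=1)
    x = mag - mag.mean()
    if not np.any(np.abs(x) > 1e-12 * max(1.0, np.abs(mag).max())):
        raise DetectionError("signal has no variation; cannot detect gait")

    n = x.size
    lo = int(round(min_period_s * ts.rate))
    hi = int(round(max_period_s * ts.rate))
    if hi >= n:
        hi = n - 1
    if lo < 1 or hi <= lo:
        raise DetectionError("recording too short for the period search range")

    # autocorrelation via FFT, biased normalization is fine for peak picking
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: n]
    window = ac[lo:hi + 1]
    k = int(np.argmax(window))
    lag = lo + k
    # require an interior local maximum: a monotone trend has no period
    interior = 0 < lag < n - 1 and ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1]
    if not interior or ac[lag] <= 0:
        raise DetectionError("no autocorrelation peak in the stride-period range")
    period = lag

    maxima, _ = find_peaks(mag, distance=max(1, int(round(peak_separation * period))),
                           prominence=min_prominence_frac * np.ptp(mag))
    minima, _ = find_peaks(-mag)
    if maxima.size == 0 or minima.size == 0:
        raise DetectionError("no magnitude extrema found")

    back = int(round(search_back * period))
    events = []
    for p in maxima:
        candidates = minima[(minima >= p - back) & (minima < p)]
        if candidates.size:
            events.append(int(candidates[-1]))
    events = sorted(set(events))
    if len(events) < 2:
        raise DetectionError("fewer than 2 heel strikes detected")
    return EventList(indices=np.array(events, dtype=np.int64), foot=ts.foot)


def select_windows(events: EventList, manifest: SessionManifest,
                   n_samples: int, rate: float) -> tuple[ConditionWindow, ConditionWindow]:
    """Select the beginning (B) and end (E) walkway-length windows.

    Distance is accrued as elapsed time × nominal speed, with the nominal
    speed taken from the manifest's 6-minute walk distance (six_mwd / 360 s).
    Window B runs from the first heel strike until the accrued distance
    reaches ``walkway_length``; window E is selected symmetrically from the
    last heel strike backwards. Each window's average speed v is
    walkway_length divided by its elapsed time.
    """
    if manifest.six_mwd is None:
        raise ConfigurationError(
            "six_mwd is required for distance-based window selection")
    if len(events) < 3:
        raise WindowError("too few heel strikes to place windows")
    idx = events.indices
    if idx[-1] >= n_samples:
        raise WindowError("events extend beyond the recording")
    v_nom = manifest.six_mwd / 360.0
    L = manifest.walkway_length

    t = (idx - idx[0]) / rate  # elapsed time at each event
    dist = t * v_nom
    reach = np.nonzero(dist >= L)[0]
    if reach.size == 0:
        raise WindowError("recording shorter than one walkway length")
    kB = int(reach[0])  # strides [0, kB) cover >= L

    t_end = (idx[-1] - idx) / rate
    dist_end = t_end * v_nom
    reach_e = np.nonzero(dist_end >= L)[0]
    kE = int(reach_e[-1])  # strides [kE, n_events-1) cover >= L

    if kE < kB:
        raise WindowError(
            "beginning and end windows overlap; recording too short")

    elapsed_B = float(t[kB])
    elapsed_E = float(t_end[kE])
    win_B = ConditionWindow(condition="B", stride_start=0, stride_stop=kB,
                            elapsed_s=elapsed_B, distance_m=L,
                            average_speed=L / elapsed_B)
    win_E = ConditionWindow(condition="E", stride_start=kE,
                            stride_stop=len(events) - 1,
                            elapsed_s=elapsed_E, distance_m=L,
                            average_speed=L / elapsed_E)
    return win_B, win_E


def cut_strides(ts: AccelerationTimeSeries, events: EventList,
                window: ConditionWindow,
                outlier_low: float = 0.4,
                outlier_high: float = 1.6) -> list[StrideCycle]:
    """Cut the recording into strides within a window, discarding outliers.

    Stride i spans samples ``[event_i, event_{i+1})``. Strides shorter than
    ``outlier_low``× or longer than ``outlier_high``× the median stride
    length within the window are discarded — a guard against corrupted
    cycles (e.g. turns at the hallway ends).
    """
    idx = events.indices
    starts = idx[window.stride_start:window.stride_stop]
    stops = idx[window.stride_start + 1:window.stride_stop + 1]
    if starts.size < 2:
        raise ComputationError("fewer than 2 strides in window")
    lengths = stops - starts
    med = float(np.median(lengths))
    keep = (lengths >= outlier_low * med) & (lengths <= outlier_high * med)
    strides = [StrideCycle(samples=ts.samples[a:b], foot=ts.foot,
                           condition=window.condition)
               for a, b, k in zip(starts, stops, keep) if k]
    if len(strides) < 2:
        raise ComputationError("fewer than 2 strides survive the outlier guard")
    return strides


def normalize_cycle(stride: StrideCycle, m: int = 200) -> NormalizedCycle:
    """Resample one stride to m phase points by cubic-spline interpolation.

    The stride's samples are placed at phases t/n for t = 0..n−1 and
    evaluated at τ_j = j/m; the first point stays anchored at the heel
    strike. The final sub-sample of phase is cubic extrapolation, which is
    benign for band-limited cycles.
    """
    if m < 4:
        raise ConfigurationError("m must be at least 4")
    n = len(stride)
    x = np.arange(n) / n
    tau = np.arange(m) / m
    spline = CubicSpline(x, stride.samples, axis=0)
    return NormalizedCycle(samples=spline(tau), foot=stride.foot,
                           condition=stride.condition)
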