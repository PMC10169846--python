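"""Resistive-pulse event detection and statistics for single-channel traces.

The analysis chain mirrors standard single-channel practice: low-pass
Bessel conditioning, robust open-pore baseline estimation, threshold
detection with hysteresis, and per-event blockade/dwell statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording.

    samples are in pA, sampling_rate in Hz, applied_potential in mV.
    """

    samples: np.ndarray
    sampling_rate: float
    applied_potential_mv: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class BlockadeEvent:
    """One detected current blockade.

    blockade_fraction = (I0 - Ib) / I0 against the local baseline; larger
    means deeper. dwell is the threshold-to-threshold duration in ms.
    """

    start_time_s: float
    dwell_ms: float
    mean_blocked_current_pa: float
    baseline_pa: float
    blockade_fraction: float


@dataclass
class EventStatistics:
    """Summary statistics of a detected event population."""

    n_events: int
    duration_s: float
    capture_rate_per_min: float
    blockade_mean: float
    blockade_sd: float
    dwell_mean_ms: float
    blockade_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    dwell_hist: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


def bessel_lowpass(
    trace: CurrentTrace, cutoff_hz: float, order: int = 4
) -> CurrentTrace:
    """Low-pass Bessel filter with corner (-3 dB) frequency cutoff_hz.

    Causal filtering, as applied by recording hardware; DC gain is 1.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = signal.bessel(order, cutoff_hz, btype="low", norm="mag",
                        fs=trace.sampling_rate, output="sos")
    # start in DC steady state at the first sample: no startup transient
    zi = signal.sosfilt_zi(sos) * trace.samples[0] if trace.samples.size else None
    if zi is None:
        filtered = trace.samples.copy()
    else:
        filtered, _ = signal.sosfilt(sos, trace.samples, zi=zi)
    return CurrentTrace(filtered, trace.sampling_rate,
                        trace.applied_potential_mv, trace.label)


def estimate_baseline(trace: CurrentTrace, n_iter: int = 4) -> tuple[float, float]:
    """Robust open-pore level I0 (pA) and noise sigma (pA).

    Starts from the trace median and iterates a one-sided clip that
    discards samples more than 3 sigma *below* the current level, so that
    blockade events do not drag the baseline down. Sigma is the scaled
    median absolute deviation of the retained samples. Warns when more
    than half the trace sits below the final baseline band (baseline
    unreliable).
    """
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    if x.size > 2_000_000:
        # robust statistics converge long before 1e6 samples
        x = x[:: x.size // 1_000_000]
    i0 = float(np.median(x))
    sigma = 1.4826 * float(np.median(np.abs(x - i0)))
    for _ in range(n_iter):
        if sigma == 0:
            break
        keep = x > i0 - 3.0 * sigma
        if not np.any(keep):
            break
        sel = x[keep]
        i0 = float(np.median(sel))
        sigma = 1.4826 * float(np.median(np.abs(sel - i0)))
    if sigma > 0:
        below = np.mean(x < i0 - 3.0 * sigma)
        above = np.mean(x > i0 + 3.0 * sigma)
        # a majority-blocked trace either leaves >50% of samples below the
        # band, or the estimator locks onto the blocked level and a large
        # population sits above it
        if below > 0.5 or above > 0.05:
            warnings.warn(
                "trace appears dominated by the blocked level; "
                "baseline estimate unreliable",
                stacklevel=2,
            )
    return i0, sigma


def _event_segments(
    x: np.ndarray, open_thr: float, close_thr: float
) -> list[tuple[int, int]]:
    """Hysteresis segmentation: open below open_thr, close above close_thr.

    Returns half-open sample index ranges [start, end). Runs on index
    arrays of threshold crossings, so cost scales with the number of
    events, not trace length.
    """
    below_open = np.flatnonzero(x < open_thr)
    above_close = np.flatnonzero(x > close_thr)
    segments: list[tuple[int, int]] = []
    pos = 0
    n = x.size
    while True:
        j = np.searchsorted(below_open, pos)
        if j == len(below_open):
            break
        start = int(below_open[j])
        k = np.searchsorted(above_close, start)
        end = int(above_close[k]) if k < len(above_close) else n
        segments.append((start, end))
        pos = end + 1
        if end >= n:
            break
    return segments


def detect_events(
    trace: CurrentTrace,
    threshold_k: float = 5.0,
    min_dwell_ms: float = 0.4,
    baseline: tuple[float, float] | None = None,
    edge_exclude_s: float = 8e-5,
) -> list[BlockadeEvent]:
    """Detect downward blockade events by threshold crossing with hysteresis.

    An event opens when the current drops below I0 - threshold_k * sigma
    and closes when it returns above I0 - threshold_k/2 * sigma (re-cross
    at half the entry threshold prevents chatter). Events shorter than
    min_dwell_ms are discarded. The mean blocked current excludes
    edge_exclude_s of samples at each boundary (filter settling time,
    ~80 us at a 5 kHz corner); events too short for that keep their
    central third.

    baseline may be supplied as (i0_pa, sigma_pa) to skip re-estimation.
    Positive (current-increase) excursions are ignored.
    """
    if baseline is None:
        i0, sigma = estimate_baseline(trace)
    else:
        i0, sigma = baseline
    x = trace.samples
    if sigma == 0:
        if np.any(x < i0):
            # noiseless trace: any dip below baseline is an event
            segs = _event_segments(x, i0 - 1e-12, i0 - 1e-12)
        else:
            warnings.warn("zero noise and no excursions: no events detectable",
                          stacklevel=2)
            return []
    else:
        open_thr = i0 - threshold_k * sigma
        close_thr = i0 - 0.5 * threshold_k * sigma
        segs = _event_segments(x, open_thr, close_thr)

    fs = trace.sampling_rate
    min_samples = min_dwell_ms * 1e-3 * fs
    n_edge = int(round(edge_exclude_s * fs))
    events: list[BlockadeEvent] = []
    for start, end in segs:
        n = end - start
        if n < max(min_samples, 1):
            continue
        lo, hi = start + n_edge, end - n_edge
        if hi - lo < max(1, n // 3):
            third = max(1, n // 3)
            lo = start + (n - third) // 2
            hi = lo + third
        ib = float(np.mean(x[lo:hi]))
        frac = (i0 - ib) / i0 if i0 != 0 else 0.0
        frac = float(np.clip(frac, 0.0, 1.0))
        events.append(
            BlockadeEvent(
                start_time_s=start / fs,
                dwell_ms=n / fs * 1e3,
                mean_blocked_current_pa=ib,
                baseline_pa=i0,
                blockade_fraction=frac,
            )
        )
    return events


def summarize_events(
    events: list[BlockadeEvent],
    duration_s: float,
    blockade_bins: int | np.ndarray = 50,
    dwell_bins: int | np.ndarray = 50,
) -> EventStatistics:
    """Aggregate event statistics: capture rate, blockade and dwell summaries.

    capture_rate = 60 * n_events / duration_s (events per minute). An
    empty event list yields zeroed statistics, not an error.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    if n == 0:
        empty = (np.array([]), np.array([0.0, 1.0]))
        return EventStatistics(0, duration_s, 0.0, 0.0, 0.0, 0.0, empty, empty)
    blockades = np.array([e.blockade_fraction for e in events])
    dwells = np.array([e.dwell_ms for e in events])
    b_counts, b_edges = np.histogram(blockades, bins=blockade_bins)
    d_counts, d_edges = np.histogram(dwells, bins=dwell_bins)
    return EventStatistics(
        n_events=n,
        duration_s=duration_s,
        capture_rate_per_min=60.0 * n / duration_s,
        blockade_mean=float(blockades.mean()),
        blockade_sd=float(blockades.std(ddof=1)) if n > 1 else 0.0,
        dwell_mean_ms=float(dwells.mean()),
        blockade_hist=(b_counts, b_edges),
        dwell_hist=(d_counts, d_edges),
    )


def hysteresis_dwell_bias(
    sampling_rate: float,
    cutoff_hz: float,
    amplitude_pa: float,
    sigma_pa: float,
    threshold_k: float = 5.0,
    order: int = 4,
) -> float:
    """Systematic dwell lengthening (ms) of the hysteresis detector.

    For a rectangular blockade of amplitude A through the low-pass Bessel
    filter, the event opens when the falling edge crosses k*sigma below
    baseline (a fraction k*sigma/A of the step, crossed early) and closes
    when the rising edge recovers past k/2*sigma below baseline (a
    fraction 1 - k*sigma/(2A), crossed late). The measured dwell is the
    true dwell plus the difference of the two step-response crossing
    times, computed here numerically from the same filter.
    """
    if amplitude_pa <= 0:
        raise ValueError("amplitude must be positive")
    f_open = threshold_k * sigma_pa / amplitude_pa
    f_close = 1.0 - 0.5 * threshold_k * sigma_pa / amplitude_pa
    if not 0 < f_open < 1 or not 0 < f_close < 1:
        return 0.0
    sos = signal.bessel(order, cutoff_hz, btype="low", norm="mag",
                        fs=sampling_rate, output="sos")
    n = int(10 * sampling_rate / cutoff_hz)
    step = signal.sosfilt(sos, np.ones(n))

    def crossing(frac: float) -> float:
        idx = int(np.searchsorted(step > frac, True))
        return idx / sampling_rate

    return (crossing(f_close) - crossing(f_open)) * 1e3


def truncation_corrected_rate(
    events: list[BlockadeEvent],
    duration_s: float,
    min_dwell_ms: float,
    dwell_bias_ms: float = 0.0,
) -> float:
    """Capture rate (events/min) corrected for the min-dwell cutoff.

    Threshold detection with a minimum-dwell filter left-censors an
    exponential dwell distribution: events whose *true* dwell falls below
    min_dwell_ms - dwell_bias_ms (the measured cutoff corrected for the
    detector's systematic dwell lengthening, see hysteresis_dwell_bias)
    are never counted, a fraction 1 - exp(-t_cut / tau). For a memoryless
    dwell law the detected dwells are cutoff + Exp(tau), so tau is the
    detected mean dwell minus min_dwell_ms, and the raw rate is divided
    by the detected fraction.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    if n == 0:
        return 0.0
    raw = 60.0 * n / duration_s
    t_cut = max(min_dwell_ms - dwell_bias_ms, 0.0)
    if min_dwell_ms <= 0 or t_cut == 0.0:
        return raw
    mean_dwell = float(np.mean([e.dwell_ms for e in events]))
    tau = mean_dwell - min_dwell_ms
    if tau <= 0:
        warnings.warn("detected mean dwell at or below the cutoff; "
                      "returning uncorrected rate", stacklevel=2)
        return raw
    return raw / float(np.exp(-t_cut / tau))
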