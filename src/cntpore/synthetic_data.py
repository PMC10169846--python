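"""Synthetic inputs with known ground truth for every pipeline stage.

Generates resistive-pulse current recordings (Poisson-arriving rectangular
blockades on a noisy baseline, optionally Bessel-filtered), populations of
tube conductances from diameter/length distributions, reversal-potential
experiments with a known true selectivity, and blinking fluorescent-spot
image stacks.

Defaults follow the study conditions of the recordings being emulated:
100 kHz sampling, 5 kHz Bessel corner, 70 pA open-pore baseline at 80 mV,
exponential dwell law. Recording noise is not stated by any source; 2 pA
RMS at 5 kHz bandwidth, typical of planar-bilayer recordings, is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K
from .trace_analysis import CurrentTrace, bessel_lowpass
from .transport_models import (
    ElectrolyteState,
    PoreGeometry,
    reversal_from_transference,
    transference_from_selectivity,
    tube_conductance,
)


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic resistive-pulse recording.

    baseline_current_pa: open-pore current I0. event_rate_per_min is the
    Poisson intensity; blockade_depth the fractional drop in (0, 1);
    dwell_law "exponential" (mean dwell_mean_ms) or "lognormal"
    (dwell_mean_ms mean with dwell_shape log-sd). filter_cutoff_hz None
    disables filtering.
    """

    baseline_current_pa: float = 70.0
    noise_sigma_pa: float = 2.0
    event_rate_per_min: float = 150.0
    blockade_depth: float = 0.442
    dwell_law: str = "exponential"
    dwell_mean_ms: float = 1.0
    dwell_shape: float = 0.5
    duration_s: float = 60.0
    sampling_rate_hz: float = 100_000.0
    filter_cutoff_hz: float | None = 5_000.0
    applied_potential_mv: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.blockade_depth < 1.0:
            raise ValueError("blockade depth must lie in (0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.event_rate_per_min < 0:
            raise ValueError("event rate must be non-negative")
        if self.dwell_mean_ms <= 0:
            raise ValueError("dwell mean must be positive")
        if self.dwell_law not in ("exponential", "lognormal"):
            raise ValueError(f"unknown dwell law {self.dwell_law!r}")
        if self.filter_cutoff_hz is not None:
            if self.sampling_rate_hz <= 2.0 * self.filter_cutoff_hz:
                raise ValueError("sampling rate must exceed twice the filter cutoff")
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError("duration x sampling rate must be a positive integer")


@dataclass
class TubePopulationConfig:
    """Population of tubes with diameter and length distributions.

    diameter_law / length_law are either a constant (nm) or a callable
    rng -> sample drawing one value per tube, e.g.
    ``lambda rng: rng.normal(1.2, 0.05)``.
    """

    n_tubes: int
    diameter_law: float | Callable[[np.random.Generator], float] = 1.2
    length_law: float | Callable[[np.random.Generator], float] = 10.0
    electrolyte: ElectrolyteState = field(default_factory=ElectrolyteState)
    seed: int = 0


def _draw_dwells_ms(config: SimulationConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    if config.dwell_law == "exponential":
        return rng.exponential(config.dwell_mean_ms, size=n)
    # lognormal parameterized by its arithmetic mean and log-sd
    s = config.dwell_shape
    mu = np.log(config.dwell_mean_ms) - 0.5 * s**2
    return rng.lognormal(mu, s, size=n)


def simulate_trace(config: SimulationConfig) -> tuple[CurrentTrace, pd.DataFrame]:
    """Simulate a resistive-pulse recording with ground-truth events.

    Events arrive as a Poisson process; each replaces the baseline with
    baseline * (1 - depth) for its dwell (rectangular, instantaneous
    transitions). Gaussian noise is added, then the optional low-pass
    Bessel filter. Overlapping arrivals are merged into one longer
    ground-truth event, since no detector can separate them.

    Returns the trace and a DataFrame with columns start_s, dwell_ms,
    depth_frac (post-merge ground truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.sampling_rate_hz))
    fs = config.sampling_rate_hz

    rate_per_s = config.event_rate_per_min / 60.0
    if rate_per_s > 0:
        n_arrivals = rng.poisson(rate_per_s * config.duration_s)
        starts = np.sort(rng.uniform(0.0, config.duration_s, size=n_arrivals))
    else:
        starts = np.array([])
    dwells_s = _draw_dwells_ms(config, starts.size, rng) * 1e-3

    # merge overlapping events
    merged: list[tuple[float, float]] = []
    for s, d in zip(starts, dwells_s):
        e = min(s + d, config.duration_s)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    merged = [(s, e) for s, e in merged if e > s]

    x = np.full(n_samples, config.baseline_current_pa)
    blocked = config.baseline_current_pa * (1.0 - config.blockade_depth)
    for s, e in merged:
        i0 = int(round(s * fs))
        i1 = int(round(e * fs))
        x[i0:i1] = blocked
    if config.noise_sigma_pa > 0:
        x = x + rng.normal(0.0, config.noise_sigma_pa, size=n_samples)

    trace = CurrentTrace(x, fs, config.applied_potential_mv,
                         label=f"synthetic seed={config.seed}")
    if config.filter_cutoff_hz is not None:
        trace = bessel_lowpass(trace, config.filter_cutoff_hz)

    truth = pd.DataFrame(
        {
            "start_s": [s for s, _ in merged],
            "dwell_ms": [(e - s) * 1e3 for s, e in merged],
            "depth_frac": config.blockade_depth,
        }
        if merged
        else {"start_s": [], "dwell_ms": [], "depth_frac": []}
    )
    return trace, truth


def simulate_tube_population(config: TubePopulationConfig) -> np.ndarray:
    """Draw (D, L) per tube and return conductances (nS) via the
    electrolyte-cylinder model."""
    if config.n_tubes < 0:
        raise ValueError("n_tubes must be non-negative")
    rng = np.random.default_rng(config.seed)

    def draw(law) -> float:
        v = law(rng) if callable(law) else float(law)
        if v <= 0:
            raise ValueError("sampled diameter/length must be positive")
        return v

    out = np.empty(config.n_tubes)
    for i in range(config.n_tubes):
        d = draw(config.diameter_law)
        length = draw(config.length_law)
        out[i] = tube_conductance(PoreGeometry(d, length), config.electrolyte)
    return out


def simulate_reversal_experiment(
    true_sr: float,
    a_cis: float,
    a_trans: float,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    noise_mv: float = 0.0,
    seed: int | None = None,
) -> float:
    """Reversal potential (mV) of a pore with known selectivity ratio.

    Converts the true selectivity ratio to a transference number, forms
    the exact GHK reversal potential, and adds Gaussian measurement noise
    of noise_mv. Equal cis/trans activities make the reversal potential
    identically zero for any selectivity and are rejected as
    non-identifiable.
    """
    if true_sr <= 0:
        raise ValueError("selectivity ratio must be positive")
    if a_cis <= 0 or a_trans <= 0:
        raise ValueError("activities must be positive")
    if a_cis == a_trans:
        raise ValueError(
            "equal cis/trans activities: the experiment is non-identifiable"
        )
    t_k = transference_from_selectivity(true_sr)
    v_r = reversal_from_transference(t_k, a_cis, a_trans, temperature_k)
    if noise_mv > 0:
        rng = np.random.default_rng(seed)
        v_r += rng.normal(0.0, noise_mv)
    return v_r


def simulate_image_stack(
    spot_positions: Sequence[tuple[float, float]],
    blink_traces: Sequence[np.ndarray],
    psf_sigma_px: float = 1.5,
    frame_noise: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    background: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Multi-frame image stack of blinking Gaussian point-spread spots.

    Each frame is background + sum over spots of a Gaussian PSF scaled by
    that spot's intensity in that frame, plus Gaussian noise. Coordinates
    are 0-based (row, col), pixel centers at integers. Returns the stack
    (frames, rows, cols) and a ground-truth dict with positions and
    per-frame intensities.
    """
    if len(spot_positions) != len(blink_traces):
        raise ValueError("one blink trace per spot is required")
    n_frames = len(blink_traces[0]) if blink_traces else 0
    for bt in blink_traces:
        if len(bt) != n_frames:
            raise ValueError("all blink traces must have equal length")
    h, w = shape
    for r, c in spot_positions:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot ({r}, {c}) outside frame bounds {shape}")
    if n_frames == 0:
        n_frames = 1
        blink_traces = [np.array([]) for _ in spot_positions]

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:h, 0:w]
    psfs = [
        np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * psf_sigma_px**2))
        for r, c in spot_positions
    ]
    stack = np.full((n_frames, h, w), background, dtype=float)
    for t in range(n_frames):
        for psf, bt in zip(psfs, blink_traces):
            if len(bt):
                stack[t] += bt[t] * psf
    if frame_noise > 0:
        stack += rng.normal(0.0, frame_noise, size=stack.shape)
    truth = {
        "positions": [tuple(p) for p in spot_positions],
        "intensities": [np.asarray(bt, dtype=float) for bt in blink_traces],
    }
    return stack, truth
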