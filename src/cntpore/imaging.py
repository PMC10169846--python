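"""Single-spot fluorescence analysis for optical ion-flux recordings.

Finds fluorescent spots in an image stack (droplet-hydrogel bilayer
calcium-flux movies), extracts per-spot intensity time series, detects
blinking (dark) events by reusing the resistive-pulse hysteresis detector,
and summarizes spot populations with covariance confidence ellipses.

Image coordinates are 0-based (row, col) with pixel centers at integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.feature import peak_local_max

from .trace_analysis import BlockadeEvent, CurrentTrace, detect_events


@dataclass
class SpotTrack:
    """One fluorescent spot: location, size and intensity time series.

    pixel_size is the count of above-threshold pixels at the brightest
    frame; intensities are background-subtracted sums over the analysis
    window, arbitrary units.
    """

    centroid: tuple[float, float]
    pixel_size: int
    intensity_series: np.ndarray
    max_intensity: float


@dataclass
class ConfidenceEllipse:
    """Covariance ellipse at a given confidence level.

    semi_axes are sorted descending; angle_rad is the orientation of the
    major axis against the first coordinate. degenerate flags a singular
    covariance.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    angle_rad: float
    level: float
    covariance: np.ndarray
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (Mahalanobis test)."""
        d = np.atleast_2d(points) - self.center
        inv = np.linalg.pinv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return m2 <= stats.chi2.ppf(self.level, df=2)


def _background_stats(stack: np.ndarray) -> tuple[float, float]:
    """Robust background mean and sd from all voxels (median / scaled MAD)."""
    med = float(np.median(stack))
    sd = 1.4826 * float(np.median(np.abs(stack - med)))
    return med, sd


def detect_spots(
    stack: np.ndarray,
    k_sigma: float = 5.0,
    min_distance: int = 3,
    window_radius: int = 3,
) -> list[tuple[float, float]]:
    """Candidate spot centroids from the temporal-maximum projection.

    Spots are local maxima of the max-over-time projection exceeding the
    robust background mean + k_sigma * sd; centroids are refined by an
    intensity-weighted mean (background-subtracted, clipped at zero)
    within a window of window_radius pixels.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (frames, rows, cols) with >= 1 frame")
    bg, sd = _background_stats(stack)
    proj = stack.max(axis=0)
    threshold = bg + k_sigma * sd
    peaks = peak_local_max(proj, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=False)
    centroids = []
    h, w = proj.shape
    r = window_radius
    for pr, pc in peaks:
        r0, r1 = max(0, pr - r), min(h, pr + r + 1)
        c0, c1 = max(0, pc - r), min(w, pc + r + 1)
        win = np.clip(proj[r0:r1, c0:c1] - bg, 0.0, None)
        total = win.sum()
        if total == 0:
            centroids.append((float(pr), float(pc)))
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        centroids.append(
            (float((rows * win).sum() / total), float((cols * win).sum() / total))
        )
    return centroids


def extract_track(
    stack: np.ndarray,
    centroid: tuple[float, float],
    window_radius: int = 3,
    k_sigma: float = 5.0,
) -> SpotTrack:
    """Intensity time series and size of one spot.

    Per-frame intensity is the background-subtracted sum over the window;
    pixel_size counts above-threshold pixels in the window at the
    brightest frame, using the same background threshold as detection.
    """
    stack = np.asarray(stack, dtype=float)
    bg, sd = _background_stats(stack)
    h, w = stack.shape[1:]
    pr, pc = int(round(centroid[0])), int(round(centroid[1]))
    r = window_radius
    r0, r1 = max(0, pr - r), min(h, pr + r + 1)
    c0, c1 = max(0, pc - r), min(w, pc + r + 1)
    window = stack[:, r0:r1, c0:c1]
    series = (window - bg).sum(axis=(1, 2))
    brightest = int(np.argmax(series))
    pixel_size = int(np.sum(window[brightest] > bg + k_sigma * sd))
    return SpotTrack(
        centroid=(float(centroid[0]), float(centroid[1])),
        pixel_size=max(pixel_size, 1),
        intensity_series=series,
        max_intensity=float(series.max()),
    )


def extract_blinking(
    track: SpotTrack,
    frame_period_ms: float,
    threshold_k: float = 5.0,
    min_dwell_frames: int = 1,
) -> list[BlockadeEvent]:
    """Dark (blinking-off) events in a spot intensity series.

    The series is treated as a current-like trace sampled at one frame
    per period and run through the hysteresis blockade detector; dark
    dwell times are therefore quantized to multiples of frame_period_ms,
    and events shorter than one frame are undetectable by contract.
    """
    if track.intensity_series.size == 0:
        raise ValueError("empty intensity series")
    fs = 1e3 / frame_period_ms  # frames per second
    trace = CurrentTrace(track.intensity_series, fs, label="blink series")
    return detect_events(
        trace,
        threshold_k=threshold_k,
        min_dwell_ms=min_dwell_frames * frame_period_ms * 0.999,
        edge_exclude_s=0.0,
    )


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Covariance confidence ellipse of a 2-D point cloud.

    Centered at the sample mean; semi-axes are sqrt(eigenvalue *
    chi2_quantile(level, df=2)) of the sample covariance, so for Gaussian
    data the ellipse contains the stated fraction of points. A singular
    covariance (e.g. all points identical) is flagged degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(np.min(evals) <= 1e-12 * max(np.max(evals), 1.0))
    if degenerate:
        warnings.warn("singular covariance: degenerate confidence ellipse",
                      stacklevel=2)
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(evals, 0.0, None) * q)
    # major axis last in eigh's ascending order
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    major = evecs[:, order[0]]
    angle = float(np.arctan2(major[1], major[0]))
    # canonical half-turn range
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return ConfidenceEllipse(center, semi, angle, level, cov, degenerate)
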