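"""Elementary chromatographic signal operations.

Smoothing, local-maxima candidate extraction, peak-border detection,
baseline-corrected trapezoidal integration, and resampling onto a common
time grid.  These primitives are deliberately simple and exactly testable;
everything downstream (quality scores, alignment, prototype integration)
is built on them.

Conventions: indices are 0-based, windows are closed intervals in time,
and all times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import Chromatogram, ProcessingParams

__all__ = [
    "PeakCandidate",
    "smooth",
    "find_candidates",
    "detect_borders",
    "integrate",
    "resample",
]


@dataclass
class PeakCandidate:
    """One candidate peak with its location, size and (later) scores."""

    metabolite: str
    sample_id: str
    apex_idx: int
    apex_time: float
    start_time: float
    end_time: float
    height: float            # baseline-subtracted apex intensity
    area: float              # counts * min above the linear baseline
    smoothed_apex: float = 0.0
    qs: np.ndarray | None = None    # 20-element quality-score vector
    score: float | None = None      # picking-classifier score in [0, 1]

    def __post_init__(self) -> None:
        if not self.start_time <= self.apex_time <= self.end_time:
            raise ValueError("require start_time <= apex_time <= end_time")
        if self.height < 0 or self.area < 0:
            raise ValueError("height and area must be >= 0")


def smooth(intensities: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge windows shrunk to available points.

    ``width`` must be odd; ``width=1`` is the identity.  The output has the
    same length as the input and is non-negative for non-negative input.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"smoothing width must be odd and >= 1, got {width}")
    x = np.asarray(intensities, dtype=float)
    if width > len(x):
        raise ValueError("smoothing width exceeds series length")
    if width == 1:
        return x.copy()
    kernel = np.ones(width)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _local_maxima(smoothed: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateau apexes count once)."""
    peaks, _ = find_peaks(smoothed)
    return peaks


def detect_borders(
    chrom: Chromatogram,
    apex_idx: int,
    border_frac: float = 0.01,
    smoothing_width: int = 5,
    smoothed: np.ndarray | None = None,
) -> tuple[float, float]:
    """Walk outward from the apex on the smoothed trace to find peak borders.

    In each direction the walk stops at the first point that is a local
    minimum (the trace starts rising again) or that falls below
    ``border_frac`` x the smoothed apex intensity, whichever comes first;
    borders are clipped to the trace extent.  The threshold is measured
    above the trace floor (the minimum of the smoothed trace), so a
    constant background offset does not defeat it.
    """
    s = smoothed if smoothed is not None else smooth(chrom.intensities, smoothing_width)
    n = len(s)
    apex_val = s[apex_idx]
    left_ok = apex_idx == 0 or s[apex_idx - 1] <= apex_val
    right_ok = apex_idx == n - 1 or s[apex_idx + 1] <= apex_val
    if not (left_ok and right_ok):
        raise ValueError(f"apex_idx {apex_idx} is not a local maximum")
    floor = float(s.min())
    threshold = floor + border_frac * (apex_val - floor)

    j = apex_idx
    while j + 1 < n:
        if s[j + 1] > s[j]:
            break               # local minimum: the valley between peaks
        j += 1
        if s[j] < threshold:
            break
    end_idx = j

    i = apex_idx
    while i - 1 >= 0:
        if s[i - 1] > s[i]:
            break
        i -= 1
        if s[i] < threshold:
            break
    start_idx = i
    return float(chrom.times[start_idx]), float(chrom.times[end_idx])


def integrate(
    chrom: Chromatogram, start_time: float, end_time: float
) -> tuple[float, float]:
    """Area and height above a linear baseline between the window borders.

    The baseline is the straight line through the (interpolated) intensities
    at ``start_time`` and ``end_time``; area is the trapezoidal integral of
    the signal above it and height the maximum excess, both clamped at 0.
    """
    t = chrom.times
    if not start_time < end_time:
        raise ValueError("require start_time < end_time")
    eps = 1e-9
    if start_time < t[0] - eps or end_time > t[-1] + eps:
        raise ValueError(
            f"integration window [{start_time}, {end_time}] outside trace "
            f"extent [{t[0]}, {t[-1]}]"
        )
    inner = (t > start_time) & (t < end_time)
    tw = np.concatenate(([start_time], t[inner], [end_time]))
    yw = np.interp(tw, t, chrom.intensities)
    baseline = np.interp(tw, [tw[0], tw[-1]], [yw[0], yw[-1]])
    excess = yw - baseline
    area = float(max(0.0, np.trapezoid(excess, tw)))
    height = float(max(0.0, excess.max()))
    return area, height


def resample(chrom: Chromatogram, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation onto ``grid``; points outside the source are 0."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resampling grid must be non-empty")
    return np.interp(grid, chrom.times, chrom.intensities, left=0.0, right=0.0)


def find_candidates(
    chrom: Chromatogram,
    params: ProcessingParams,
    window_center: float,
    window_halfwidth: float,
    metabolite: str = "",
    sample_id: str = "",
) -> list[PeakCandidate]:
    """Extract up to ``n_candidates`` local maxima of the smoothed trace.

    Candidates inside ``[center - halfwidth, center + halfwidth]`` are
    ranked by smoothed apex intensity (ties broken by earlier retention
    time) and returned with borders from :func:`detect_borders` and
    baseline-corrected area/height from :func:`integrate`.  An empty list
    (flat trace) is a valid result.
    """
    width = min(params.smoothing_width, len(chrom))
    if width % 2 == 0:
        width -= 1
    s = smooth(chrom.intensities, width)
    peaks = _local_maxima(s)
    lo, hi = window_center - window_halfwidth, window_center + window_halfwidth
    in_window = peaks[(chrom.times[peaks] >= lo) & (chrom.times[peaks] <= hi)]
    if in_window.size == 0:
        return []
    order = np.lexsort((chrom.times[in_window], -s[in_window]))
    out: list[PeakCandidate] = []
    for idx in in_window[order][: params.n_candidates]:
        start, end = detect_borders(
            chrom, int(idx), params.border_frac, params.smoothing_width, smoothed=s
        )
        if not start < end:
            continue
        area, height = integrate(chrom, start, end)
        out.append(
            PeakCandidate(
                metabolite=metabolite,
                sample_id=sample_id,
                apex_idx=int(idx),
                apex_time=float(chrom.times[idx]),
                start_time=start,
                end_time=end,
                height=height,
                area=area,
                smoothed_apex=float(s[idx]),
            )
        )
    return out


def gaussian(t: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    """Gaussian peak shape used for simulation and shape scoring."""
    return amplitude * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
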