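"""Growth-curve correction, diauxic-phase segmentation and rate estimation.

Raw OD_560 readings are background-corrected against blank wells and
linearized with a cubic calibration polynomial (derived from an OD ladder
spanning the reader's 0-2 dynamic range):

    x_adj = -0.01454 + 1.231 x - 0.6393 x^2 + 0.4985 x^3

Phase segmentation uses a deterministic rolling-regression estimator of
the specific growth rate (least-squares slope of ln OD in a sliding
window): the diauxic shift is the deepest local minimum of the rate
series that sits between two local maxima both exceeding a rate floor,
and the pre-/post-shift growth rates are the maximal rates on either side
of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: cubic OD_560 calibration coefficients (constant, x, x^2, x^3)
OD_ADJUST_COEFFS = (-0.01454, 1.231, -0.6393, 0.4985)

#: local maxima must exceed this fraction of the global max rate to
#: qualify as growth phases flanking a shift
RATE_FLOOR_FRACTION = 0.1


@dataclass
class GrowthCurve:
    time: np.ndarray          # h, strictly increasing
    od_raw: np.ndarray        # OD_560
    od_adjusted: np.ndarray | None = None
    well_id: str = ""
    strain: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        if self.time.shape != self.od_raw.shape:
            raise ValueError("time and od_raw must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class PhaseAnnotation:
    shift_time: float | None
    pre_rate: float
    post_rate: float | None
    pre_window: tuple[float, float]
    post_window: tuple[float, float] | None


def adjust_od(x):
    """Cubic calibration of background-corrected OD_560 readings.

    Strictly increasing on the reader's [0, 2] range (the derivative's
    discriminant is negative), so it preserves the ordering of readings.
    Apply exactly once, after background correction.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("OD input must be finite")
    if np.any((x < 0) | (x > 2)):
        warnings.warn("OD input outside the calibrated range [0, 2]")
    c0, c1, c2, c3 = OD_ADJUST_COEFFS
    out = c0 + c1 * x + c2 * x**2 + c3 * x**3
    return float(out) if out.ndim == 0 else out


def background_correct(od_raw: np.ndarray, blank_wells: np.ndarray) -> np.ndarray:
    """Subtract the per-timepoint mean of blank wells; floor at zero.

    ``blank_wells`` is (n_blanks, n_timepoints) or a single series.
    """
    od_raw = np.asarray(od_raw, dtype=float)
    blanks = np.atleast_2d(np.asarray(blank_wells, dtype=float))
    if blanks.size == 0:
        raise ValueError("at least one blank well is required")
    if blanks.shape[1] != od_raw.shape[0]:
        raise ValueError("blank series length does not match the curve")
    return np.maximum(od_raw - blanks.mean(axis=0), 0.0)


def rolling_rate(time: np.ndarray, od: np.ndarray, window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Rolling least-squares slope of ln(OD): specific growth rate series.

    Windows containing non-positive OD are skipped.  Returns (window
    center times, rates); raises if every window is skipped.
    """
    if len(time) < window:
        raise ValueError("curve shorter than the smoothing window")
    centers, rates = [], []
    for i in range(len(time) - window + 1):
        t = time[i:i + window]
        y = od[i:i + window]
        if np.any(y <= 0):
            continue
        slope = np.polyfit(t, np.log(y), 1)[0]
        centers.append(t.mean())
        rates.append(slope)
    if not centers:
        raise ValueError("no usable windows: OD non-positive throughout")
    return np.asarray(centers), np.asarray(rates)


def _local_extrema(series: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of strict-or-plateau local maxima and minima (interior points
    plus the endpoints, which count as maxima/minima of their side)."""
    n = len(series)
    maxima, minima = [], []
    for i in range(n):
        left = series[i - 1] if i > 0 else -np.inf
        right = series[i + 1] if i < n - 1 else -np.inf
        if series[i] >= left and series[i] >= right:
            maxima.append(i)
        left = series[i - 1] if i > 0 else np.inf
        right = series[i + 1] if i < n - 1 else np.inf
        if series[i] <= left and series[i] <= right:
            minima.append(i)
    return maxima, minima


def detect_phases(curve: GrowthCurve, smoothing_window: int = 5) -> PhaseAnnotation:
    """Segment an adjusted growth curve into pre- and post-shift phases.

    The shift is the deepest local minimum of the rolling growth-rate
    series lying between two local maxima that both exceed
    ``RATE_FLOOR_FRACTION`` of the global maximum rate.  Without a
    qualifying minimum no shift is reported and the whole curve is the
    pre phase.
    """
    if len(curve.time) < 10:
        raise ValueError("phase detection needs >= 10 timepoints")
    od = curve.od_adjusted if curve.od_adjusted is not None else curve.od_raw
    centers, rates = rolling_rate(curve.time, np.asarray(od, dtype=float),
                                  smoothing_window)
    max_rate = float(rates.max())
    if max_rate <= 1e-9:  # numerically flat: no growth at all
        return PhaseAnnotation(shift_time=None, pre_rate=0.0, post_rate=None,
                               pre_window=(curve.time[0], curve.time[-1]),
                               post_window=None)
    floor = RATE_FLOOR_FRACTION * max_rate
    maxima, minima = _local_extrema(rates)
    qualifying = []
    for m in minima:
        left_ok = any(i < m and rates[i] > floor for i in maxima)
        right_ok = any(i > m and rates[i] > floor for i in maxima)
        if left_ok and right_ok and rates[m] < floor:
            qualifying.append(m)
    if not qualifying:
        return PhaseAnnotation(shift_time=None, pre_rate=max_rate, post_rate=None,
                               pre_window=(curve.time[0], curve.time[-1]),
                               post_window=None)
    m = min(qualifying, key=lambda i: rates[i])
    shift_time = float(centers[m])
    pre = centers < shift_time
    post = centers > shift_time
    pre_rate = float(rates[pre].max()) if pre.any() else 0.0
    post_rate = float(rates[post].max()) if post.any() else 0.0
    return PhaseAnnotation(
        shift_time=shift_time,
        pre_rate=max(pre_rate, 0.0),
        post_rate=max(post_rate, 0.0),
        pre_window=(float(curve.time[0]), shift_time),
        post_window=(shift_time, float(curve.time[-1])),
    )


def process_curve(time, od_raw, blank_wells, well_id="", strain="",
                  smoothing_window: int = 5) -> tuple[GrowthCurve, PhaseAnnotation]:
    """Background-correct, adjust, and segment one well's readings."""
    corrected = background_correct(od_raw, blank_wells)
    curve = GrowthCurve(time=time, od_raw=np.asarray(od_raw, dtype=float),
                        well_id=well_id, strain=strain)
    curve.od_adjusted = adjust_od(np.clip(corrected, 0.0, 2.0))
    return curve, detect_phases(curve, smoothing_window)
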