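"""Transit-time aortic pulse wave velocity from velocity-time curves.

The regional wave speed is ``path length / transit time`` where the transit
time is the difference between the wave-foot onsets at two sampling sites.
Each onset is the intersection of a horizontal line modelling diastolic flow
(mean over the final 250 ms of the cycle) with a straight line fitted through
the systolic upslope (ordinary least squares over the samples lying between
20% and 80% of the velocity range above baseline).

Units are fixed throughout: time in ms, distance in mm, velocity in cm/s.
PWV is emitted in m/s, which is numerically identical to mm/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError, PropagationError, ResolutionError

DIASTOLIC_WINDOW_MS = 250.0
UPSLOPE_BAND = (0.2, 0.8)

#: transit times below this are unresolvable at any realistic sampling and
#: signal a degenerate (near-infinite PWV) or mislabeled curve pair
MIN_TRANSIT_MS = 1e-2


@dataclass(frozen=True)
class VelocityTimeCurve:
    """One cardiac cycle of maximal lumen velocity versus time at one site.

    ``time`` is in ms from the R-wave trigger, strictly increasing with
    uniform spacing; ``velocity`` is the maximal velocity over the lumen in
    cm/s, one value per reconstructed phase.
    """

    time: np.ndarray
    velocity: np.ndarray
    rr_interval: float
    site_label: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        velocity = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "velocity", velocity)
        if time.ndim != 1 or velocity.shape != time.shape:
            raise DataError("time and velocity must be 1-D arrays of equal length")
        if time.size < 10:
            raise DataError(f"curve needs >= 10 samples, got {time.size}")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise DataError("time must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-6 * abs(steps[0]):
            raise DataError("time spacing must be uniform (within 1e-6 relative)")
        if time[-1] > self.rr_interval + 1e-9:
            raise DataError("last sample time exceeds the RR interval")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def shifted(self, dt_ms: float) -> "VelocityTimeCurve":
        """Curve with the time axis translated by ``dt_ms`` (for tests)."""
        return VelocityTimeCurve(
            self.time + dt_ms, self.velocity, self.rr_interval + dt_ms, self.site_label
        )


@dataclass(frozen=True)
class OnsetFit:
    """Wave-foot fit: diastolic baseline, upslope line, and their intersection."""

    baseline_level: float
    upslope_slope: float
    upslope_intercept: float
    onset_time: float
    n_upslope_points: int
    foot_fallback: bool = False


@dataclass(frozen=True)
class PwvResult:
    path_length: float  # mm
    transit_time: float  # ms
    pwv: float  # m/s == mm/ms
    site_pair: str = ""


def max_velocity_curve(
    series: np.ndarray, mask: np.ndarray, rr_interval: float, site_label: str = ""
) -> VelocityTimeCurve:
    """Reduce a per-frame velocity image series to a maximal velocity-time curve.

    ``series`` has shape (n_frames, ny, nx); ``mask`` is a boolean lumen mask
    of shape (ny, nx). Frame ``i`` is sampled at ``i * rr_interval / n_frames``.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if series.ndim != 3:
        raise DataError("series must be (n_frames, ny, nx)")
    if mask.shape != series.shape[1:]:
        raise DataError(
            f"mask shape {mask.shape} does not match frame shape {series.shape[1:]}"
        )
    if not mask.any():
        raise DataError("lumen mask is empty")
    n = series.shape[0]
    spacing = rr_interval / n
    velocity = series[:, mask].max(axis=1)
    time = np.arange(n) * spacing
    return VelocityTimeCurve(time, velocity, rr_interval, site_label)


def diastolic_level(curve: VelocityTimeCurve) -> float:
    """Mean velocity over the final 250 ms of the cycle (diastolic baseline)."""
    span = curve.time[-1] - curve.time[0]
    if span < DIASTOLIC_WINDOW_MS:
        raise ResolutionError(
            f"curve spans {span:.1f} ms; >= {DIASTOLIC_WINDOW_MS:.0f} ms required"
        )
    window = curve.time > curve.rr_interval - DIASTOLIC_WINDOW_MS
    return float(curve.velocity[window].mean())


def upslope_fit(curve: VelocityTimeCurve, baseline: float) -> OnsetFit:
    """OLS line through the systolic upslope, 20-80% band above baseline.

    The systolic peak is the global maximum (earliest sample on ties).  The
    wave foot is the last sample at or below baseline before the peak; if the
    curve never returns to baseline the window starts at the first sample and
    the result is flagged.  The regression uses the samples strictly between
    foot and peak whose velocity lies within [baseline + 0.2 R, baseline + 0.8 R]
    inclusive, with R the peak-minus-baseline range.
    """
    v = curve.velocity
    t = curve.time
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    if peak <= baseline:
        raise FitError("no systolic peak above the diastolic baseline")
    below = np.nonzero(v[:peak_idx] <= baseline)[0]
    if below.size:
        foot_idx, fallback = int(below[-1]), False
    else:
        foot_idx, fallback = 0, True
    rng = peak - baseline
    lo, hi = baseline + UPSLOPE_BAND[0] * rng, baseline + UPSLOPE_BAND[1] * rng
    seg = slice(foot_idx + 1, peak_idx)
    sel = (v[seg] >= lo) & (v[seg] <= hi)
    tt, vv = t[seg][sel], v[seg][sel]
    if tt.size < 2:
        raise ResolutionError(
            f"only {tt.size} sample(s) in the 20-80% upslope band; >= 2 required"
        )
    slope, intercept = np.polyfit(tt, vv, 1)
    if slope <= 0:
        raise FitError(f"fitted upslope is non-positive ({slope:.4g} cm/s per ms)")
    return OnsetFit(
        baseline_level=baseline,
        upslope_slope=float(slope),
        upslope_intercept=float(intercept),
        onset_time=np.nan,
        n_upslope_points=int(tt.size),
        foot_fallback=fallback,
    )


def wave_onset(curve: VelocityTimeCurve) -> OnsetFit:
    """Wave-foot onset: intersection of diastolic baseline and upslope line."""
    baseline = diastolic_level(curve)
    fit = upslope_fit(curve, baseline)
    onset = (baseline - fit.upslope_intercept) / fit.upslope_slope
    if not (0.0 <= onset <= curve.rr_interval):
        raise FitError(
            f"onset {onset:.2f} ms outside [0, {curve.rr_interval:.1f}] ms"
        )
    return OnsetFit(
        baseline_level=baseline,
        upslope_slope=fit.upslope_slope,
        upslope_intercept=fit.upslope_intercept,
        onset_time=float(onset),
        n_upslope_points=fit.n_upslope_points,
        foot_fallback=fit.foot_fallback,
    )


def transit_time(
    proximal_curve: VelocityTimeCurve, distal_curve: VelocityTimeCurve
) -> float:
    """Transit time Delta-t = distal onset minus proximal onset, in ms."""
    dt = wave_onset(distal_curve).onset_time - wave_onset(proximal_curve).onset_time
    if dt <= 0:
        raise PropagationError(
            f"non-positive transit time ({dt:.3f} ms): sites mislabeled or fit failed"
        )
    if dt < MIN_TRANSIT_MS:
        raise PropagationError(
            f"transit time {dt:.4g} ms below the resolvable floor "
            f"({MIN_TRANSIT_MS} ms); wave speed is effectively unmeasurable"
        )
    return float(dt)


def aortic_path_length(*polylines: np.ndarray) -> float:
    """Centerline path length in mm, averaged over repeated tracings.

    Each polyline is an ordered (n, 2) or (n, 3) array of points in mm; its
    length is the sum of Euclidean segment lengths.
    """
    if not polylines:
        raise DataError("at least one centerline polyline is required")
    lengths = []
    for pl in polylines:
        pts = np.asarray(pl, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] not in (2, 3):
            raise DataError("each polyline must be an (n>=2, 2-or-3) point array")
        lengths.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
    return float(np.mean(lengths))


def pulse_wave_velocity(delta_x: float, delta_t: float, site_pair: str = "") -> PwvResult:
    """PWV = Delta-x / Delta-t; mm/ms is emitted unchanged as m/s."""
    if delta_x <= 0:
        raise DataError(f"path length must be positive, got {delta_x}")
    if delta_t <= 0:
        raise PropagationError(f"transit time must be positive, got {delta_t}")
    return PwvResult(
        path_length=float(delta_x),
        transit_time=float(delta_t),
        pwv=float(delta_x) / float(delta_t),
        site_pair=site_pair,
    )


def estimate_pwv(
    proximal_curve: VelocityTimeCurve,
    distal_curve: VelocityTimeCurve,
    path_length: float,
    site_pair: str = "",
) -> PwvResult:
    """End-to-end transit-time PWV from a curve pair and a path length."""
    dt = transit_time(proximal_curve, distal_curve)
    return pulse_wave_velocity(path_length, dt, site_pair=site_pair)
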