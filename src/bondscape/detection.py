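"""Detection and filtering of single unbinding events in AFM recordings.

Force–distance curves: the baseline (zero-force) level and its noise sd
are estimated from the far end of the retract by a least-absolute-
deviations line fit; candidate ruptures are local adhesion maxima that
drop back to baseline within 2 nm; events are *specific* when they fall in
the tether-length separation window (5–25 nm for binding, 10–25 nm for
extraction of the membrane-inserted polypeptide) and exceed five times the
baseline noise sd (≈15 pN at 3 pN noise). Only curves with exactly one
specific event are kept for analysis.

Force–time (height-clamp) traces: after running-average smoothing, a
binding event is a contiguous force excursion above baseline that starts
and ends at the baseline within the trace; events whose internal force
fluctuates by more than 5 pN are discarded. The event lifetime is the
excursion duration and the force step is the mean excursion force above
baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (
    ClampEvent,
    ClampTrace,
    DomainError,
    ForceCurve,
    InsufficientDataError,
    RuptureEvent,
)

#: Force floor (pN) replacing k×sd thresholds on noiseless synthetic curves.
_NOISELESS_FLOOR = 0.5


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the event-detection pipeline.

    The defaults implement the published filtering protocol: specific
    binding events at 5–25 nm from the contact point, extraction events at
    10–25 nm, a threshold of 5× the baseline noise sd, and a 5 pN
    fluctuation limit for clamp events. Windows are closed intervals.
    """

    specific_window: tuple[float, float] = (5.0, 25.0)  # nm, binding mode
    extraction_window: tuple[float, float] = (10.0, 25.0)  # nm, extraction mode
    threshold_multiplier: float = 5.0  # × baseline noise sd
    baseline_fraction: float = 0.3  # far fraction of the retract used for baseline
    smoothing_window: int = 5  # samples, running average
    ft_fluctuation_limit: float = 5.0  # pN, intra-event peak-to-trough limit
    baseline_tolerance_multiplier: float = 2.0  # × noise sd counts as "at baseline"
    return_distance: float = 2.0  # nm within which force must return to baseline

    def __post_init__(self) -> None:
        for lo, hi in (self.specific_window, self.extraction_window):
            if not (0 < lo < hi):
                raise DomainError("window bounds must be positive and ordered")
        if self.threshold_multiplier <= 0 or self.baseline_tolerance_multiplier <= 0:
            raise DomainError("multipliers must be > 0")
        if not (0 < self.baseline_fraction < 1):
            raise DomainError("baseline_fraction must be in (0, 1)")
        if self.smoothing_window < 1:
            raise DomainError("smoothing_window must be >= 1")


def _running_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + x.size]
    return out


def estimate_baseline(
    curve: ForceCurve, params: DetectionParams = DetectionParams()
) -> tuple[float, float]:
    """Estimate the baseline force offset and noise sd of a retract curve.

    A least-absolute-deviations line is fitted over the far
    ``baseline_fraction`` of separations (beyond the 25 nm window no
    specific event can occur, so that stretch is adhesion-free by
    construction of the filters). Returns (offset at the curve far end
    evaluated as a line, noise sd = 1.4826 × median absolute residual).
    The returned offset is the fitted line's value at the far-region
    midpoint; use :func:`baseline_line` for the full trend.
    """
    sep, force = curve.separation, curve.force
    n_base = int(round(params.baseline_fraction * sep.size))
    if n_base < 8:
        raise InsufficientDataError(
            f"baseline region has {n_base} samples; need at least 8"
        )
    x, y = sep[-n_base:], force[-n_base:]
    slope, intercept = _lad_line(x, y)
    resid = y - (intercept + slope * x)
    noise_sd = 1.4826 * float(np.median(np.abs(resid)))
    offset = float(intercept + slope * x.mean())
    return offset, noise_sd


def _lad_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-absolute-deviations line fit (slope, intercept) via quantile regression."""
    import statsmodels.api as sm

    if np.ptp(y) == 0:  # perfectly flat: QuantReg is degenerate, answer exact
        return 0.0, float(y[0])
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.QuantReg(y, X).fit(q=0.5)
            return float(res.params[1]), float(res.params[0])
        except Exception:
            coef = np.polyfit(x, y, 1)  # fallback: ordinary LS trend
            return float(coef[0]), float(coef[1])


def baseline_line(curve: ForceCurve, params: DetectionParams = DetectionParams()):
    """Baseline trend evaluated on the whole separation grid, plus noise sd."""
    sep, force = curve.separation, curve.force
    n_base = int(round(params.baseline_fraction * sep.size))
    if n_base < 8:
        raise InsufficientDataError("baseline region too short")
    x, y = sep[-n_base:], force[-n_base:]
    slope, intercept = _lad_line(x, y)
    resid = y - (intercept + slope * x)
    noise_sd = 1.4826 * float(np.median(np.abs(resid)))
    return intercept + slope * sep, noise_sd


def detect_rupture_events(
    curve: ForceCurve, params: DetectionParams = DetectionParams()
) -> tuple[list[RuptureEvent], float]:
    """Detect candidate rupture events on a retract curve.

    Candidates are local maxima of the baseline-corrected, lightly
    smoothed adhesion force that show an abrupt detachment within
    ``return_distance`` nm after the peak: the force must fall back to
    within the baseline tolerance, or — when another tether still carries
    load, as on multi-event curves whose WLC rises overlap — drop by at
    least half the peak height. Events are returned in ascending rupture
    distance together with the baseline noise sd (needed by
    :func:`classify_specific`); classification is a separate step.
    """
    if curve.segment != "retract":
        raise DomainError("rupture detection requires a retract segment")
    trend, noise_sd = baseline_line(curve, params)
    detrended = curve.force - trend
    smoothed = _running_average(detrended, params.smoothing_window)
    # lightly smoothed version for the peak-force readout: the full smoothing
    # window biases the peak low on steep rises, raw samples are noisy
    lightly = _running_average(detrended, 3)

    min_height = max(3.0 * noise_sd, _NOISELESS_FLOOR)
    peaks, _ = find_peaks(smoothed, height=min_height, prominence=min_height)
    tol = max(params.baseline_tolerance_multiplier * noise_sd, _NOISELESS_FLOOR)
    sep = curve.separation

    events = []
    for p in peaks:
        after = (sep > sep[p]) & (sep <= sep[p] + params.return_distance)
        drop_target = max(tol, 0.5 * smoothed[p])
        if not np.any(smoothed[after] <= drop_target):
            continue
        lo = max(p - params.smoothing_window, 0)
        hi = min(p + params.smoothing_window + 1, detrended.size)
        apex = lo + int(np.argmax(lightly[lo:hi]))
        lr = event_loading_rate(curve, apex, smoothed)
        events.append(
            RuptureEvent(
                rupture_distance=float(sep[apex]),
                rupture_force=float(lightly[apex]),
                loading_rate=lr,
                specific=False,
                curve_id=curve.curve_id,
            )
        )
    events.sort(key=lambda e: e.rupture_distance)
    return events, noise_sd


def classify_specific(
    event: RuptureEvent,
    noise_sd: float,
    params: DetectionParams = DetectionParams(),
    mode: str = "binding",
) -> bool:
    """Is an event specific? Inside the mode's distance window and above 5×sd."""
    if mode == "binding":
        lo, hi = params.specific_window
    elif mode == "extraction":
        lo, hi = params.extraction_window
    else:
        raise DomainError(f"mode must be binding|extraction, got {mode!r}")
    threshold = max(params.threshold_multiplier * noise_sd, _NOISELESS_FLOOR)
    return (lo <= event.rupture_distance <= hi) and event.rupture_force >= threshold


def select_single_event(
    events: list[RuptureEvent],
) -> tuple[RuptureEvent | None, str]:
    """Keep a curve only if it shows exactly one specific event.

    Returns (event, "ok"), (None, "empty") or (None, "multiple"); the
    reason string feeds the per-curve discard log.
    """
    specific = [e for e in events if e.specific]
    if len(specific) == 1:
        return specific[0], "ok"
    if len(specific) == 0:
        return None, "empty"
    return None, "multiple"


def event_loading_rate(
    curve: ForceCurve,
    peak_index: int,
    detrended: np.ndarray | None = None,
) -> float:
    """Loading rate (pN/s) from the force rise preceding a rupture.

    Least-squares slope of force against time over the contiguous stretch
    before the peak where the force lies between 30% and 95% of the peak
    force; time is reconstructed as separation / pulling velocity. Returns
    NaN when fewer than 6 samples lie on the rise (the event is kept for
    force distributions but carries no loading rate).
    """
    if detrended is None:
        trend, _ = baseline_line(curve)
        detrended = curve.force - trend
    peak_force = detrended[peak_index]
    lo, hi = 0.30 * peak_force, 0.95 * peak_force
    idx = []
    for i in range(peak_index, -1, -1):
        if detrended[i] > hi:
            continue
        if detrended[i] < lo:
            break
        idx.append(i)
    if len(idx) < 6:
        return math.nan
    idx = np.array(idx[::-1])
    v_nm_per_s = curve.pulling_velocity * 1000.0
    time = curve.separation[idx] / v_nm_per_s
    slope = float(np.polyfit(time, detrended[idx], 1)[0])
    return slope if slope > 0 else math.nan


def analyze_curve(
    curve: ForceCurve,
    params: DetectionParams = DetectionParams(),
    mode: str = "binding",
) -> tuple[RuptureEvent | None, str]:
    """Full single-curve pipeline: detect, classify, apply the single-event rule."""
    events, noise_sd = detect_rupture_events(curve, params)
    events = [
        RuptureEvent(
            rupture_distance=e.rupture_distance,
            rupture_force=e.rupture_force,
            loading_rate=e.loading_rate,
            specific=classify_specific(e, noise_sd, params, mode),
            curve_id=e.curve_id,
        )
        for e in events
    ]
    return select_single_event(events)


def extract_clamp_events(
    trace: ClampTrace, params: DetectionParams = DetectionParams()
) -> list[ClampEvent]:
    """Extract single binding events from a height-clamp force–time trace.

    The trace is smoothed with a ``smoothing_window`` running average; its
    baseline level and noise are taken as the median and scaled median
    absolute deviation (events are sparse, so both are robust to them). An
    event is a contiguous excursion above baseline + tolerance that starts
    and ends inside the trace and whose peak clears the detection
    threshold (``threshold_multiplier`` × noise sd, the same five-sigma
    rule as for force–distance events — it keeps correlated noise wiggles
    above the 2σ boundary tolerance from counting as events). The
    intra-event fluctuation check
    (peak-to-trough > ``ft_fluctuation_limit`` → discard) is evaluated on
    the excursion interior, excluding one smoothing window at each edge
    where the running average ramps.
    """
    smoothed = _running_average(trace.force, params.smoothing_window)
    baseline = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - baseline)))
    noise_sd = 1.4826 * mad
    tol = max(params.baseline_tolerance_multiplier * noise_sd, _NOISELESS_FLOOR)

    above = smoothed > baseline + tol
    # contiguous runs of `above`
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]]) if edges.size else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [above.size - 1]

    peak_min = max(params.threshold_multiplier * noise_sd, _NOISELESS_FLOOR)
    dt = trace.dt
    events = []
    for i0, i1 in zip(sorted(starts), sorted(ends)):
        if i0 <= 0 or i1 >= above.size - 1:
            continue  # does not start and end at baseline within the trace
        if smoothed[i0:i1 + 1].max() - baseline < peak_min:
            continue  # noise wiggle, not a binding event
        w = params.smoothing_window
        interior = smoothed[i0 + w:i1 - w + 1]
        if interior.size == 0:
            interior = smoothed[i0:i1 + 1]
        if float(interior.max() - interior.min()) > params.ft_fluctuation_limit:
            continue
        force_step = float(interior.mean() - baseline)
        lifetime = (i1 - i0 + 1) * dt
        if force_step <= 0 or lifetime <= 0:
            continue
        events.append(
            ClampEvent(lifetime=lifetime, force_step=force_step, trace_id=trace.trace_id)
        )
    return events
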