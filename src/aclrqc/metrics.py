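"""Per-procedure QC metrics from a load/displacement trace.

Segments a trace into the five protocol phases, detects the rupture event
(abrupt load drop during the injury ramp) and the diagnostic "catch"
(secondary load bearing after failure), and computes the QC metric vector:
rupture displacement/load, ultimate displacement/load, linear elongation
stiffness, total creep during preloading and preconditioning, and percent
errors in preconditioning load amplitudes and ultimate displacement.

All displacement metrics on the injury ramp are measured from ramp start,
so successful ruptures land in the expected 0.9-1.3 mm range within the
1.5 mm commanded ramp.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .protocol import (
    DEFAULT_LIMITS,
    ControlMode,
    LoadingProtocol,
    MotionLimits,
    PhaseShape,
    default_protocol,
    phase_duration,
)
from .trace_io import Trace

__all__ = [
    "PhaseSegmentation",
    "RuptureEvent",
    "RuptureMetrics",
    "StiffnessFit",
    "SpringCheckResult",
    "DetectionParams",
    "SegmentationError",
    "MetricError",
    "segment_phases",
    "compute_creep",
    "precond_amplitude_error",
    "detect_rupture",
    "detect_catch",
    "fit_stiffness",
    "extract_metrics",
    "analyze_spring_check",
]


class SegmentationError(ValueError):
    """Trace cannot be aligned to the protocol phases."""


class MetricError(ValueError):
    """A metric's preconditions are not met on this trace."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds for event detection and metric windows.

    The drop criterion is deliberately conservative: a candidate rupture is
    a loss, within a ``window_s`` sliding window, of at least
    ``abs_min_drop`` newtons or ``frac_min_drop`` of the running ramp
    maximum, whichever is larger.
    """

    window_s: float = 0.010  # sliding drop-detection window (s)
    abs_min_drop: float = 1.0  # N
    frac_min_drop: float = 0.15  # fraction of running ramp maximum
    trough_window_s: float = 0.030  # post-drop trough search span (s)
    catch_refrac: float = 0.25  # re-loading fraction of drop magnitude
    floor_min: float = 0.5  # N, post-drop load floor for a catch
    stiffness_window_mm: float = 0.3
    stiffness_min_r2: float = 0.99
    stiffness_stride_fraction: float = 1.0  # window advance, fraction of width
    stiffness_smooth_samples: int = 1  # optional moving-average width for the fit
    creep_anchor_fraction: float = 0.95  # of the preload target
    extremum_min_separation_s: float = 0.2
    extremum_min_prominence: float = 0.5  # N, on the smoothed signal
    precond_smooth_s: float = 0.05  # extremum localisation smoothing
    precond_value_halfwidth_s: float = 0.025  # raw-signal averaging window
    ramp_onset_rate_fraction: float = 0.5  # of commanded ramp rate
    ramp_onset_sustain: int = 5  # samples


DEFAULT_PARAMS = DetectionParams()


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open per-phase sample-index intervals ``[start, stop)``."""

    intervals: Tuple[Tuple[int, int], ...]
    alignment_offset: float  # s, time of phase-1 start on the trace clock
    method: str  # "command_channel" | "signal_detected"

    def __post_init__(self) -> None:
        prev = None
        for start, stop in self.intervals:
            if stop < start:
                raise SegmentationError("interval stop before start")
            if prev is not None and start < prev:
                raise SegmentationError("intervals overlap or are unordered")
            prev = stop

    def phase(self, k: int) -> Tuple[int, int]:
        """1-based phase interval."""
        return self.intervals[k - 1]


@dataclass(frozen=True)
class RuptureEvent:
    index: int  # global sample index of the rupture point
    displacement_at_rupture: float  # mm from ramp start
    load_at_rupture: float  # N
    drop_magnitude: float  # N
    drop_duration: float  # s
    trough_index: int
    drop_count: int

    def __post_init__(self) -> None:
        if self.drop_magnitude <= 0:
            raise ValueError("drop_magnitude must be positive")


@dataclass(frozen=True)
class StiffnessFit:
    stiffness: float  # N/mm
    r_squared: float
    window: Tuple[float, float]  # mm from ramp start
    reliable: bool  # True iff r_squared >= the configured threshold


@dataclass
class RuptureMetrics:
    """The per-procedure QC metric vector."""

    rupture_displacement: Optional[float]
    rupture_load: Optional[float]
    ultimate_displacement: float
    ultimate_load: float
    linear_stiffness: Optional[float]
    stiffness_r2: Optional[float]
    stiffness_reliable: Optional[bool]
    total_creep: float
    precond_amplitude_error_pct: float
    displacement_error_pct: float
    catch_detected: Optional[bool]
    drop_count: int
    post_drop_floor_load: Optional[float]

    def __post_init__(self) -> None:
        if (
            self.rupture_load is not None
            and self.ultimate_load < self.rupture_load - 1e-9
        ):
            raise ValueError("ultimate_load must be >= rupture_load")
        if self.precond_amplitude_error_pct < 0 or self.displacement_error_pct < 0:
            raise ValueError("percent errors must be >= 0")


@dataclass(frozen=True)
class SpringCheckResult:
    measured_stiffness: float  # N/mm
    deviation_pct: float
    precond_amplitude_error_pct: float
    instrument_fault: bool  # a rupture-like drop was seen on a spring
    passed: bool


# ---------------------------------------------------------------------------


def _nominal_durations(
    protocol: LoadingProtocol, limits: MotionLimits
) -> List[float]:
    return [phase_duration(ph, limits) for ph in protocol.phases]


def _ramp_phase_index(protocol: LoadingProtocol) -> int:
    return list(protocol.phases).index(protocol.injury_ramp)


def segment_phases(
    trace: Trace,
    protocol: Optional[LoadingProtocol] = None,
    limits: MotionLimits = DEFAULT_LIMITS,
    params: DetectionParams = DEFAULT_PARAMS,
) -> PhaseSegmentation:
    """Locate the protocol phases on the trace.

    Uses the logged command-phase channel verbatim when present; otherwise
    detects the injury-ramp onset (displacement rate exceeding half the
    commanded ramp rate, sustained for several samples) and lays out the
    remaining phases by their nominal durations anchored to that onset.
    """
    if protocol is None:
        protocol = default_protocol()
    n_phases = len(protocol.phases)
    n = trace.n_samples
    fs = trace.sample_rate

    if trace.command_phase is not None:
        ch = np.asarray(trace.command_phase)
        intervals = []
        for k in range(1, n_phases + 1):
            where = np.flatnonzero(ch == k)
            if where.size == 0:
                intervals.append((intervals[-1][1] if intervals else 0,) * 2)
            else:
                intervals.append((int(where[0]), int(where[-1]) + 1))
        seg = PhaseSegmentation(
            intervals=tuple(intervals),
            alignment_offset=float(trace.time[0]),
            method="command_channel",
        )
    else:
        k_ramp = _ramp_phase_index(protocol)
        ramp_rate = protocol.injury_ramp.rate
        rate = np.gradient(trace.displacement, 1.0 / fs)
        fast = rate > params.ramp_onset_rate_fraction * ramp_rate
        sustain = params.ramp_onset_sustain
        run = np.convolve(fast.astype(int), np.ones(sustain, dtype=int), "valid")
        hits = np.flatnonzero(run == sustain)
        if hits.size == 0:
            raise SegmentationError(
                "injury-ramp onset not found: displacement rate never exceeded "
                f"{params.ramp_onset_rate_fraction:.0%} of {ramp_rate} mm/s "
                f"for {sustain} consecutive samples"
            )
        onset = int(hits[0])
        # back off to where motion actually begins
        slow = 0.05 * ramp_rate
        while onset > 0 and rate[onset - 1] > slow:
            onset -= 1
        durations = _nominal_durations(protocol, limits)
        t_onset = onset / fs
        t_start = t_onset - sum(durations[:k_ramp])
        bounds = np.concatenate([[t_start], t_start + np.cumsum(durations)])
        idx = np.clip(np.round(bounds * fs).astype(int), 0, n)
        intervals = tuple(
            (int(idx[k]), int(idx[k + 1])) for k in range(n_phases)
        )
        seg = PhaseSegmentation(
            intervals=intervals,
            alignment_offset=float(trace.time[0] + t_start),
            method="signal_detected",
        )

    k_ramp = _ramp_phase_index(protocol)
    rs, re = seg.phase(k_ramp + 1)
    if re <= rs:
        raise SegmentationError("empty injury-ramp interval")
    if seg.intervals[-1][1] > n:
        raise SegmentationError("trace is shorter than the protocol")
    return seg


def compute_creep(
    trace: Trace,
    seg: PhaseSegmentation,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> float:
    """Total creep (mm): displacement gained between preload seating and the
    end of the second hold.

    Anchored at the first phase-1 sample where load reaches 95 % of the
    preload target; ends at the last sample of phase 3.
    """
    if protocol is None:
        protocol = default_protocol()
    preload = protocol.phases[0].target
    s1, e1 = seg.phase(1)
    _, e3 = seg.phase(3)
    threshold = params.creep_anchor_fraction * preload
    rel = np.flatnonzero(trace.load[s1:e1] >= threshold)
    if rel.size == 0:
        raise MetricError(
            f"preload target never reached: phase-1 load stayed below "
            f"{threshold:.3g} N"
        )
    anchor = s1 + int(rel[0])
    return float(trace.displacement[e3 - 1] - trace.displacement[anchor])


def precond_amplitude_error(
    trace: Trace,
    seg: PhaseSegmentation,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> float:
    """Mean preconditioning amplitude error in percent.

    Per cycle the load peak P and valley V are located (local extrema with a
    minimum separation); the error is the mean over cycles of
    (|P - target|/target + |V - lower|/lower)/2, as a percentage.

    Extrema are located on a lightly smoothed copy of the load (noise spikes
    otherwise masquerade as extrema) and their values measured as short
    window means of the raw signal, which leaves the amplitude estimate
    unbiased by either the smoothing or the noise.
    """
    if protocol is None:
        protocol = default_protocol()
    sin_phase = next(
        ph for ph in protocol.phases if ph.shape is PhaseShape.SINUSOID
    )
    hi, lo = sin_phase.target, sin_phase.secondary_target
    s2, e2 = seg.phase(2)
    load = trace.load[s2:e2]
    fs = trace.sample_rate
    k = max(1, int(round(params.precond_smooth_s * fs)) | 1)  # odd width
    if load.size > k > 1:
        smooth = np.convolve(load, np.ones(k) / k, mode="same")
        smooth[: k // 2] = smooth[k // 2]
        smooth[-(k // 2):] = smooth[-(k // 2) - 1]
    else:
        smooth = load
    dist = max(1, int(round(params.extremum_min_separation_s * fs)))
    prom = params.extremum_min_prominence
    peaks, _ = find_peaks(smooth, distance=dist, prominence=prom)
    valleys, _ = find_peaks(-smooth, distance=dist, prominence=prom)
    n_cycles = min(peaks.size, valleys.size)
    if n_cycles < 2:
        raise MetricError(
            f"fewer extrema than preconditioning cycles: found {peaks.size} "
            f"peaks and {valleys.size} valleys, need at least 2 of each"
        )
    h = max(0, int(round(params.precond_value_halfwidth_s * fs)))

    def window_mean(idx):
        return np.array(
            [np.mean(load[max(0, i - h): min(load.size, i + h + 1)]) for i in idx]
        )

    p = window_mean(peaks[:n_cycles])
    v = window_mean(valleys[:n_cycles])
    per_cycle = 0.5 * (np.abs(p - hi) / hi + np.abs(v - lo) / lo)
    return float(100.0 * np.mean(per_cycle))


def detect_rupture(
    trace: Trace,
    seg: PhaseSegmentation,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> Optional[RuptureEvent]:
    """Scan the injury ramp for an abrupt load drop.

    A candidate drop at sample i is (max load over the trailing window)
    minus load[i], qualifying when it reaches max(abs_min_drop,
    frac_min_drop x running ramp maximum).  The rupture point is the last
    local maximum preceding the first qualifying drop.  Returns ``None``
    when no drop qualifies.
    """
    if protocol is None:
        protocol = default_protocol()
    k_ramp = _ramp_phase_index(protocol)
    rs, re = seg.phase(k_ramp + 1)
    load = trace.load[rs:re]
    disp = trace.displacement[rs:re] - trace.displacement[rs]
    fs = trace.sample_rate
    w = max(2, int(round(params.window_s * fs)))
    if load.size <= w:
        return None

    # trailing-window maximum and its index at each sample
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(load, w)  # windows[i] = load[i : i + w]
    win_max = windows.max(axis=1)
    win_arg = windows.argmax(axis=1)
    ends = np.arange(w - 1, load.size)  # window end index
    drop = win_max - load[ends]
    runmax = np.maximum.accumulate(load)[ends]
    threshold = np.maximum(params.abs_min_drop, params.frac_min_drop * runmax)
    qualifying = drop >= threshold
    if not np.any(qualifying):
        return None

    # disjoint candidate groups -> drop count
    q = qualifying.astype(int)
    group_starts = np.flatnonzero(np.diff(np.concatenate([[0], q])) == 1)
    drop_count = int(group_starts.size)

    first = int(np.flatnonzero(qualifying)[0])
    j = int(win_arg[first] + first)  # rupture point: peak within the window
    # trough: minimum over a bounded post-rupture span
    span = max(2, int(round(params.trough_window_s * fs)))
    trough_rel = int(np.argmin(load[j : min(j + span, load.size)]))
    trough = j + trough_rel
    magnitude = float(load[j] - load[trough])
    if magnitude <= 0:
        return None
    d_star, p_star = _refine_rupture_point(disp, load, j, trough)
    return RuptureEvent(
        index=rs + j,
        displacement_at_rupture=d_star,
        load_at_rupture=p_star,
        drop_magnitude=magnitude,
        drop_duration=trough_rel / fs,
        trough_index=rs + trough,
        drop_count=drop_count,
    )


def _refine_rupture_point(
    disp: np.ndarray, load: np.ndarray, j: int, trough: int, n_pre: int = 20
) -> Tuple[float, float]:
    """Sub-sample rupture point: intersection of the pre-drop regression
    line with the falling-edge line.

    The sampled peak sits up to one sample below/before the true failure
    point; intersecting the two local lines removes that discretization
    bias and averages out the single-sample noise.  Falls back to the raw
    sample when the geometry degenerates.
    """
    d_j, p_j = float(disp[j]), float(load[j])
    s = max(0, j - n_pre)
    if j - s >= 3 and disp[j] - disp[s] > 0:
        k1, b1 = np.polyfit(disp[s : j + 1], load[s : j + 1], 1)
    else:
        return d_j, p_j
    e = max(trough, j + 1)
    if e > load.size - 1:
        return d_j, p_j
    dd = disp[j : e + 1]
    ll = load[j : e + 1]
    steps_d = np.diff(dd)
    if np.any(steps_d <= 0):
        return d_j, p_j
    # steepest falling step: lies fully inside the drop, unlike a chord to
    # the trough which gets diluted by the flat post-drop region
    slopes = np.diff(ll) / steps_d
    i = int(np.argmin(slopes))
    k2 = float(slopes[i])
    b2 = float(ll[i] - k2 * dd[i])
    if k2 >= k1:  # not actually falling relative to the loading line
        return d_j, p_j
    d_star = (b2 - b1) / (k1 - k2)
    # keep the refinement local: within one sample of the detected peak
    lo = float(disp[max(0, j - 1)])
    hi = float(disp[min(disp.size - 1, j + 1)])
    d_star = min(max(d_star, lo), hi)
    return float(d_star), float(k1 * d_star + b1)


def detect_catch(
    trace: Trace,
    seg: PhaseSegmentation,
    event: RuptureEvent,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> Tuple[bool, float]:
    """Decide whether the joint "caught" after the rupture.

    A catch is called when, between the drop trough and the end of the
    ramp, the load either re-rises by at least ``catch_refrac`` of the drop
    magnitude or never falls below ``floor_min``.  Also returns the minimum
    post-drop load (the floor).
    """
    if protocol is None:
        protocol = default_protocol()
    k_ramp = _ramp_phase_index(protocol)
    rs, re = seg.phase(k_ramp + 1)
    if not rs <= event.index < re:
        raise MetricError("rupture event lies outside the injury ramp")
    region = trace.load[event.trough_index : re]
    if region.size == 0:
        region = trace.load[event.trough_index : event.trough_index + 1]
    floor = float(np.min(region))
    rise = float(np.max(region) - region[0])
    caught = rise >= params.catch_refrac * event.drop_magnitude or (
        floor >= params.floor_min
    )
    return caught, floor


def _window_slopes(d: np.ndarray, y: np.ndarray, width_mm: float, stride: int = 1):
    """Least-squares slope and R^2 of y vs d over sliding windows.

    Windows advance by ``stride`` samples; O(1) per window via cumulative
    sums.  Yields (start, stop, slope, r2).
    """
    n = d.size
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    cd = np.concatenate([[0.0], np.cumsum(d)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cdd = np.concatenate([[0.0], np.cumsum(d * d)])
    cdy = np.concatenate([[0.0], np.cumsum(d * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    stops = np.searchsorted(d, d + width_mm, side="right")
    out = []
    for s in range(0, n, max(1, stride)):
        e = int(stops[s])
        if e - s < 5 or d[e - 1] - d[s] < 0.9 * width_mm:
            continue
        m = c1[e] - c1[s]
        sd = cd[e] - cd[s]
        sy = cy[e] - cy[s]
        sdd = cdd[e] - cdd[s]
        sdy = cdy[e] - cdy[s]
        syy = cyy[e] - cyy[s]
        vard = sdd - sd * sd / m
        vary = syy - sy * sy / m
        cov = sdy - sd * sy / m
        if vard <= 0:
            continue
        slope = cov / vard
        if vary <= 1e-30:
            r2 = 0.0  # constant signal: no linear elongation information
        else:
            r2 = min(1.0, cov * cov / (vard * vary))
        out.append((s, e, slope, r2))
    return out


def fit_stiffness(
    trace: Trace,
    seg: PhaseSegmentation,
    event: Optional[RuptureEvent] = None,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> StiffnessFit:
    """Linear elongation stiffness (N/mm) on the injury ramp.

    Least-squares slope of load vs displacement over a sliding window
    (default 0.3 mm, advancing by its own width so windows do not overlap)
    restricted to the pre-rupture ramp; reports the maximum slope among
    windows with R^2 >= 0.99, falling back to the best-R^2 window with
    ``reliable=False``.  Non-overlapping windows keep the max-slope rule
    from riding noise maxima.
    """
    if protocol is None:
        protocol = default_protocol()
    k_ramp = _ramp_phase_index(protocol)
    rs, re = seg.phase(k_ramp + 1)
    stop = event.index if event is not None else re
    d = trace.displacement[rs:stop] - trace.displacement[rs]
    y = trace.load[rs:stop]
    if d.size < 5 or (d[-1] - d[0]) < params.stiffness_window_mm:
        raise MetricError(
            f"pre-rupture ramp spans {0.0 if d.size == 0 else d[-1] - d[0]:.3g} mm, "
            f"shorter than the {params.stiffness_window_mm:g} mm fit window"
        )
    k = params.stiffness_smooth_samples
    if k > 1 and y.size > k:
        kernel = np.ones(k) / k
        y = np.convolve(y, kernel, mode="valid")
        half = (k - 1) // 2
        d = d[half : half + y.size]
    med_dd = float(np.median(np.diff(d))) if d.size > 1 else 0.0
    stride = 1
    if med_dd > 0:
        stride = max(
            1,
            int(
                round(
                    params.stiffness_stride_fraction
                    * params.stiffness_window_mm
                    / med_dd
                )
            ),
        )
    fits = _window_slopes(d, y, params.stiffness_window_mm, stride)
    if not fits:
        raise MetricError("no full-width stiffness window fits the pre-rupture ramp")
    good = [f for f in fits if f[3] >= params.stiffness_min_r2]
    if good:
        s, e, slope, r2 = max(good, key=lambda f: f[2])
        reliable = True
    else:
        s, e, slope, r2 = max(fits, key=lambda f: f[3])
        reliable = False
    return StiffnessFit(
        stiffness=float(slope),
        r_squared=float(r2),
        window=(float(d[s]), float(d[e - 1])),
        reliable=reliable,
    )


def extract_metrics(
    trace: Trace,
    seg: PhaseSegmentation,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> RuptureMetrics:
    """Compute the full QC metric vector for one procedure."""
    if protocol is None:
        protocol = default_protocol()
    k_ramp = _ramp_phase_index(protocol)
    rs, re = seg.phase(k_ramp + 1)
    ramp_disp = trace.displacement[rs:re] - trace.displacement[rs]
    ramp_load = trace.load[rs:re]
    commanded = protocol.injury_ramp.target

    ultimate_displacement = float(np.max(ramp_disp))
    ultimate_load = float(np.max(ramp_load))
    displacement_error_pct = (
        100.0 * abs(ultimate_displacement - commanded) / commanded
    )
    total_creep = compute_creep(trace, seg, protocol, params)
    amp_err = precond_amplitude_error(trace, seg, protocol, params)

    event = detect_rupture(trace, seg, protocol, params)
    if event is not None:
        caught, floor = detect_catch(trace, seg, event, protocol, params)
        # the sub-sample refined rupture point is part of the ramp, so the
        # ramp maximum can never sit below it
        ultimate_load = max(ultimate_load, event.load_at_rupture)
    else:
        caught, floor = None, None

    try:
        fit = fit_stiffness(trace, seg, event, protocol, params)
        stiffness, r2, reliable = fit.stiffness, fit.r_squared, fit.reliable
    except MetricError:
        stiffness, r2, reliable = None, None, None

    return RuptureMetrics(
        rupture_displacement=(
            event.displacement_at_rupture if event is not None else None
        ),
        rupture_load=event.load_at_rupture if event is not None else None,
        ultimate_displacement=ultimate_displacement,
        ultimate_load=ultimate_load,
        linear_stiffness=stiffness,
        stiffness_r2=r2,
        stiffness_reliable=reliable,
        total_creep=total_creep,
        precond_amplitude_error_pct=amp_err,
        displacement_error_pct=displacement_error_pct,
        catch_detected=caught,
        drop_count=event.drop_count if event is not None else 0,
        post_drop_floor_load=floor,
    )


def analyze_spring_check(
    trace: Trace,
    nominal_stiffness: float,
    tolerance_pct: float = 5.0,
    protocol: Optional[LoadingProtocol] = None,
    params: DetectionParams = DEFAULT_PARAMS,
) -> SpringCheckResult:
    """Daily calibration-spring run analysis.

    A spring trace must show the nominal stiffness (within
    ``tolerance_pct``) and no rupture-like drop; a drop on a spring flags
    an instrument fault and fails the check.
    """
    if nominal_stiffness <= 0:
        raise ValueError("nominal_stiffness must be positive")
    if protocol is None:
        protocol = default_protocol()
    seg = segment_phases(trace, protocol, params=params)
    event = detect_rupture(trace, seg, protocol, params)
    fault = event is not None
    fit = fit_stiffness(trace, seg, None, protocol, params)
    deviation = 100.0 * abs(fit.stiffness - nominal_stiffness) / nominal_stiffness
    amp_err = precond_amplitude_error(trace, seg, protocol, params)
    return SpringCheckResult(
        measured_stiffness=fit.stiffness,
        deviation_pct=deviation,
        precond_amplitude_error_pct=amp_err,
        instrument_fault=fault,
        passed=(deviation <= tolerance_pct) and not fault,
    )
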