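"""On-line sweat-event detection by derivative thresholding.

A sweat event creates a conductive saline layer at the sensor–skin
interface: the sweat-sensitive channel rises fast and decays slowly, so a
positive-going threshold crossing of its (smoothed) time derivative is an
easy and effective on-line detector.  The threshold is selected from a pool
of candidates as the one with the best trade-off between missed and false
detections (F1 score against annotated events).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .session_io import Session

__all__ = [
    "SweatEvent",
    "DetectorConfig",
    "channel_derivative",
    "detect_events",
    "detect_session_events",
    "select_threshold",
    "first_rbg_after",
]


@dataclass
class SweatEvent:
    """A detected perturbation on the sweat-sensitive channel."""

    detection_time_s: float
    peak_derivative: float  # a.u./s
    first_rbg_after_s: float | None = None


@dataclass
class DetectorConfig:
    sweat_channel: int
    threshold: float  # TH, a.u./s, > 0
    smooth_window: int = 5  # moving-average width, samples
    refractory_s: float = 600.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.refractory_s < 0:
            raise ValueError("refractory must be ≥ 0")
        if self.smooth_window < 1:
            raise ValueError("smoothing window must be ≥ 1")


def channel_derivative(session: Session, config: DetectorConfig) -> np.ndarray:
    """Smoothed time derivative of the sweat channel (a.u./s).

    Moving-average smoothing of width ``smooth_window`` followed by a
    central finite difference on the uniform grid; the endpoints use
    one-sided differences.
    """
    if not 0 <= config.sweat_channel < session.n_channels:
        raise ValueError("sweat_channel out of range")
    if config.smooth_window >= session.n_samples:
        raise ValueError("smoothing window must be shorter than the session")
    y = session.X[config.sweat_channel]
    if config.smooth_window > 1:
        y = uniform_filter1d(y, config.smooth_window, mode="nearest")
    d = np.empty_like(y)
    dt = session.dt
    d[1:-1] = (y[2:] - y[:-2]) / (2 * dt)
    d[0] = (y[1] - y[0]) / dt
    d[-1] = (y[-1] - y[-2]) / dt
    return d


def detect_events(
    t: np.ndarray, derivative: np.ndarray, config: DetectorConfig
) -> list[SweatEvent]:
    """Threshold the derivative series into events.

    An event opens at the first sample with derivative > TH when no event
    was opened within the refractory window; later super-threshold samples
    inside the refractory window merge into the open event (updating its
    peak derivative).  Only positive-going excursions trigger.
    """
    events: list[SweatEvent] = []
    for i in np.flatnonzero(derivative > config.threshold):
        if events and t[i] - events[-1].detection_time_s < config.refractory_s:
            ev = events[-1]
            ev.peak_derivative = max(ev.peak_derivative, float(derivative[i]))
        else:
            events.append(SweatEvent(float(t[i]), float(derivative[i])))
    return events


def first_rbg_after(session: Session, event: SweatEvent) -> float | None:
    """Time of the first RBG strictly after the detection, if any."""
    later = session.rbg_times[session.rbg_times > event.detection_time_s]
    return float(later[0]) if later.size else None


def detect_session_events(
    session: Session, config: DetectorConfig
) -> list[SweatEvent]:
    """Detect events on a session and attach each one's next RBG time."""
    d = channel_derivative(session, config)
    events = detect_events(session.t, d, config)
    for ev in events:
        ev.first_rbg_after_s = first_rbg_after(session, ev)
    return events


def _match_counts(
    detections: Sequence[float], truths: Sequence[float], window_s: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to annotated onsets."""
    truths = list(truths)
    used = [False] * len(truths)
    tp = 0
    for det in detections:
        best, best_gap = -1, np.inf
        for j, onset in enumerate(truths):
            gap = abs(det - onset)
            if not used[j] and gap <= window_s and gap < best_gap:
                best, best_gap = j, gap
        if best >= 0:
            used[best] = True
            tp += 1
    fp = len(detections) - tp
    fn = len(truths) - tp
    return tp, fp, fn


def select_threshold(
    candidates: Sequence[float],
    annotated_sessions: Sequence[tuple[Session, Sequence[float]]],
    config: DetectorConfig,
    matching_window_s: float = 600.0,
) -> float:
    """Pick the candidate TH with the best missed/false trade-off (max F1).

    ``annotated_sessions`` pairs each session with its true event onsets.
    A detection matches a true event when within ``matching_window_s``.
    Ties break toward the larger TH (fewer false alarms); if every
    candidate misses everything, the largest TH is returned with a warning.
    """
    candidates = [float(th) for th in np.asarray(candidates).ravel()]
    if not candidates:
        raise ValueError("no candidate thresholds")
    if not annotated_sessions:
        raise ValueError("no annotated sessions")
    best_th, best_f1 = None, -1.0
    for th in sorted(candidates):
        tp = fp = fn = 0
        for session, onsets in annotated_sessions:
            cfg = DetectorConfig(
                sweat_channel=config.sweat_channel,
                threshold=float(th),
                smooth_window=config.smooth_window,
                refractory_s=config.refractory_s,
            )
            events = detect_session_events(session, cfg)
            a, b, c = _match_counts(
                [e.detection_time_s for e in events], onsets, matching_window_s
            )
            tp, fp, fn = tp + a, fp + b, fn + c
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 >= best_f1:  # ≥ keeps the larger TH on ties (sorted ascending)
            best_th, best_f1 = float(th), f1
    if best_f1 == 0.0:
        warnings.warn("all candidate thresholds miss all events (F1 = 0)")
    return best_th
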