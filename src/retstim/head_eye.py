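"""Head-velocity event detection and event-triggered eye averages.

Events are samples where a gyroscope component exceeds 2.5x the median
velocity of its direction (median taken over the signed half of the
trace for that direction), thinned by a 50-ms refractory period.  The
eye trace snippets around each event are aligned at t = 0 and averaged,
optionally min-max normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "HeadEventSet",
    "TriggeredAverage",
    "head_velocity_events",
    "triggered_eye_average",
    "dominant_pitch_frequency",
]

DIRECTIONS = ("right", "left", "up", "down")
_POSITIVE = {"right": True, "up": True, "left": False, "down": False}


@dataclass
class HeadEventSet:
    direction: str
    threshold_dps: float
    event_times: np.ndarray
    event_velocities: np.ndarray
    refractory_s: float = 0.05


@dataclass
class TriggeredAverage:
    lag_s: np.ndarray
    mean: np.ndarray
    traces: np.ndarray  # (n_events, n_lags)
    n_events: int
    normalized: bool


def head_velocity_events(
    t: np.ndarray,
    gy_component: np.ndarray,
    direction: str,
    k: float = 2.5,
    refractory_s: float = 0.05,
) -> HeadEventSet:
    """Detect high-velocity head events for one direction.

    The median is computed over the signed half of the trace (positive
    samples for right/up, magnitudes of negative samples for
    left/down); samples above ``k`` x that median become events, and
    events closer than ``refractory_s`` to the previous one are
    suppressed.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    t = np.asarray(t, dtype=float)
    v = np.asarray(gy_component, dtype=float)
    if t.size and t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of data")
    signed = v if _POSITIVE[direction] else -v
    half = signed[signed > 0]
    if half.size == 0:
        warnings.warn(f"no {direction}-ward samples; zero events", stacklevel=2)
        return HeadEventSet(direction, np.inf, np.zeros(0), np.zeros(0), refractory_s)
    threshold = k * float(np.median(half))
    above = np.nonzero(signed > threshold)[0]
    times, vels = [], []
    last = -np.inf
    for i in above:
        if t[i] - last >= refractory_s:
            times.append(t[i])
            vels.append(signed[i])
            last = t[i]
    return HeadEventSet(
        direction, threshold, np.asarray(times), np.asarray(vels), refractory_s
    )


def triggered_eye_average(
    eye_t: np.ndarray,
    eye_pos: np.ndarray,
    events: HeadEventSet | np.ndarray,
    window_s: float = 1.0,
    normalize: bool = False,
    exclude_mask: np.ndarray | None = None,
    max_excluded_frac: float = 0.4,
) -> TriggeredAverage:
    """Average eye-position snippets centered on head events.

    Only events whose full ±``window_s`` window lies inside the
    recording contribute.  ``exclude_mask`` (e.g. blink frames) drops
    snippets with more than ``max_excluded_frac`` masked samples.
    With ``normalize``, the averaged trace is min-max scaled to [0, 1].
    """
    eye_t = np.asarray(eye_t, dtype=float)
    eye_pos = np.asarray(eye_pos, dtype=float)
    times = events.event_times if isinstance(events, HeadEventSet) else np.asarray(events)
    dt = float(np.median(np.diff(eye_t)))
    half = int(round(window_s / dt))
    snippets = []
    for ev in times:
        center = int(round((ev - eye_t[0]) / dt))
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > eye_t.size:
            continue
        if exclude_mask is not None:
            if exclude_mask[lo:hi].mean() > max_excluded_frac:
                continue
        snippets.append(eye_pos[lo:hi])
    if not snippets:
        raise ValueError("no usable events with a full window inside the recording")
    traces = np.vstack(snippets)
    mean = traces.mean(axis=0)
    if normalize:
        lo_v, hi_v = mean.min(), mean.max()
        if hi_v > lo_v:
            mean = (mean - lo_v) / (hi_v - lo_v)
    lag = (np.arange(-half, half + 1)) * dt
    return TriggeredAverage(
        lag_s=lag, mean=mean, traces=traces, n_events=traces.shape[0], normalized=normalize
    )


def dominant_pitch_frequency(
    t: np.ndarray,
    gy_pitch: np.ndarray,
    band_hz: tuple[float, float] = (0.2, 10.0),
) -> float:
    """Peak frequency (Hz) of the detrended pitch-velocity spectrum."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(gy_pitch, dtype=float)
    if t[-1] - t[0] < 5.0:
        raise ValueError("need at least 5 s of data")
    fs = 1.0 / float(np.median(np.diff(t)))
    detrended = signal.detrend(v)
    freqs, power = signal.periodogram(detrended, fs=fs)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("band empty for this sampling rate")
    return float(freqs[in_band][np.argmax(power[in_band])])
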