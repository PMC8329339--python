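"""Window classification (Δ statistic) and seizure event extraction.

A query window's ST vector ``Q`` is compared with both state prototypes:

    Δ = NHD(Q, P_int) − NHD(Q, P_ict)

Positive Δ means the window is closer to the ictal prototype.  The Δ trace
is turned into discrete seizure events by three rules: Δ must exceed a
threshold θ (default 0, the plain sign rule) continuously for at least a
minimum duration τ, and supra-threshold activity resuming within a
refractory period ρ of an event's offset is merged into that event rather
than counted again.

``evaluate`` scores detected events against ground-truth intervals with
standard overlap matching: sensitivity, false detections per hour, and
onset latency of matched events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import Prototype, encode_recording
from .hdcore import nhd
from .itemmemory import ItemMemory
from .symbolize import Recording


def _vec(p) -> np.ndarray:
    return p.vector if isinstance(p, Prototype) else np.asarray(p, dtype=np.uint8)


def classify_window(Q, P_int, P_ict) -> float:
    """Δ = nhd(Q, P_int) − nhd(Q, P_ict), in [−1, 1]."""
    q = _vec(Q)
    return nhd(q, _vec(P_int)) - nhd(q, _vec(P_ict))


def delta_trace(sts: np.ndarray, P_int, P_ict) -> np.ndarray:
    """Δ for a stack of ST vectors (n_windows, D), vectorized."""
    sts = np.atleast_2d(np.asarray(sts, dtype=np.uint8))
    pi, pc = _vec(P_int), _vec(P_ict)
    if sts.shape[1] != pi.shape[0] or pi.shape[0] != pc.shape[0]:
        raise ValueError("dimension mismatch between queries and prototypes")
    d_int = (sts != pi).mean(axis=1)
    d_ict = (sts != pc).mean(axis=1)
    return d_int - d_ict


@dataclass(frozen=True)
class Event:
    onset_s: float
    offset_s: float
    peak_delta: float


@dataclass(frozen=True)
class DetectionTrace:
    """Δ time series plus the events derived from it."""

    times: np.ndarray
    delta: np.ndarray
    events: list[Event]
    params: dict = field(default_factory=dict)


def detect(times: np.ndarray, delta: np.ndarray, *, theta: float = 0.0,
           tau: float = 5.0, rho: float = 30.0,
           window_s: float = 1.0) -> DetectionTrace:
    """Extract seizure events from a uniformly spaced Δ trace.

    A maximal run of windows with Δ > θ spanning at least τ seconds seeds
    an event whose onset is the *first* supra-threshold window (latency is
    therefore not inflated by the τ confirmation).  Any later
    supra-threshold run starting within ρ seconds of the current event's
    offset is merged into it, qualifying on its own or not.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if times.shape != delta.shape:
        raise ValueError("times and delta must have equal length")
    if tau < 0 or rho < 0:
        raise ValueError("tau and rho must be non-negative")
    params = {"theta": theta, "tau": tau, "rho": rho, "window_s": window_s}
    if times.size == 0:
        return DetectionTrace(times, delta, [], params)

    above = delta > theta
    # maximal runs of consecutive supra-threshold windows
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)  # [start, stop) window indices
    events: list[Event] = []
    for start, stop in runs:
        onset = times[start]
        offset = times[stop - 1] + window_s
        peak = float(delta[start:stop].max())
        if events and onset <= events[-1].offset_s + rho:
            prev = events[-1]
            events[-1] = Event(prev.onset_s, offset, max(prev.peak_delta, peak))
        elif offset - onset >= tau:
            events.append(Event(onset, offset, peak))
    return DetectionTrace(times, delta, events, params)


def run_detection(rec: Recording, im: ItemMemory, P_int: Prototype,
                  P_ict: Prototype, *, window_s: float = 1.0,
                  stride_s: float = 1.0, theta: float = 0.0, tau: float = 5.0,
                  rho: float = 30.0, tie_seed: int = 0) -> DetectionTrace:
    """Encode ``rec`` window by window and detect events in its Δ trace.

    Queries go through the same spatiotemporal encoding used to learn the
    prototypes; only the inputs differ.
    """
    times, sts = encode_recording(rec, im, window_s=window_s,
                                  stride_s=stride_s, tie_seed=tie_seed)
    delta = delta_trace(sts, P_int, P_ict)
    return detect(times, delta, theta=theta, tau=tau, rho=rho, window_s=window_s)


def evaluate(events: list[Event] | list[tuple], labels: list[tuple],
             total_duration_s: float | None = None) -> dict:
    """Overlap-match detected events against ground-truth intervals.

    A label is detected if any event overlaps it; an event is false if it
    overlaps no label.  Latency is (first matching event's onset − label
    onset), negative when the detector fires early.  False detections are
    normalized per hour when ``total_duration_s`` is given.
    """
    evs = [(e.onset_s, e.offset_s) if isinstance(e, Event) else (e[0], e[1])
           for e in events]
    matched_labels = 0
    latencies = []
    for on, off in labels:
        hits = [e for e in evs if e[0] < off and e[1] > on]
        if hits:
            matched_labels += 1
            latencies.append(min(h[0] for h in hits) - on)
    false_events = sum(1 for e in evs
                       if not any(e[0] < off and e[1] > on for on, off in labels))
    out = {
        "n_labels": len(labels),
        "n_events": len(evs),
        "sensitivity": matched_labels / len(labels) if labels else float("nan"),
        "false_detections": false_events,
        "latencies_s": latencies,
        "mean_latency_s": float(np.mean(latencies)) if latencies else float("nan"),
    }
    if total_duration_s:
        out["false_per_hour"] = false_events / (total_duration_s / 3600.0)
    return out
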