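"""Fluorescence normalization and peri-event slicing.

Two normalizations are used, matching the two kinds of comparison the
downstream statistics make:

* across-time comparisons use dF/F, ``(F - F_mean) / F_mean`` with
  ``F_mean`` the per-neuron average over the entire recording;
* peri-event comparisons use z-scores, ``(F - F_mean) / F_sd`` with the
  moments taken over the union of a designated baseline period and the
  event's pre-stimulus window.  F_sd is the sample (n-1) standard
  deviation.

Peri-event windows are sliced so that relative frame 0 is the first
frame at or after event onset, and the window is inclusive of that
onset frame: a +/-10 s window at 6 frames/s is 121 frames.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    DegenerateBaselineError,
    Event,
    EventSchedule,
    NormalizedTrace,
    OutOfRangeError,
    PeriEventTensor,
    TraceMatrix,
)


def deltaf_over_f(trace: TraceMatrix) -> NormalizedTrace:
    """Recording-wide dF/F: ``(F - F_mean) / F_mean`` per neuron.

    Raises :class:`DegenerateBaselineError` (naming the neuron) if any
    neuron's recording-wide mean is zero.  Invariant to multiplicative
    rescaling of the raw trace.
    """
    f_mean = trace.values.mean(axis=1)
    bad = np.flatnonzero(f_mean == 0)
    if bad.size:
        raise DegenerateBaselineError(
            f"neuron(s) {trace.neuron_ids[bad].tolist()} have zero mean fluorescence; "
            "dF/F undefined"
        )
    values = (trace.values - f_mean[:, None]) / f_mean[:, None]
    return NormalizedTrace(
        values=values,
        frame_rate=trace.frame_rate,
        mode="dff",
        neuron_ids=trace.neuron_ids,
        t0=trace.t0,
    )


def _window_frames(trace: TraceMatrix | NormalizedTrace, start: float, stop: float) -> np.ndarray:
    """Frame indices with start <= t < stop (half-open, onset convention)."""
    i0 = max(trace.frame_at(start), 0)
    i1 = min(trace.frame_at(stop), trace.n_frames)
    return np.arange(i0, i1)


def peri_event_zscore(
    trace: TraceMatrix,
    event: Event,
    baseline_window: tuple[float, float],
    pre: float = 0.0,
) -> NormalizedTrace:
    """Z-score traces against a baseline + pre-stimulus reference.

    The reference frames are the union of ``baseline_window``
    (session-clock seconds, half-open) and the ``pre`` seconds
    immediately preceding the event onset.  Moments use the sample
    (n-1) standard deviation; a zero-spread reference raises
    :class:`DegenerateBaselineError`.  Invariant to positive affine
    transforms of the raw trace.
    """
    idx = _window_frames(trace, *baseline_window)
    if pre > 0:
        idx = np.union1d(idx, _window_frames(trace, event.onset - pre, event.onset))
    if idx.size < 2:
        raise DegenerateBaselineError("baseline + pre-stimulus window has fewer than 2 frames")
    ref = trace.values[:, idx]
    f_mean = ref.mean(axis=1)
    f_sd = ref.std(axis=1, ddof=1)
    bad = np.flatnonzero(f_sd == 0)
    if bad.size:
        raise DegenerateBaselineError(
            f"neuron(s) {trace.neuron_ids[bad].tolist()} have zero baseline variance; "
            "z-score undefined"
        )
    values = (trace.values - f_mean[:, None]) / f_sd[:, None]
    return NormalizedTrace(
        values=values,
        frame_rate=trace.frame_rate,
        mode="zscore",
        neuron_ids=trace.neuron_ids,
        t0=trace.t0,
        baseline_window=tuple(baseline_window),
    )


def slice_peri_event(
    norm: NormalizedTrace | TraceMatrix,
    schedule: EventSchedule,
    pre: float,
    post: float,
    label: str | None = None,
) -> PeriEventTensor:
    """Cut aligned snippets around each event onset.

    Relative frame 0 is the event-onset frame (first frame at or after
    onset); the snippet spans ``round(pre*rate)`` frames before to
    ``round(post*rate)`` frames after, inclusive of the onset frame.
    Raises :class:`OutOfRangeError` naming any event whose window falls
    outside the recording.  An empty schedule yields an empty tensor
    with the declared window.
    """
    events = list(schedule if label is None else schedule.select(label))
    n_pre = int(round(pre * norm.frame_rate))
    n_post = int(round(post * norm.frame_rate))
    width = n_pre + n_post + 1
    snippets = np.empty((norm.values.shape[0], len(events), width))
    for j, ev in enumerate(events):
        i0 = norm.frame_at(ev.onset)
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > norm.values.shape[1]:
            raise OutOfRangeError(
                f"event {ev.label!r} at {ev.onset} s: window [{lo}, {hi}) outside "
                f"recording of {norm.values.shape[1]} frames"
            )
        snippets[:, j, :] = norm.values[:, lo:hi]
    if not events:
        snippets = snippets.reshape(norm.values.shape[0], 0, width)
    return PeriEventTensor(
        values=snippets,
        frame_rate=norm.frame_rate,
        window=(pre, post),
        alignment=label or (events[0].label if events else ""),
        neuron_ids=getattr(norm, "neuron_ids", None),
    )
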