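"""Ectopic-event grouping, Torsade de Pointes classification and scoring.

Torsade de Pointes (TdP) is a polymorphic ventricular tachycardia of at
least five beats twisting around the isoelectric line.  Inducibility is
>= 3 TdP within the 10 minutes following the start of the dofetilide
infusion.  Each arrhythmic event scores n + 1 points (n = number of
ectopic beats), overridden by 50 / 75 / 100 points when the episode needed
one / two / three-or-more defibrillations; the final arrhythmia score (AS)
averages the three most severe episodes inside the window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiducials import BeatAnnotation

WINDOW_S = 600.0  # "within 10 min following start of dofetilide"
TDP_MIN_BEATS = 5
POLYMORPHISM_THRESHOLD = 0.3


@dataclass
class ArrhythmiaEvent:
    """A maximal run of consecutive ectopic beats."""

    start_ms: float
    end_ms: float
    n_beats: int
    beat_indices: tuple = ()
    polymorphism_index: float = float("nan")
    is_tdp: bool = False
    defibrillations: int = 0
    terminated_by_cardioversion: bool = False

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("an event needs at least one ectopic beat")
        if self.start_ms > self.end_ms:
            raise ValueError("event start after end")


@dataclass
class ArrhythmiaScore:
    episode_scores: list[float]
    final_as: float
    window_s: tuple[float, float]
    inducible: bool
    n_tdp: int = 0
    events_in_window: int = 0
    meta: dict = field(default_factory=dict)


def group_episodes(beats: list[BeatAnnotation]) -> list[ArrhythmiaEvent]:
    """Group consecutive ectopic-flagged beats into events.

    A maximal run uninterrupted by a non-ectopic beat forms one event;
    the total ectopic count is conserved across events.
    """
    events = []
    run: list[int] = []

    def flush():
        if run:
            events.append(ArrhythmiaEvent(
                start_ms=beats[run[0]].beat_time_ms,
                end_ms=beats[run[-1]].beat_time_ms,
                n_beats=len(run),
                beat_indices=tuple(run),
            ))

    for i, b in enumerate(beats):
        if b.ectopic:
            run.append(i)
        else:
            flush()
            run = []
    flush()
    return events


def polymorphism_index(polarities, amplitudes=None) -> float:
    """0-1 surrogate for the "twisting" of a run.

    The fraction of within-run beat pairs whose dominant QRS polarity
    differs, combined (by maximum) with the depth of the amplitude
    envelope modulation.  Monomorphic runs score ~0.
    """
    pol = np.sign(np.asarray(polarities, dtype=float))
    n = len(pol)
    if n < 2:
        return 0.0
    pos = int((pol > 0).sum())
    frac = pos * (n - pos) / (n * (n - 1) / 2.0)
    depth = 0.0
    if amplitudes is not None:
        a = np.abs(np.asarray(amplitudes, dtype=float))
        if np.isfinite(a).all() and a.max() + a.min() > 0:
            depth = float((a.max() - a.min()) / (a.max() + a.min()))
    return float(max(frac, depth))


def classify_tdp(
    event: ArrhythmiaEvent,
    beats: list[BeatAnnotation] | None = None,
    threshold: float = POLYMORPHISM_THRESHOLD,
    min_beats: int = TDP_MIN_BEATS,
) -> bool:
    """TdP = at least ``min_beats`` beats AND polymorphic morphology.

    Polymorphism is judged from the annotated per-beat QRS polarity and
    amplitude of the run's beats.  Updates the event in place and returns
    the flag.
    """
    if beats is not None and event.beat_indices:
        pols = [beats[i].polarity_sign for i in event.beat_indices]
        amps = [beats[i].r_amp for i in event.beat_indices]
        event.polymorphism_index = polymorphism_index(pols, amps)
    if not np.isfinite(event.polymorphism_index):
        raise ValueError("cannot classify: no polymorphism index and no annotations")
    event.is_tdp = (event.n_beats >= min_beats
                    and event.polymorphism_index >= threshold)
    return event.is_tdp


def _in_window(event: ArrhythmiaEvent, t0_s: float, window_s: float) -> bool:
    # half-open (t0, t0 + window]; membership by event start
    t0 = t0_s * 1000.0
    return t0 < event.start_ms <= t0 + window_s * 1000.0


def inducibility(events: list[ArrhythmiaEvent], dofetilide_start_s: float,
                 window_s: float = WINDOW_S) -> bool:
    """True iff >= 3 TdP start within the window after infusion start."""
    return sum(e.is_tdp and _in_window(e, dofetilide_start_s, window_s)
               for e in events) >= 3


def episode_score(event: ArrhythmiaEvent) -> float:
    """n + 1 points, overridden by 50/75/100 for 1/2/>=3 defibrillations."""
    if event.defibrillations < 0:
        raise ValueError("negative defibrillation count")
    if event.defibrillations >= 3:
        return 100.0
    if event.defibrillations == 2:
        return 75.0
    if event.defibrillations == 1:
        return 50.0
    return float(event.n_beats + 1)


def arrhythmia_score(
    events: list[ArrhythmiaEvent],
    dofetilide_start_s: float,
    window_s: float = WINDOW_S,
    zero_event_score: float = 0.0,
) -> ArrhythmiaScore:
    """Final AS: mean of the three most severe episode scores in the
    10-min window (mean of fewer if fewer occurred; ``zero_event_score``
    when none did)."""
    in_win = [e for e in events if _in_window(e, dofetilide_start_s, window_s)]
    scores = sorted((episode_score(e) for e in in_win), reverse=True)
    final = float(np.mean(scores[:3])) if scores else float(zero_event_score)
    n_tdp = sum(e.is_tdp for e in in_win)
    return ArrhythmiaScore(
        episode_scores=scores,
        final_as=final,
        window_s=(dofetilide_start_s, dofetilide_start_s + window_s),
        inducible=n_tdp >= 3,
        n_tdp=n_tdp,
        events_in_window=len(in_win),
    )


def attach_defibrillations(events: list[ArrhythmiaEvent], log) -> None:
    """Attach defibrillation counts to events.

    ``log`` is an iterable of ``(time_ms, count)`` rows (or dicts with
    ``start_ms``/``defibrillations``); each row is assigned to the event
    whose span is nearest to its time.
    """
    if not events:
        return
    starts = np.array([e.start_ms for e in events])
    ends = np.array([e.end_ms for e in events])
    for row in log:
        if isinstance(row, dict):
            t, c = row["start_ms"], row["defibrillations"]
        else:
            t, c = row
        dist = np.where((starts <= t) & (t <= ends), 0.0,
                        np.minimum(np.abs(starts - t), np.abs(ends - t)))
        k = int(np.argmin(dist))
        events[k].defibrillations += int(c)
        if c:
            events[k].terminated_by_cardioversion = True
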