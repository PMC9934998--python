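"""Radial-strain dyssynchrony metrics.

The left ventricle is divided into six short-axis segments at papillary
level.  Two adjoining segments are averaged into a septal wall and two into
a free wall; the two intermediate segments are discarded.  From each wall
trace three features are read: peak strain (PS, %), time-to-peak (TTP, ms
from the beat reference) and contraction onset (ms).  Dyssynchrony deltas
are free-wall minus septum (ΔPS, ΔOnset, ΔTTP).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical short-axis segment names, in circumferential order
SEGMENTS = (
    "anteroseptal",
    "anterior",
    "anterolateral",
    "inferolateral",
    "inferior",
    "inferoseptal",
)

#: default two-segments-per-wall assignment; "anterior" and "inferior" are
#: the intermediate segments and are discarded
DEFAULT_WALL_MAP = {
    "free_wall": ("anterolateral", "inferolateral"),
    "septum": ("anteroseptal", "inferoseptal"),
}

WALLS = ("free_wall", "septum")


@dataclass
class StrainCurveSet:
    """Six per-segment radial strain traces on one shared time base.

    ``reference_ms`` is the beat reference (QRS-onset equivalent) that TTP
    and onset are measured from.
    """

    time_ms: np.ndarray
    traces: dict[str, np.ndarray]
    wall_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_WALL_MAP)
    )
    reference_ms: float = 0.0

    def validate(self) -> None:
        n = len(self.time_ms)
        for name, tr in self.traces.items():
            if len(tr) != n:
                raise ValueError(f"segment {name!r} is not on the shared time base")
        for wall, segs in self.wall_map.items():
            if len(segs) != 2:
                raise ValueError(f"wall {wall!r} must map exactly two segments")


@dataclass
class StrainFeatures:
    """PS / onset / TTP of one wall trace."""

    ps_pct: float
    onset_ms: float
    ttp_ms: float
    valid: bool = True


@dataclass
class StrainDeltas:
    d_ps: float
    d_onset: float
    d_ttp: float


def wall_average(curves: StrainCurveSet) -> dict[str, np.ndarray]:
    """Point-wise mean of the two mapped segments per wall.

    Discarded (unmapped) segments never enter the result.  Raises if a
    mapped segment is missing from the curve set.
    """
    curves.validate()
    walls: dict[str, np.ndarray] = {}
    for wall, (a, b) in curves.wall_map.items():
        for seg in (a, b):
            if seg not in curves.traces:
                raise ValueError(f"wall {wall!r} needs segment {seg!r}, which is missing")
        walls[wall] = 0.5 * (curves.traces[a] + curves.traces[b])
    return walls


def _parabolic_vertex(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample vertex (offset in samples, value) around index ``i``.

    Refinement only applies at a strict local maximum; on a plateau the
    sample itself is returned so ties keep breaking to the earlier time.
    """
    if i <= 0 or i >= len(y) - 1:
        return 0.0, float(y[i])
    if not (y[i] > y[i - 1] and y[i] > y[i + 1]):
        return 0.0, float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-12:
        return 0.0, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return delta, float(value)


def strain_features(
    trace: np.ndarray,
    time_ms: np.ndarray,
    reference_ms: float = 0.0,
    onset_frac: float = 0.1,
    sustain_ms: float = 20.0,
) -> StrainFeatures:
    """Extract PS, onset and TTP from one wall trace.

    PS is the (sub-sample refined) maximum strain.  TTP is its time minus
    the reference; on a plateau with equal maxima the earlier time wins.
    Onset is the first time strain exceeds ``onset_frac`` of PS and stays
    above it for at least ``sustain_ms`` (a fractional threshold is
    amplitude-invariant; the generator places its pulses so this crossing
    falls at the programmed onset).  Non-positive PS flags the features
    invalid.
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    i = int(np.argmax(trace))
    dt = float(time_ms[1] - time_ms[0]) if len(time_ms) > 1 else 1.0
    delta, ps = _parabolic_vertex(trace, i)
    ttp = float(time_ms[i] + delta * dt - reference_ms)
    if not np.isfinite(ps) or ps <= 0:
        return StrainFeatures(ps_pct=float(ps), onset_ms=np.nan, ttp_ms=ttp, valid=False)

    thr = onset_frac * ps
    sustain = max(1, int(round(sustain_ms / dt)))
    above = trace >= thr
    onset = np.nan
    for j in np.flatnonzero(above):
        if above[j : j + sustain].all() and (j + sustain <= len(trace)):
            if j == 0:
                onset = float(time_ms[0] - reference_ms)
            else:
                # linear interpolation of the threshold crossing
                y0, y1 = trace[j - 1], trace[j]
                frac = (thr - y0) / (y1 - y0) if y1 != y0 else 1.0
                onset = float(time_ms[j - 1] + frac * dt - reference_ms)
            break
    return StrainFeatures(ps_pct=float(ps), onset_ms=onset, ttp_ms=ttp,
                          valid=np.isfinite(onset))


def strain_deltas(fw: StrainFeatures, sep: StrainFeatures) -> StrainDeltas:
    """Free-wall minus septum for each feature."""
    return StrainDeltas(
        d_ps=fw.ps_pct - sep.ps_pct,
        d_onset=fw.onset_ms - sep.onset_ms,
        d_ttp=fw.ttp_ms - sep.ttp_ms,
    )


def analyze_strain(curves: StrainCurveSet) -> tuple[dict[str, StrainFeatures], StrainDeltas]:
    """Wall-average a curve set and return per-wall features plus deltas."""
    walls = wall_average(curves)
    feats = {
        wall: strain_features(tr, curves.time_ms, curves.reference_ms)
        for wall, tr in walls.items()
    }
    deltas = strain_deltas(feats["free_wall"], feats["septum"])
    return feats, deltas
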