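"""Repolarization variability and dyssynchrony statistics.

Short-term variability (STV) is the Poincare-plot-derived statistic
``sum |D_{n+1} - D_n| / (N sqrt(2))`` where D is a per-beat repolarization
duration (RV MAPD or LV ARI).  Interventricular dispersion of
repolarization is ``dMAPD = mean LV ARI - RV MAPD``; interventricular
activation delay is ``dAT = LV_AT - RV_AT``.  Intraventricular electrical
dyssynchrony is summarized by the ordinary-least-squares slope of ARI on
AT across the LV electrodes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress


@dataclass
class ATARIFit:
    """OLS fit of ARI on AT across electrodes."""

    slope: float
    intercept: float
    r: float
    n_points: int
    phase: str = ""


def stv(series, n_diffs: int = 30, mode: str = "differences") -> float:
    """Short-term variability of a repolarization-duration series (ms).

    ``mode="differences"`` (default) uses the last ``n_diffs`` successive
    differences (``n_diffs + 1`` beats) with divisor ``n_diffs * sqrt(2)``,
    so every summand matches the divisor.  ``mode="literal"`` reads the
    formula over ``n_diffs`` *beats* (``n_diffs - 1`` differences, same
    divisor).  For iid Normal(0, sigma^2) perturbations the expectation is
    ``sigma * sqrt(2/pi)``.
    """
    d = np.asarray(series, dtype=float)
    if np.isnan(d).any():
        raise ValueError("repolarization series contains missing beats")
    if mode == "differences":
        need = n_diffs + 1
    elif mode == "literal":
        need = n_diffs
    else:
        raise ValueError(f"unknown STV mode {mode!r}")
    if len(d) < need:
        raise ValueError(f"STV needs at least {need} beats, got {len(d)}")
    window = d[-need:]
    return float(np.abs(np.diff(window)).sum() / (n_diffs * math.sqrt(2.0)))


def delta_mapd(lv_ari_mean_ms: float, rv_mapd_ms: float) -> float:
    """Interventricular dispersion of repolarization: mean LV ARI - RV MAPD."""
    return lv_ari_mean_ms - rv_mapd_ms


def delta_at(lv_at_mean_ms: float, rv_at_ms: float) -> float:
    """Interventricular activation delay: LV_AT - RV_AT."""
    return lv_at_mean_ms - rv_at_ms


def at_ari_slope(ats, aris, phase: str = "") -> ATARIFit:
    """OLS regression of per-electrode ARI on AT.

    NaN pairs are dropped; at least three valid electrode pairs are
    required and the ATs must not be constant (the slope is undefined).
    """
    x = np.asarray(ats, dtype=float)
    y = np.asarray(aris, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"AT-ARI slope needs >= 3 electrode pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("AT-ARI slope undefined: zero activation-time variance")
    fit = linregress(x, y)
    return ATARIFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    r=float(fit.rvalue), n_points=int(len(x)), phase=phase)


def select_measurement_window(
    beat_times_ms,
    ectopic,
    dofetilide_start_s: float | None = None,
    phase: str = "baseline",
    window_s: float = 300.0,
    min_beats: int = 6,
) -> np.ndarray:
    """Beat indices of the measurement stretch for a phase.

    Baseline: the last run of consecutive non-ectopic beats before the
    infusion starts (or before the end of the recording).  Dofetilide: the
    clean stretch inside ``(start, start + window_s]``, additionally
    truncated at the first ectopic beat after the start — measurements are
    taken before the first ectopic beat or at the end of the infusion ramp.
    """
    t = np.asarray(beat_times_ms, dtype=float)
    ect = np.asarray(ectopic, dtype=bool)
    t0 = dofetilide_start_s * 1000.0 if dofetilide_start_s is not None else None

    if phase == "baseline":
        hi = t0 if t0 is not None else np.inf
        eligible = (~ect) & (t < hi)
    elif phase == "dofetilide":
        if t0 is None:
            raise ValueError("dofetilide phase requested but no infusion start given")
        end = t0 + window_s * 1000.0
        after = np.flatnonzero(ect & (t > t0))
        if len(after):
            end = min(end, t[after[0]])
        eligible = (~ect) & (t > t0) & (t <= end)
    else:
        raise ValueError(f"unknown phase {phase!r}")

    runs, cur = [], []
    for i in range(len(t)):
        if eligible[i]:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    runs = [r for r in runs if len(r) >= min_beats]
    if not runs:
        raise ValueError(f"no window with {min_beats} clean beats in phase {phase!r}")
    return np.asarray(runs[-1], dtype=int)
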