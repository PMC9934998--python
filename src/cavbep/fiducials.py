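"""Per-beat fiducials and interval measurements.

Conventions used throughout (all times in ms from recording start):

* LV activation time (AT): pacing spike to the minimum dV/dt of the
  unipolar electrogram, derivative taken on a lightly smoothed trace;
  ties broken by the earliest time.
* Activation recovery interval (ARI): Wyatt convention — time of the
  maximum dV/dt inside the T-wave window minus the activation time,
  regardless of T-wave polarity.
* RV activation: spike to steepest MAP upstroke; MAP duration at 80%
  repolarization (first crossing of baseline + 0.2 x amplitude).
* Surface-ECG intervals are averaged over five consecutive clean beats;
  QTc uses the Van der Water correction, JTc = QTc - QRS.

Electrodes 1 and 10 of the duo-decapolar catheter are excluded from LV
aggregates (P-wave interference in the real preparation); LV means run
over available electrodes 2-9.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .synth import SignalRecording

LV_ELECTRODES = tuple(range(2, 10))  # electrode numbers included in LV aggregates


@dataclass
class BeatAnnotation:
    """Fiducials of one beat on the surface ECG."""

    beat_index: int
    beat_time_ms: float  # pacing spike when available, else QRS onset
    r_peak_ms: float
    r_amp: float
    polarity_sign: int
    qrs_on_ms: float
    qrs_off_ms: float
    t_peak_ms: float
    t_end_ms: float
    ectopic: bool
    template_corr: float


@dataclass
class ECGIntervals:
    """Five-beat averaged surface-ECG intervals (ms)."""

    pp: float
    rr: float
    qrs: float
    qt: float
    qtc: float
    jtc: float
    tpe: float
    n_beats: int
    beat_indices: tuple


# ------------------------------------------------------------------ helpers

def _noise_sigma(x: np.ndarray) -> float:
    """Robust noise SD from first differences (waveform slopes are slow
    compared with sample-to-sample noise)."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def _smooth_deriv(x: np.ndarray, fs: float, smooth_ms: float = 5.0) -> np.ndarray:
    """Centered finite difference (per ms) after a moving-average smooth."""
    size = max(1, int(round(smooth_ms * fs / 1000.0)))
    if size % 2 == 0:
        size += 1
    xm = uniform_filter1d(x, size=size, mode="nearest")
    return np.gradient(xm) * (fs / 1000.0)


def _refine(d: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of an extremum index (in samples)."""
    if i <= 0 or i >= len(d) - 1:
        return 0.0
    denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
    if abs(denom) < 1e-15:
        return 0.0
    return float(np.clip(0.5 * (d[i - 1] - d[i + 1]) / denom, -0.5, 0.5))


def _flat_top_center(d: np.ndarray, i: int, mode: str) -> float:
    """Centre of a run of samples tied with the extremum (plateaus arise
    with step-like inputs after boxcar smoothing)."""
    v = d[i]
    tol = 1e-12 + 1e-9 * abs(v)
    j0 = i
    while j0 > 0 and abs(d[j0 - 1] - v) <= tol:
        j0 -= 1
    j1 = i
    while j1 < len(d) - 1 and abs(d[j1 + 1] - v) <= tol:
        j1 += 1
    if j1 > j0:
        return 0.5 * (j0 + j1)
    return i + _refine(d, i)


def _idx(t_ms: float, fs: float) -> int:
    return int(round(t_ms * fs / 1000.0))


def _cross_down(x: np.ndarray, start: int, stop: int, thr: float, fs: float,
                sustain_ms: float = 10.0, on_abs: bool = True) -> float:
    """First sustained downward crossing of |x| (or x) below ``thr`` after
    ``start``; returns the interpolated crossing time in ms, or NaN."""
    v = np.abs(x) if on_abs else x
    sus = max(1, int(round(sustain_ms * fs / 1000.0)))
    stop = min(stop, len(v))
    for j in range(start + 1, stop):
        if v[j] < thr and v[j : min(j + sus, stop)].max(initial=-np.inf) < thr:
            y0, y1 = v[j - 1], v[j]
            frac = (y0 - thr) / (y0 - y1) if y0 > y1 else 1.0
            return ((j - 1) + frac) * 1000.0 / fs
    return np.nan


def _cross_up_back(x: np.ndarray, peak: int, thr: float, fs: float,
                   sustain_ms: float = 8.0) -> float:
    """Scanning backwards from ``peak``: the (interpolated) time |x| last
    rose through ``thr``; NaN-free — falls back to the window start."""
    v = np.abs(x)
    sus = max(1, int(round(sustain_ms * fs / 1000.0)))
    for j in range(peak - 1, -1, -1):
        if v[j] < thr and v[max(0, j - sus + 1) : j + 1].max(initial=-np.inf) < thr:
            y0, y1 = v[j], v[min(j + 1, len(v) - 1)]
            frac = (thr - y0) / (y1 - y0) if y1 > y0 else 0.0
            return (j + frac) * 1000.0 / fs
    return 0.0


# ------------------------------------------------------------- beat detection

def detect_beats(
    recording: SignalRecording,
    ecg_channel: str = "ecg",
    corr_threshold: float = 0.95,
    rr_tol: float = 0.25,
    width_tol: float = 0.25,
) -> list[BeatAnnotation]:
    """Detect beats on the surface ECG and annotate their fiducials.

    A beat is flagged ectopic when its morphology deviates from the beat
    template (low correlation, deviant QRS width, or opposite dominant
    polarity) or when both adjacent cycles deviate from the dominant cycle
    length.  Raises on a flat or beat-free trace.
    """
    x = recording.channel(ecg_channel)
    fs = recording.fs_hz
    if np.ptp(x) < 1e-9:
        raise ValueError("no detectable beats: ECG channel is flat")
    ax = np.abs(x)
    sigma = _noise_sigma(x)
    peaks, _ = find_peaks(ax, height=0.35 * ax.max(),
                          distance=max(1, int(round(0.18 * fs))))
    if len(peaks) == 0:
        raise ValueError("no detectable beats above amplitude threshold")

    dt = 1000.0 / fs
    n = len(x)
    amps = x[peaks]
    pols = np.sign(amps).astype(int)
    pol_dom = 1 if (pols > 0).mean() >= 0.5 else -1

    qrs_on = np.empty(len(peaks))
    qrs_off = np.empty(len(peaks))
    for i, p in enumerate(peaks):
        thr = max(0.01 * abs(amps[i]), 4.0 * sigma)
        qrs_on[i] = _cross_up_back(x, p, thr, fs)
        stop = peaks[i + 1] - int(0.05 * fs) if i + 1 < len(peaks) else n
        off = _cross_down(x, p, stop, thr, fs, sustain_ms=8.0)
        qrs_off[i] = off if np.isfinite(off) else min(p * dt + 120.0, (n - 1) * dt)

    # T-wave fiducials per beat
    t_peak = np.full(len(peaks), np.nan)
    t_end = np.full(len(peaks), np.nan)
    for i, p in enumerate(peaks):
        w0 = _idx(qrs_off[i] + 10.0, fs)
        w1 = _idx(qrs_on[i + 1] - 30.0, fs) if i + 1 < len(peaks) else n
        if w1 - w0 < int(0.02 * fs):
            continue
        seg = x[w0:w1]
        j = int(np.argmax(np.abs(seg)))
        t_amp = seg[j]
        if abs(t_amp) < max(0.08 * abs(amps[i]), 5.0 * sigma):
            continue
        t_peak[i] = (w0 + j + _refine(np.abs(seg), j)) * dt
        thr = max(0.005 * abs(t_amp), 4.0 * sigma)
        t_end[i] = _cross_down(x, w0 + j, w1, thr, fs, sustain_ms=10.0)

    # template correlation on +/-150 ms windows
    hw = int(0.15 * fs)
    wins, have = [], []
    for p in peaks:
        if p - hw >= 0 and p + hw < n:
            w = x[p - hw : p + hw + 1]
            w = w - w.mean()
            wins.append(w)
            have.append(True)
        else:
            wins.append(None)
            have.append(False)
    stack = np.array([w for w in wins if w is not None])
    template = np.median(stack, axis=0) if len(stack) else None
    corr = np.ones(len(peaks))
    if template is not None and np.linalg.norm(template) > 0:
        tn = template / np.linalg.norm(template)
        for i, w in enumerate(wins):
            if w is None:
                continue
            nw = np.linalg.norm(w)
            corr[i] = float(w @ tn / nw) if nw > 0 else 0.0

    times = peaks * dt
    rr = np.diff(times)
    med_rr = float(np.median(rr)) if len(rr) else np.nan
    widths = qrs_off - qrs_on
    med_w = float(np.median(widths))

    spikes = np.asarray(recording.pacing_spikes_ms)
    beats = []
    for i, p in enumerate(peaks):
        prev_dev = (i > 0 and np.isfinite(med_rr)
                    and abs(rr[i - 1] - med_rr) > rr_tol * med_rr)
        next_dev = (i < len(rr) and np.isfinite(med_rr)
                    and abs(rr[i] - med_rr) > rr_tol * med_rr)
        ectopic = bool(
            corr[i] < corr_threshold
            or abs(widths[i] - med_w) > width_tol * med_w
            or pols[i] != pol_dom
            or (prev_dev and next_dev)
        )
        beat_time = qrs_on[i]
        if len(spikes):
            k = int(np.argmin(np.abs(spikes - qrs_on[i])))
            if -80.0 <= qrs_on[i] - spikes[k] <= 30.0:
                beat_time = float(spikes[k])
        beats.append(BeatAnnotation(
            beat_index=i,
            beat_time_ms=float(beat_time),
            r_peak_ms=float(times[i]),
            r_amp=float(amps[i]),
            polarity_sign=int(pols[i]),
            qrs_on_ms=float(qrs_on[i]),
            qrs_off_ms=float(qrs_off[i]),
            t_peak_ms=float(t_peak[i]),
            t_end_ms=float(t_end[i]),
            ectopic=ectopic,
            template_corr=float(corr[i]),
        ))
    return beats


# -------------------------------------------------------------- ECG intervals

def qtc_van_der_water(qt_ms: float, rr_ms: float) -> float:
    """Van der Water heart-rate correction: QTc = QT - 0.087 (RR - 1000)."""
    if qt_ms <= 0 or rr_ms <= 0:
        raise ValueError("QT and RR must be positive")
    return qt_ms - 0.087 * (rr_ms - 1000.0)


def jtc(qtc_ms: float, qrs_ms: float) -> float:
    """JTc = QTc - QRS."""
    if qtc_ms <= 0 or qrs_ms <= 0:
        raise ValueError("QTc and QRS must be positive")
    return qtc_ms - qrs_ms


def _clean_runs(beats: list[BeatAnnotation], t_range_ms=None) -> list[list[int]]:
    """Maximal runs of consecutive clean (non-ectopic, complete-fiducial)
    beats, optionally restricted to a time range."""
    runs, cur = [], []
    for i, b in enumerate(beats):
        ok = (not b.ectopic and np.isfinite(b.t_end_ms)
              and np.isfinite(b.qrs_on_ms) and np.isfinite(b.qrs_off_ms))
        if ok and t_range_ms is not None:
            ok = t_range_ms[0] <= b.beat_time_ms <= t_range_ms[1]
        if ok:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def detect_p_peaks(recording: SignalRecording, beats: list[BeatAnnotation]) -> np.ndarray:
    """P-wave peak times: peak search on the ECG with QRS-T regions masked."""
    x = recording.channel("ecg").copy()
    fs = recording.fs_hz
    for b in beats:
        a = _idx(b.qrs_on_ms - 15.0, fs)
        e = b.t_end_ms + 25.0 if np.isfinite(b.t_end_ms) else b.qrs_on_ms + 350.0
        x[max(a, 0) : min(_idx(e, fs), len(x))] = 0.0
    if np.ptp(x) < 1e-9:
        return np.array([])
    height = max(0.4 * np.abs(x).max(), 5.0 * _noise_sigma(x))
    pk, _ = find_peaks(np.abs(x), height=height, distance=max(1, int(0.15 * fs)))
    return pk * 1000.0 / fs


def measure_intervals(
    recording: SignalRecording,
    beats: list[BeatAnnotation],
    n_beats: int = 5,
    t_range_ms: tuple[float, float] | None = None,
    phase: str = "",
) -> ECGIntervals:
    """Surface-ECG intervals averaged over ``n_beats`` consecutive clean
    beats — the latest artefact-free stretch in the (optional) time range.

    The reported value of each interval is the arithmetic mean of the
    per-beat values; QTc is computed from the averaged QT and RR.
    """
    runs = [r for r in _clean_runs(beats, t_range_ms) if len(r) >= n_beats + 1]
    if not runs:
        raise ValueError(
            f"fewer than {n_beats + 1} consecutive clean beats available"
            + (f" in phase {phase!r}" if phase else ""))
    sel = runs[-1][-(n_beats + 1):]
    times = np.array([beats[i].beat_time_ms for i in sel])
    rr = float(np.mean(np.diff(times)))
    use = sel[1:]
    qrs = float(np.mean([beats[i].qrs_off_ms - beats[i].qrs_on_ms for i in use]))
    qt = float(np.mean([beats[i].t_end_ms - beats[i].qrs_on_ms for i in use]))
    tpe = float(np.mean([beats[i].t_end_ms - beats[i].t_peak_ms for i in use]))
    qtc = qtc_van_der_water(qt, rr)

    p_times = detect_p_peaks(recording, beats)
    lo, hi = times[0] - 1.5 * rr, times[-1] + 0.5 * rr
    p_sel = p_times[(p_times >= lo) & (p_times <= hi)]
    pp = np.nan
    if len(p_sel) >= 3:
        d = np.diff(p_sel)
        # P waves hidden under the QRS-T leave gaps of k atrial cycles;
        # estimate the fundamental from the shortest credible interval
        base = float(np.min(d))
        k = np.maximum(1, np.round(d / base))
        pp = float(np.mean(d / k))
    elif len(p_sel) == 2:
        pp = float(p_sel[1] - p_sel[0])
    return ECGIntervals(pp=pp, rr=rr, qrs=qrs, qt=qt, qtc=qtc,
                        jtc=jtc(qtc, qrs), tpe=tpe,
                        n_beats=n_beats, beat_indices=tuple(use))


# ------------------------------------------------------ intracardiac channels

def _extremum_time(d: np.ndarray, fs: float, a_ms: float, b_ms: float,
                   mode: str, min_slope: float) -> float:
    """Time (ms) of the extremum of a precomputed derivative in a window."""
    i0 = max(_idx(a_ms, fs), 1)
    i1 = min(_idx(b_ms, fs), len(d) - 1)
    if i1 <= i0:
        return np.nan
    seg = d[i0:i1]
    j = int(np.argmin(seg)) if mode == "min" else int(np.argmax(seg))
    v = seg[j]
    if (mode == "min" and v > -min_slope) or (mode == "max" and v < min_slope):
        return np.nan
    return (i0 + j + _flat_top_center(-seg if mode == "min" else seg, j, mode)
            - j) * 1000.0 / fs


def egm_at(
    egm: np.ndarray,
    fs: float,
    spike_ms: float,
    window_ms: tuple[float, float] = (0.0, 160.0),
    smooth_ms: float = 5.0,
    min_slope: float = 1e-3,
    _deriv: np.ndarray | None = None,
) -> float:
    """LV activation time: minimum dV/dt of the EGM inside the QRS window,
    relative to the pacing spike.  Ties break to the earliest time; an
    empty or flat window gives NaN."""
    d = _deriv if _deriv is not None else _smooth_deriv(np.asarray(egm, float), fs, smooth_ms)
    t = _extremum_time(d, fs, spike_ms + window_ms[0], spike_ms + window_ms[1],
                       "min", min_slope)
    return t - spike_ms if np.isfinite(t) else np.nan


def egm_ari(
    egm: np.ndarray,
    fs: float,
    at_time_ms: float,
    t_window_ms: tuple[float, float],
    smooth_ms: float = 5.0,
    coarse_ms: float = 25.0,
    min_slope: float = 2e-3,
    _deriv: np.ndarray | None = None,
    _deriv_coarse: np.ndarray | None = None,
) -> float:
    """Wyatt activation-recovery interval: maximum dV/dt inside the T-wave
    window minus the (absolute) activation time, for either T polarity.

    The T upslope is located in two stages: a heavily smoothed derivative
    finds the neighbourhood (robust to broadband noise over the long T
    window) and the lightly smoothed derivative places the maximum within
    +/- ``coarse_ms`` of it (no flattening bias).  A flat window gives NaN.
    """
    x = np.asarray(egm, float)
    d = _deriv if _deriv is not None else _smooth_deriv(x, fs, smooth_ms)
    dc = _deriv_coarse if _deriv_coarse is not None else _smooth_deriv(x, fs, coarse_ms)
    t0 = _extremum_time(dc, fs, t_window_ms[0], t_window_ms[1], "max", min_slope)
    if not np.isfinite(t0):
        return np.nan
    a = max(t_window_ms[0], t0 - 5.0)
    b = min(t_window_ms[1], t0 + 5.0)
    t = _extremum_time(d, fs, a, b, "max", min_slope)
    return t - at_time_ms if np.isfinite(t) else np.nan


def mapd80(
    map_sig: np.ndarray,
    fs: float,
    spike_ms: float,
    next_spike_ms: float | None = None,
    smooth_ms: float = 5.0,
    _deriv: np.ndarray | None = None,
) -> tuple[float, float]:
    """RV activation time and MAP duration at 80% repolarization.

    The upstroke is the steepest positive slope of the smoothed trace after
    the spike; MAPD is the time from the upstroke to the first sustained
    crossing of baseline + 0.2 x amplitude, measured on the raw trace
    (baseline = median diastolic level before the upstroke).  Fractional
    thresholds make the result invariant to amplitude scaling.  Returns
    (NaN, NaN) when no adequate upstroke exists."""
    x = np.asarray(map_sig, float)
    d = _deriv if _deriv is not None else _smooth_deriv(x, fs, smooth_ms)
    end_ms = (next_spike_ms - 20.0) if next_spike_ms is not None else spike_ms + 600.0
    end_ms = min(end_ms, (len(x) - 1) * 1000.0 / fs)

    i0 = max(_idx(spike_ms, fs), 1)
    i1 = min(_idx(min(spike_ms + 200.0, end_ms), fs), len(d) - 1)
    if i1 <= i0:
        return np.nan, np.nan
    seg = d[i0:i1]
    j = int(np.argmax(seg))
    up_idx = i0 + j
    up_ms = (i0 + j + (_flat_top_center(seg, j, "max") - j)) * 1000.0 / fs

    b0, b1 = _idx(spike_ms - 120.0, fs), _idx(spike_ms - 10.0, fs)
    if b1 <= max(b0, 0):
        b0, b1 = _idx(spike_ms, fs), up_idx
    baseline = float(np.median(x[max(b0, 0) : b1])) if b1 > max(b0, 0) else 0.0

    stop = _idx(end_ms, fs)
    peak_reg = x[up_idx:stop]
    if len(peak_reg) == 0:
        return np.nan, np.nan
    pk = int(np.argmax(peak_reg))
    amp = float(peak_reg[pk] - baseline)
    if amp <= 0 or seg[j] < 0.02 * amp:
        return np.nan, np.nan
    thr = baseline + 0.2 * amp
    cross = _cross_down(x - baseline, up_idx + pk, stop, thr - baseline, fs,
                        sustain_ms=5.0, on_abs=False)
    if not np.isfinite(cross):
        return np.nan, np.nan
    return up_ms - spike_ms, cross - up_ms


# ---------------------------------------------------------------- per-series

def measure_egm_series(
    recording: SignalRecording,
    beat_times_ms: np.ndarray,
    electrodes: tuple[int, ...] = LV_ELECTRODES,
    qrs_window_ms: float = 160.0,
    t_gap_ms: float = 50.0,
    smooth_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat AT and ARI for the requested electrodes.

    Returns two (n_beats, n_electrodes) arrays; missing fiducials are NaN.
    The T window of beat i runs from spike + QRS window to the following
    spike minus ``t_gap_ms`` (or +600 ms for the final beat).
    """
    fs = recording.fs_hz
    beat_times_ms = np.asarray(beat_times_ms, float)
    nb = len(beat_times_ms)
    at = np.full((nb, len(electrodes)), np.nan)
    ari = np.full((nb, len(electrodes)), np.nan)
    for c, el in enumerate(electrodes):
        sig = recording.channel(f"egm{el}")
        d = _smooth_deriv(sig, fs, smooth_ms)
        dc = _smooth_deriv(sig, fs, 25.0)
        for i, spike in enumerate(beat_times_ms):
            a = egm_at(sig, fs, spike, (0.0, qrs_window_ms), _deriv=d)
            at[i, c] = a
            if not np.isfinite(a):
                continue
            t_hi = (beat_times_ms[i + 1] - t_gap_ms if i + 1 < nb
                    else spike + 600.0)
            ari[i, c] = egm_ari(sig, fs, spike + a,
                                (spike + qrs_window_ms, t_hi),
                                _deriv=d, _deriv_coarse=dc)
    return at, ari


def measure_map_series(
    recording: SignalRecording,
    beat_times_ms: np.ndarray,
    smooth_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat RV activation time and MAPD80 (NaN where missing)."""
    fs = recording.fs_hz
    sig = recording.channel("map")
    d = _smooth_deriv(sig, fs, smooth_ms)
    beat_times_ms = np.asarray(beat_times_ms, float)
    nb = len(beat_times_ms)
    rv_at = np.full(nb, np.nan)
    mapd = np.full(nb, np.nan)
    for i, spike in enumerate(beat_times_ms):
        nxt = beat_times_ms[i + 1] if i + 1 < nb else None
        rv_at[i], mapd[i] = mapd80(sig, fs, spike, nxt, _deriv=d)
    return rv_at, mapd
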