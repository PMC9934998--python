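"""Seeded synthetic recordings with known ground truth.

Emulates the recording set of an anaesthetized chronic AV-block dog
experiment: one surface ECG lead, ten left-ventricular unipolar
electrograms (EGM) from a duo-decapolar catheter, and one right-ventricular
monophasic action potential (MAP), sampled at 1 kHz by default, plus
per-wall radial strain curves.

The waveform shapes are implementation choices; the contract is fiducial
placement:

* each EGM has its steepest negative slope exactly at ``beat + AT_k``;
* the T-wave of electrode ``k`` has its maximum dV/dt exactly at
  ``beat + AT_k + ARI_{k,beat}`` where
  ``ARI = ari_base + at_ari_slope * (AT_k - mean AT) + eps_beat`` with
  ``eps_beat ~ N(0, stv_sigma^2)`` iid per beat;
* the MAP has its steepest upstroke at ``beat + rv_at`` and crosses the
  20%-of-amplitude level exactly ``MAPD`` later;
* after the start of a dofetilide infusion ARIs prolong by
  ``ari_gain * (1 + gradient_weight * earliness_k)``, ramped linearly over
  the infusion (5 min by default) and then held, where ``earliness_k`` is
  the rank-normalized earliness of electrode ``k`` centred on zero
  (earliest +0.5, latest -0.5), so early-activated regions prolong most.

Ectopic runs suspend the regular rhythm; polymorphic runs rotate QRS
polarity and amplitude with a period of >= 3 beats, monomorphic runs do
not.  All randomness comes from one seeded generator, so identical
parameters give bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .strain import DEFAULT_WALL_MAP, SEGMENTS, StrainCurveSet

MS_PER_MIN = 60_000.0

# fixed morphology constants (ms / dimensionless amplitudes)
QRS_WAVELET_SIGMA = 8.0
EGM_T_SIGMA = 25.0
EGM_T_AMP = 0.6
ECG_T_AMP = 0.3
ECG_P_AMP = 0.15
ECG_P_WIDTH = 50.0
ECTOPIC_QRS_MS = 140.0
MAP_RISE_MS = 2.0
_MAPD_X = float(np.arccos(-0.6) / np.pi)  # fractional position of the 20% crossing


@dataclass(frozen=True)
class DofetilideSpec:
    """Time-varying I_Kr-block challenge.

    ``ari_gain_ms`` is the steady-state mean ARI prolongation; the spatial
    gradient (early regions prolong more) is controlled by
    ``gradient_weight``; the effect ramps linearly over ``ramp_s`` seconds.
    """

    start_s: float
    ari_gain_ms: float = 120.0
    gradient_weight: float = 0.5
    ramp_s: float = 300.0


@dataclass(frozen=True)
class EpisodeSpec:
    """A scripted run of ectopic beats."""

    onset_s: float
    n_beats: int
    polymorphic: bool = True
    cycle_ms: float = 320.0
    defibrillations: int = 0

    def validate(self) -> None:
        if self.n_beats < 1:
            raise ValueError("an episode needs n_beats >= 1")
        if self.cycle_ms <= 0:
            raise ValueError("episode cycle_ms must be positive")
        if self.defibrillations < 0:
            raise ValueError("defibrillation count cannot be negative")


DEFAULT_ELECTRODE_ATS = (18.0, 14.0, 11.0, 10.0, 12.0, 16.0, 21.0, 27.0, 33.0, 38.0)


@dataclass
class SynthParams:
    """Generator parameters; defaults are a paced 60 bpm baseline."""

    rate_bpm: float = 60.0
    duration_s: float = 120.0
    fs_hz: float = 1000.0
    electrode_ats: tuple = DEFAULT_ELECTRODE_ATS
    ari_base_ms: float = 280.0
    at_ari_slope: float = -0.4
    stv_sigma_ms: float = 0.75
    map_stv_sigma_ms: float | None = None
    rv_at_ms: float = 30.0
    mapd_base_ms: float = 230.0
    qrs_ms: float = 100.0
    qt_ms: float = 340.0
    tpe_ms: float = 55.0
    egm_t_polarity: int = 1
    atrial_rate_bpm: float | None = None
    noise_sd: float = 0.01
    dofetilide: DofetilideSpec | None = None
    ectopy: list[EpisodeSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.rate_bpm <= 0:
            raise ValueError("rate_bpm must be positive")
        if len(self.electrode_ats) != 10:
            raise ValueError("electrode_ats must have exactly 10 entries")
        if self.stv_sigma_ms < 0:
            raise ValueError("stv_sigma_ms must be non-negative")
        if self.qt_ms <= self.qrs_ms:
            raise ValueError("qt_ms must exceed qrs_ms")
        if self.tpe_ms <= 0 or self.tpe_ms >= self.qt_ms - self.qrs_ms:
            raise ValueError("tpe_ms must lie inside the JT interval")
        if self.egm_t_polarity not in (1, -1):
            raise ValueError("egm_t_polarity must be +1 or -1")
        for ep in self.ectopy:
            ep.validate()
            end_ms = ep.onset_s * 1000.0 + (ep.n_beats - 1) * ep.cycle_ms
            if ep.onset_s < 0 or end_ms >= self.duration_s * 1000.0:
                raise ValueError(f"episode at {ep.onset_s} s is not within the recording")


@dataclass
class BeatSchedule:
    times_ms: np.ndarray
    ectopic: np.ndarray  # bool
    episode_id: np.ndarray  # -1 for regular beats
    run_pos: np.ndarray  # position within the ectopic run, -1 for regular


@dataclass
class SignalRecording:
    """Synchronized multi-channel time series plus channel metadata."""

    data: np.ndarray  # (n_samples, n_channels)
    channel_names: list[str]
    roles: dict[str, str]
    fs_hz: float
    pacing_spikes_ms: np.ndarray
    dofetilide_start_s: float | None = None
    meta: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]

    @property
    def egm_names(self) -> list[str]:
        return [c for c in self.channel_names if self.roles.get(c) == "egm"]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs_hz


@dataclass
class GroundTruth:
    """Everything the generator knows; the oracle for extraction tests."""

    beat_times_ms: np.ndarray
    ectopic: np.ndarray
    episode_id: np.ndarray
    electrode_ats: np.ndarray
    at_ms: np.ndarray  # (n_beats, 10) absolute-offset activation per electrode
    ari_ms: np.ndarray  # (n_beats, 10), NaN for ectopic beats
    rv_at_ms: np.ndarray
    mapd_ms: np.ndarray  # NaN for ectopic beats
    qrs_on_ms: np.ndarray
    qrs_off_ms: np.ndarray
    t_peak_ms: np.ndarray  # NaN for ectopic beats
    t_end_ms: np.ndarray
    events: list[dict]
    atrial_times_ms: np.ndarray | None = None


def make_beat_schedule(params: SynthParams) -> BeatSchedule:
    """Regular beats at 60000/rate_bpm ms spacing with ectopic runs inserted.

    Regular beats are suspended during a run and resume on the original
    grid no earlier than 0.85 cycle after the run ends.  Overlapping
    episodes raise, naming both.
    """
    params.validate()
    cycle = MS_PER_MIN / params.rate_bpm
    duration_ms = params.duration_s * 1000.0
    first = 500.0
    if first >= duration_ms:
        raise ValueError("duration too short for a single beat")
    regular = np.arange(first, duration_ms, cycle)

    episodes = sorted(enumerate(params.ectopy), key=lambda kv: kv[1].onset_s)
    spans = []
    for idx, ep in episodes:
        onset = ep.onset_s * 1000.0
        run_end = onset + (ep.n_beats - 1) * ep.cycle_ms
        spans.append((idx, onset - 150.0, run_end + 0.85 * cycle, ep))
    for (i, _, e0, _), (j, s1, _, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError(f"ectopic episodes {i} and {j} overlap")

    times = [(t, False, -1, -1) for t in regular]
    for idx, s0, e0, ep in spans:
        times = [b for b in times if not (s0 <= b[0] < e0)]
        onset = ep.onset_s * 1000.0
        for k in range(ep.n_beats):
            times.append((onset + k * ep.cycle_ms, True, idx, k))
    times.sort(key=lambda b: b[0])
    if not times:
        raise ValueError("duration too short for a single beat")
    arr = np.array([b[0] for b in times])
    return BeatSchedule(
        times_ms=arr,
        ectopic=np.array([b[1] for b in times], dtype=bool),
        episode_id=np.array([b[2] for b in times], dtype=int),
        run_pos=np.array([b[3] for b in times], dtype=int),
    )


# ---------------------------------------------------------------- waveforms

def _render(arr: np.ndarray, fs: float, a_ms: float, b_ms: float, fn) -> None:
    """Add ``fn(t_ms)`` to ``arr`` on the absolute interval [a_ms, b_ms]."""
    n = arr.shape[0]
    i0 = max(int(np.ceil(a_ms * fs / 1000.0)), 0)
    i1 = min(int(np.floor(b_ms * fs / 1000.0)) + 1, n)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) * (1000.0 / fs)
    arr[i0:i1] += fn(t)


def _halfsine(t, t0, width, amp):
    u = (t - t0) / width
    return amp * np.where((u >= 0) & (u <= 1), np.sin(np.pi * np.clip(u, 0, 1)), 0.0)


def _tbump(t, t_on, t_pk, t_end, amp):
    """Asymmetric T wave from two quarter-sine limbs; peak at t_pk, zero at
    t_on / t_end with a linear (detectable) landing slope."""
    y = np.zeros_like(t)
    rise = (t >= t_on) & (t <= t_pk)
    fall = (t > t_pk) & (t <= t_end)
    y[rise] = np.sin(0.5 * np.pi * (t[rise] - t_on) / (t_pk - t_on))
    y[fall] = np.sin(0.5 * np.pi * (t_end - t[fall]) / (t_end - t_pk))
    return amp * y


def _qrs_wavelet(t, t0, sigma, amp):
    """Biphasic intrinsic deflection; steepest negative slope exactly at t0."""
    u = (t - t0) / sigma
    return -amp * u * np.exp(0.5 - 0.5 * u * u)


def _gauss(t, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _map_shape(t, up_ms, mapd_ms, amp):
    """MAP: tanh upstroke (steepest slope at up_ms), plateau, cosine phase-3
    repolarization crossing 20% of amplitude exactly mapd_ms after upstroke."""
    tau = t - up_ms
    rise = 0.5 * (1.0 + np.tanh(tau / MAP_RISE_MS))
    d0 = max(mapd_ms - 80.0, 0.55 * mapd_ms)
    d1 = d0 + (mapd_ms - d0) / _MAPD_X
    decay = np.ones_like(tau)
    m = tau > d0
    decay[m] = 0.5 * (1.0 + np.cos(np.pi * np.clip((tau[m] - d0) / (d1 - d0), 0, 1)))
    return amp * rise * decay


def _map_support(mapd_ms: float) -> float:
    d0 = max(mapd_ms - 80.0, 0.55 * mapd_ms)
    return d0 + (mapd_ms - d0) / _MAPD_X


def _ectopic_polarity_amp(pos: int, polymorphic: bool) -> tuple[int, float]:
    """QRS polarity/amplitude rotation with period 4 (>= 3) for polymorphic
    runs; constant morphology for monomorphic runs."""
    if not polymorphic:
        return 1, 1.1
    pol = 1 if (pos // 2) % 2 == 0 else -1
    amp = 0.9 + 0.3 * np.sin(2.0 * np.pi * pos / 4.0)
    return pol, float(amp)


# ------------------------------------------------------------------ recording

def synth_recording(params: SynthParams) -> tuple[SignalRecording, GroundTruth]:
    """Render a full multi-channel recording and its ground truth."""
    params.validate()
    sched = make_beat_schedule(params)
    fs = params.fs_hz
    n = int(round(params.duration_s * fs))
    nb = len(sched.times_ms)
    K = 10

    rng = np.random.default_rng(params.seed)
    r_ari, r_map, r_noise = rng.spawn(3)

    ats = np.asarray(params.electrode_ats, dtype=float)
    mean_at = ats.mean()
    ranks = rankdata(ats)  # 1 = earliest
    earliness = 0.5 - (ranks - 1.0) / (K - 1.0)

    dof = params.dofetilide
    t_beats = sched.times_ms

    def ramp(t_ms: float) -> float:
        if dof is None:
            return 0.0
        return float(np.clip((t_ms / 1000.0 - dof.start_s) / dof.ramp_s, 0.0, 1.0))

    eps = r_ari.normal(0.0, params.stv_sigma_ms, nb)
    map_sigma = (params.map_stv_sigma_ms
                 if params.map_stv_sigma_ms is not None else params.stv_sigma_ms)
    eps_map = r_map.normal(0.0, map_sigma, nb)

    ari = np.full((nb, K), np.nan)
    mapd = np.full(nb, np.nan)
    at_abs = np.tile(ats, (nb, 1))
    for b in range(nb):
        r = ramp(t_beats[b])
        if not sched.ectopic[b]:
            gain = (dof.ari_gain_ms * r) if dof is not None else 0.0
            ari[b] = (params.ari_base_ms
                      + params.at_ari_slope * (ats - mean_at)
                      + eps[b]
                      + gain * (1.0 + (dof.gradient_weight if dof else 0.0) * earliness))
            mapd[b] = params.mapd_base_ms + eps_map[b] + gain

    ecg = np.zeros(n)
    egms = [np.zeros(n) for _ in range(K)]
    mapc = np.zeros(n)

    qrs_on = np.array(t_beats)
    qrs_off = np.empty(nb)
    t_pk = np.full(nb, np.nan)
    t_end = np.full(nb, np.nan)

    coupled_p = params.atrial_rate_bpm is None
    for b in range(nb):
        T = t_beats[b]
        if sched.ectopic[b]:
            ep = params.ectopy[sched.episode_id[b]]
            pol, amp = _ectopic_polarity_amp(sched.run_pos[b], ep.polymorphic)
            _render(ecg, fs, T, T + ECTOPIC_QRS_MS,
                    lambda t: _halfsine(t, T, ECTOPIC_QRS_MS, pol * amp))
            qrs_off[b] = T + ECTOPIC_QRS_MS
            for k in range(K):
                t0 = T + ats[k]
                _render(egms[k], fs, t0 - 5 * QRS_WAVELET_SIGMA, t0 + 5 * QRS_WAVELET_SIGMA,
                        lambda t, t0=t0, p=pol: _qrs_wavelet(t, t0, QRS_WAVELET_SIGMA, 0.8 * p))
            up = T + params.rv_at_ms
            mde = 0.75 * params.mapd_base_ms
            _render(mapc, fs, up - 25.0, up + _map_support(mde) + 2.0,
                    lambda t, up=up, m=mde: _map_shape(t, up, m, 1.0))
        else:
            # surface ECG: P (if coupled), half-sine QRS, asymmetric T
            if coupled_p:
                _render(ecg, fs, T - 185.0, T - 135.0,
                        lambda t: _halfsine(t, T - 185.0, ECG_P_WIDTH, ECG_P_AMP))
            _render(ecg, fs, T, T + params.qrs_ms,
                    lambda t: _halfsine(t, T, params.qrs_ms, 1.0))
            te = T + params.qt_ms
            tp = te - params.tpe_ms
            rise_w = min(2.0 * params.tpe_ms, tp - (T + params.qrs_ms) - 5.0)
            ton = tp - rise_w
            _render(ecg, fs, ton, te, lambda t, a=ton, p=tp, e=te: _tbump(t, a, p, e, ECG_T_AMP))
            qrs_off[b] = T + params.qrs_ms
            t_pk[b] = tp
            t_end[b] = te
            # unipolar EGMs
            for k in range(K):
                t0 = T + ats[k]
                _render(egms[k], fs, t0 - 5 * QRS_WAVELET_SIGMA, t0 + 5 * QRS_WAVELET_SIGMA,
                        lambda t, t0=t0: _qrs_wavelet(t, t0, QRS_WAVELET_SIGMA, 1.0))
                rt = t0 + ari[b, k]
                if params.egm_t_polarity > 0:
                    mu, amp_t = rt + EGM_T_SIGMA, EGM_T_AMP
                else:
                    mu, amp_t = rt - EGM_T_SIGMA, -EGM_T_AMP
                _render(egms[k], fs, mu - 5 * EGM_T_SIGMA, mu + 5 * EGM_T_SIGMA,
                        lambda t, mu=mu, a=amp_t: _gauss(t, mu, EGM_T_SIGMA, a))
            # RV MAP
            up = T + params.rv_at_ms
            _render(mapc, fs, up - 25.0, up + _map_support(mapd[b]) + 2.0,
                    lambda t, up=up, m=mapd[b]: _map_shape(t, up, m, 1.0))

    atrial = None
    if not coupled_p:
        # dissociated atrial train; P waves falling inside a ventricular
        # QRS-T complex are hidden there and are not rendered (they would
        # be unreadable on the surface lead anyway)
        a_cycle = MS_PER_MIN / params.atrial_rate_bpm
        atrial = np.arange(300.0, params.duration_s * 1000.0 - ECG_P_WIDTH, a_cycle)
        v_lo = t_beats - 40.0
        v_hi = np.where(sched.ectopic, t_beats + ECTOPIC_QRS_MS + 40.0,
                        t_beats + params.qt_ms + 40.0)
        visible = []
        for ta in atrial:
            j = np.searchsorted(t_beats, ta)
            clash = False
            for k in (j - 1, j):
                if 0 <= k < nb and ta + ECG_P_WIDTH > v_lo[k] and ta < v_hi[k]:
                    clash = True
            if not clash:
                visible.append(ta)
                _render(ecg, fs, ta, ta + ECG_P_WIDTH,
                        lambda t, ta=ta: _halfsine(t, ta, ECG_P_WIDTH, ECG_P_AMP))
        atrial = np.asarray(visible)

    channels = [ecg] + egms + [mapc]
    if params.noise_sd > 0:
        for ch in channels:
            ch += r_noise.normal(0.0, params.noise_sd, n)

    names = ["ecg"] + [f"egm{k + 1}" for k in range(K)] + ["map"]
    roles = {"ecg": "ecg", "map": "map", **{f"egm{k + 1}": "egm" for k in range(K)}}
    events = []
    for idx, ep in enumerate(params.ectopy):
        mask = sched.episode_id == idx
        if mask.any():
            events.append({
                "start_ms": float(t_beats[mask].min()),
                "end_ms": float(t_beats[mask].max()),
                "n_beats": int(mask.sum()),
                "polymorphic": bool(ep.polymorphic),
                "defibrillations": int(ep.defibrillations),
            })
    rec = SignalRecording(
        data=np.column_stack(channels),
        channel_names=names,
        roles=roles,
        fs_hz=fs,
        pacing_spikes_ms=t_beats.copy(),
        dofetilide_start_s=dof.start_s if dof else None,
        meta={"seed": params.seed, "rate_bpm": params.rate_bpm,
              "events": events},
    )
    gt = GroundTruth(
        beat_times_ms=t_beats.copy(),
        ectopic=sched.ectopic.copy(),
        episode_id=sched.episode_id.copy(),
        electrode_ats=ats,
        at_ms=at_abs,
        ari_ms=ari,
        rv_at_ms=np.full(nb, params.rv_at_ms),
        mapd_ms=mapd,
        qrs_on_ms=qrs_on,
        qrs_off_ms=qrs_off,
        t_peak_ms=t_pk,
        t_end_ms=t_end,
        events=events,
        atrial_times_ms=atrial,
    )
    return rec, gt


# -------------------------------------------------------------------- strain

#: sqrt(2 ln 10): Gaussian half-width (in sigmas) at 10% of peak
_W10 = float(np.sqrt(2.0 * np.log(10.0)))


@dataclass(frozen=True)
class SegmentSpec:
    onset_ms: float
    ttp_ms: float
    ps_pct: float
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not (self.ttp_ms > self.onset_ms >= 0):
            raise ValueError("need ttp_ms > onset_ms >= 0")
        if not np.isfinite(self.ps_pct):
            raise ValueError("ps_pct must be finite")


@dataclass
class StrainSynthParams:
    """Six per-segment pulse specifications."""

    segments: dict[str, SegmentSpec]
    duration_ms: float = 800.0
    wall_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_WALL_MAP)
    )
    seed: int = 0

    def validate(self) -> None:
        if set(self.segments) != set(SEGMENTS):
            raise ValueError(f"segments must be exactly {SEGMENTS}")
        for spec in self.segments.values():
            spec.validate()


def synth_strain(params: StrainSynthParams, fs_hz: float = 1000.0) -> StrainCurveSet:
    """Smooth unimodal strain pulses with known PS / onset / TTP.

    Each segment is a Gaussian bump peaking at ``ps_pct`` at ``ttp_ms``
    whose 10%-of-peak crossing falls exactly at ``onset_ms`` — the same
    operational onset definition the feature extractor uses.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_ms * fs_hz / 1000.0))
    t = np.arange(n) * (1000.0 / fs_hz)
    traces = {}
    for name in SEGMENTS:
        spec = params.segments[name]
        s = (spec.ttp_ms - spec.onset_ms) / _W10
        y = spec.ps_pct * np.exp(-0.5 * ((t - spec.ttp_ms) / s) ** 2)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, n)
        traces[name] = y
    return StrainCurveSet(time_ms=t, traces=traces,
                          wall_map=dict(params.wall_map), reference_ms=0.0)


def strain_params_for_walls(
    free_wall: tuple[float, float, float],
    septum: tuple[float, float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_ms: float = 800.0,
) -> StrainSynthParams:
    """Build a six-segment parameter set from (ps_pct, onset_ms, ttp_ms)
    per wall; both segments of a wall share the wall values and the two
    discarded intermediate segments get their average."""
    ps_f, on_f, ttp_f = free_wall
    ps_s, on_s, ttp_s = septum
    mid = SegmentSpec(0.5 * (on_f + on_s), 0.5 * (ttp_f + ttp_s),
                      0.5 * (ps_f + ps_s), noise_sd)
    segs = {
        "anterolateral": SegmentSpec(on_f, ttp_f, ps_f, noise_sd),
        "inferolateral": SegmentSpec(on_f, ttp_f, ps_f, noise_sd),
        "anteroseptal": SegmentSpec(on_s, ttp_s, ps_s, noise_sd),
        "inferoseptal": SegmentSpec(on_s, ttp_s, ps_s, noise_sd),
        "anterior": mid,
        "inferior": mid,
    }
    return StrainSynthParams(segments=segs, seed=seed, duration_ms=duration_ms)
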