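"""Reading and writing the package's on-disk formats.

A recording is stored as one numeric matrix (columns = channels), either
an HDF5 container (default) or a CSV, plus a JSON sidecar carrying the
sampling rate, channel roles, pacing-spike times and the dofetilide start.
Ground truth, annotations, events and strain curves travel as tidy CSVs
with documented column schemas (times in ms).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .arrhythmia import ArrhythmiaEvent
from .fiducials import BeatAnnotation
from .strain import StrainCurveSet, DEFAULT_WALL_MAP
from .synth import GroundTruth, SignalRecording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_recording(rec: SignalRecording, path) -> Path:
    """Write the signal matrix (.h5 or .csv, chosen by extension) plus a
    JSON sidecar; returns the sidecar path."""
    path = Path(path)
    if path.suffix == ".h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=rec.data, compression="gzip")
    elif path.suffix == ".csv":
        pd.DataFrame(rec.data, columns=rec.channel_names).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported recording container {path.suffix!r}")
    side = {
        "fs_hz": rec.fs_hz,
        "channel_names": rec.channel_names,
        "roles": rec.roles,
        "pacing_spikes_ms": np.asarray(rec.pacing_spikes_ms).tolist(),
        "dofetilide_start_s": rec.dofetilide_start_s,
        "meta": rec.meta,
    }
    sp = _sidecar_path(path)
    sp.write_text(json.dumps(side, indent=1))
    return sp


def load_recording(path) -> SignalRecording:
    path = Path(path)
    if path.suffix == ".h5":
        with h5py.File(path, "r") as f:
            data = f["signals"][...]
    elif path.suffix == ".csv":
        data = pd.read_csv(path).to_numpy(dtype=float)
    else:
        raise ValueError(f"unsupported recording container {path.suffix!r}")
    side = json.loads(_sidecar_path(path).read_text())
    return SignalRecording(
        data=data,
        channel_names=list(side["channel_names"]),
        roles=dict(side["roles"]),
        fs_hz=float(side["fs_hz"]),
        pacing_spikes_ms=np.asarray(side["pacing_spikes_ms"], dtype=float),
        dofetilide_start_s=side.get("dofetilide_start_s"),
        meta=side.get("meta", {}),
    )


def ground_truth_frames(gt: GroundTruth) -> dict[str, pd.DataFrame]:
    """Ground truth as tidy frames: per-beat scalars, per-beat-per-electrode
    AT/ARI, and the scripted event list."""
    beats = pd.DataFrame({
        "beat_time_ms": gt.beat_times_ms,
        "ectopic": gt.ectopic,
        "episode_id": gt.episode_id,
        "rv_at_ms": gt.rv_at_ms,
        "mapd_ms": gt.mapd_ms,
        "qrs_on_ms": gt.qrs_on_ms,
        "qrs_off_ms": gt.qrs_off_ms,
        "t_peak_ms": gt.t_peak_ms,
        "t_end_ms": gt.t_end_ms,
    })
    nb, K = gt.ari_ms.shape
    long = pd.DataFrame({
        "beat": np.repeat(np.arange(nb), K),
        "electrode": np.tile(np.arange(1, K + 1), nb),
        "at_ms": gt.at_ms.ravel(),
        "ari_ms": gt.ari_ms.ravel(),
    })
    events = pd.DataFrame(gt.events) if gt.events else pd.DataFrame(
        columns=["start_ms", "end_ms", "n_beats", "polymorphic", "defibrillations"])
    return {"beats": beats, "electrodes": long, "events": events}


def save_ground_truth(gt: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in ground_truth_frames(gt).items():
        frame.to_csv(out / f"ground_truth_{name}.csv", index=False)


def annotations_to_frame(beats: list[BeatAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(b) for b in beats])


def annotations_from_frame(df: pd.DataFrame) -> list[BeatAnnotation]:
    fields = [f.name for f in dataclasses.fields(BeatAnnotation)]
    return [BeatAnnotation(**{k: row[k] for k in fields})
            for _, row in df.iterrows()]


def events_to_frame(events: list[ArrhythmiaEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        d = dataclasses.asdict(e)
        d.pop("beat_indices")
        rows.append(d)
    return pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["start_ms", "end_ms", "n_beats", "polymorphism_index",
                 "is_tdp", "defibrillations", "terminated_by_cardioversion"])


def events_from_frame(df: pd.DataFrame) -> list[ArrhythmiaEvent]:
    events = []
    for _, row in df.iterrows():
        events.append(ArrhythmiaEvent(
            start_ms=float(row["start_ms"]),
            end_ms=float(row["end_ms"]),
            n_beats=int(row["n_beats"]),
            polymorphism_index=float(row.get("polymorphism_index", np.nan)),
            is_tdp=bool(row.get("is_tdp", False)),
            defibrillations=int(row.get("defibrillations", 0)),
        ))
    return events


def strain_to_long(curves: StrainCurveSet) -> pd.DataFrame:
    """Long format: segment, time_ms, strain_pct."""
    frames = [pd.DataFrame({"segment": name, "time_ms": curves.time_ms,
                            "strain_pct": tr})
              for name, tr in curves.traces.items()]
    return pd.concat(frames, ignore_index=True)


def strain_from_long(df: pd.DataFrame, wall_map=None,
                     reference_ms: float = 0.0) -> StrainCurveSet:
    traces = {}
    time_ms = None
    for name, g in df.groupby("segment", sort=False):
        g = g.sort_values("time_ms")
        traces[str(name)] = g["strain_pct"].to_numpy(dtype=float)
        if time_ms is None:
            time_ms = g["time_ms"].to_numpy(dtype=float)
    return StrainCurveSet(time_ms=time_ms, traces=traces,
                          wall_map=dict(wall_map or DEFAULT_WALL_MAP),
                          reference_ms=reference_ms)
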