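"""Readers and writers for the package's on-disk formats.

* WAV: mono PCM16 or float32, via ``scipy.io.wavfile``; PCM is normalized
  to full-scale floats on read.
* Attenuation functions: two-column CSV ``hz,db``.
* Filters: JSON ``{"order", "rate", "taps"}``.
* Landmarks: long CSV ``frame,point_id,x,y``.
* Trial tables: CSV with the standard trial columns; rows are validated on
  load and every offending line is reported by number.

CSV files are comma-separated UTF-8 with a required header; lines starting
with ``#`` are provenance comments and are skipped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile as _wavfile

from .acoustics import AttenuationFunction, MaskFilter, Waveform
from .scoring import TRIAL_COLUMNS, validate_trials
from .visual import N_LANDMARKS, LandmarkFrame

__all__ = [
    "read_wav",
    "write_wav",
    "read_attenuation_csv",
    "write_attenuation_csv",
    "read_filter_json",
    "write_filter_json",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "load_trial_table",
    "write_trial_table",
]


def read_wav(path) -> Waveform:
    rate, data = _wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples, rate)


def write_wav(path, wave: Waveform, subtype: str = "float32") -> None:
    if subtype == "float32":
        _wavfile.write(path, wave.rate, wave.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(wave.samples, -1.0, 1.0)
        _wavfile.write(path, wave.rate, (clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def write_attenuation_csv(path, att: AttenuationFunction, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("hz,db\n")
        for f, a in zip(att.frequencies, att.attenuation_db):
            fh.write(f"{f:.6g},{a:.6g}\n")


def read_attenuation_csv(path, provenance: str = "") -> AttenuationFunction:
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["hz", "db"]:
        raise ValueError(f"{path}: expected columns hz,db, got {list(df.columns)}")
    return AttenuationFunction(df["hz"].to_numpy(), df["db"].to_numpy(),
                               provenance or str(path))


def write_filter_json(path, filt: MaskFilter, extra: dict | None = None) -> None:
    payload = {"order": filt.order, "rate": filt.rate,
               "taps": filt.taps.tolist()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_filter_json(path) -> MaskFilter:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return MaskFilter(np.asarray(payload["taps"], dtype=float),
                      rate=int(payload["rate"]))


def write_landmarks_csv(path, frames: list[LandmarkFrame]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame,point_id,x,y\n")
        for frame in frames:
            for pid, (x, y) in enumerate(frame.points):
                fh.write(f"{frame.frame_index},{pid},{x:.3f},{y:.3f}\n")


def read_landmarks_csv(path, frame_size=None) -> list[LandmarkFrame]:
    df = pd.read_csv(path, comment="#")
    frames = []
    for idx, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values("point_id")
        if list(sub["point_id"]) != list(range(N_LANDMARKS)):
            raise ValueError(
                f"{path}: frame {idx} does not contain point_ids 0..{N_LANDMARKS - 1}"
            )
        frames.append(LandmarkFrame(int(idx), sub[["x", "y"]].to_numpy(),
                                    frame_size=frame_size))
    return frames


def load_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial CSV; errors name offending data rows."""
    df = pd.read_csv(path, comment="#",
                     dtype={"subject_id": str, "target": str, "response": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        validate_trials(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None
    return df


def write_trial_table(path, trials: pd.DataFrame, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        trials.to_csv(fh, index=False)
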