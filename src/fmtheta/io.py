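"""Readers and writers for the pipeline's on-disk artifacts.

EEG interchange comes in two flavors:

* European Data Format (EDF+C), one file per session, with segment
  boundaries and blink events stored as standard EDF annotations.  Writing
  uses a minimal EDF+ encoder implemented here (16-bit quantization);
  reading goes through :mod:`mne`, which also serves as an independent
  decoder of the files this module produces.
* A lossless plain binary matrix (float64) with a JSON sidecar, used where
  bit-identical round trips matter.

Morphometry tables are TSV/CSV with canonical column names (atlas-style
aliases are accepted, see :func:`fmtheta.rois.roi_alias_map`).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNELS
from .errors import FormatError, ValidationError
from .feedback import ArtifactBand, BaselineReference, SessionRecord
from .rois import canonical_roi_columns, roi_alias_map
from .synthetic import EEGRecording, SubjectProfile

# ---------------------------------------------------------------------------
# EDF+C

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise FormatError(f"EDF header field too long: {text!r}")
    return raw.ljust(width)


def write_edf(recording: EEGRecording, path: str | Path,
              annotation_bytes_per_record: int = 512) -> None:
    """Write a recording as EDF+C with one-second data records.

    Samples are quantized to 16 bits over each channel's physical range, so
    the round-trip error is at most one quantization step.  Segment intervals
    are written as annotations ``label`` with onset/duration; blink events as
    zero-duration ``blink`` annotations.
    """
    path = Path(path)
    fs = recording.sampling_rate_hz
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_records = recording.n_samples / spr
    if abs(n_records - round(n_records)) > 1e-9:
        raise FormatError("EDF writer requires an integer number of seconds")
    n_records = int(round(n_records))
    n_sig = len(recording.channel_labels)

    pmins = np.floor(recording.data.min(axis=1))
    pmaxs = np.ceil(recording.data.max(axis=1))
    flat = pmaxs <= pmins
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0
    scale = (_DIG_MAX - _DIG_MIN) / (pmaxs - pmins)
    digital = np.rint((recording.data - pmins[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    ann_per_rec = annotation_bytes_per_record // 2
    tals: dict[int, list[bytes]] = {r: [] for r in range(n_records)}
    for label, start, end in recording.segments:
        rec = min(int(start), n_records - 1)
        tals[rec].append(f"+{start:g}\x15{end - start:g}\x14{label}\x14".encode("ascii"))
    for t in np.asarray(recording.blink_events, dtype=float):
        rec = min(int(t), n_records - 1)
        tals[rec].append(f"+{t:.3f}\x14blink\x14".encode("ascii"))

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (n_sig + 2)), 8), _pad("EDF+C", 44),
        _pad(str(n_records), 8), _pad("1", 8), _pad(str(n_sig + 1), 4),
    ])
    labels = [_pad(ch, 16) for ch in recording.channel_labels] + [_pad("EDF Annotations", 16)]
    fields = [
        b"".join(labels),
        b"".join(_pad("", 80) for _ in range(n_sig + 1)),
        b"".join([_pad("uV", 8)] * n_sig + [_pad("", 8)]),
        b"".join([_pad(f"{v:g}"[:8], 8) for v in pmins] + [_pad("-1", 8)]),
        b"".join([_pad(f"{v:g}"[:8], 8) for v in pmaxs] + [_pad("1", 8)]),
        b"".join([_pad(str(_DIG_MIN), 8)] * (n_sig + 1)),
        b"".join([_pad(str(_DIG_MAX), 8)] * (n_sig + 1)),
        b"".join(_pad("", 80) for _ in range(n_sig + 1)),
        b"".join([_pad(str(spr), 8)] * n_sig + [_pad(str(ann_per_rec), 8)]),
        b"".join(_pad("", 32) for _ in range(n_sig + 1)),
    ]

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
            payload = f"+{r}\x14\x14\x00".encode("ascii") + b"\x00".join(tals[r])
            if len(payload) > annotation_bytes_per_record:
                raise FormatError(f"too many annotations in second {r} to fit the "
                                  "annotation channel; increase annotation_bytes_per_record")
            fh.write(payload.ljust(annotation_bytes_per_record, b"\x00"))


def read_edf(path: str | Path,
             require_channels: tuple[str, ...] | None = CHANNELS) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (via mne)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:           # malformed file
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    labels = tuple(raw.ch_names)
    if require_channels:
        missing = [ch for ch in require_channels if ch not in labels]
        if missing:
            raise FormatError(f"EDF file {path} is missing channel(s): "
                              f"{', '.join(missing)}")
    data = raw.get_data() * 1e6        # Volts -> uV
    segments: list[tuple[str, float, float]] = []
    blinks: list[float] = []
    for onset, duration, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                     raw.annotations.description):
        if desc == "blink":
            blinks.append(float(onset))
        else:
            segments.append((str(desc), float(onset), float(onset + duration)))
    return EEGRecording(float(raw.info["sfreq"]), labels, data, segments,
                        np.asarray(blinks))


# ---------------------------------------------------------------------------
# Lossless matrix + JSON sidecar

def write_eeg_matrix(recording: EEGRecording, prefix: str | Path) -> None:
    prefix = Path(prefix)
    recording.data.astype("<f8").tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_labels": list(recording.channel_labels),
        "n_samples": int(recording.n_samples),
        "dtype": "<f8", "order": "C",
        "segments": [[label, s, e] for label, s, e in recording.segments],
        "blink_events": np.asarray(recording.blink_events, dtype=float).tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg_matrix(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    try:
        meta = json.loads(prefix.with_suffix(".json").read_text())
        labels = tuple(meta["channel_labels"])
        data = np.fromfile(prefix.with_suffix(".bin"), dtype=meta["dtype"])
        data = data.reshape(len(labels), meta["n_samples"])
    except (KeyError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read matrix+JSON pair at {prefix}: {exc}") from exc
    return EEGRecording(float(meta["sampling_rate_hz"]), labels, data,
                        [tuple(seg) for seg in meta["segments"]],
                        np.asarray(meta["blink_events"], dtype=float))


# ---------------------------------------------------------------------------
# ROI morphometry tables

def write_roi_table(table: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_csv(path, sep=sep, index=True, index_label="subject_id")


def read_roi_table(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a subjects x ROI-measures table (TSV or CSV).

    Atlas-style aliases are mapped to canonical names; unknown columns are
    reported with a warning and dropped.  Concentration values outside [0, 1]
    or non-positive volumes raise :class:`ValidationError` naming the
    offending subjects and column.  ``strict=True`` additionally requires all
    40 canonical columns.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    else:
        df = df.set_index(df.columns[0]).rename_axis("subject_id")

    aliases = roi_alias_map()
    canonical = set(canonical_roi_columns())
    rename, unknown = {}, []
    for col in df.columns:
        if col in canonical:
            continue
        if col in aliases:
            rename[col] = aliases[col]
        else:
            unknown.append(col)
    if unknown:
        warnings.warn(f"dropping unknown ROI columns: {', '.join(unknown)}", stacklevel=2)
        df = df.drop(columns=unknown)
    df = df.rename(columns=rename)
    if strict:
        missing = [c for c in canonical_roi_columns() if c not in df.columns]
        if missing:
            raise ValidationError(f"missing ROI columns: {', '.join(missing)}")
    for col in df.columns:
        values = df[col].to_numpy(dtype=float)
        if "_conc_" in col:
            bad = (values < 0) | (values > 1)
            kind = "concentration outside [0, 1]"
        else:
            bad = values <= 0
            kind = "non-positive volume"
        if bad.any():
            subjects = ", ".join(map(str, df.index[bad]))
            raise ValidationError(f"{kind} in column {col} for subject(s): {subjects}")
    return df


# ---------------------------------------------------------------------------
# JSON artifacts: profiles and session records

def _profile_to_dict(profile: SubjectProfile) -> dict:
    d = dataclasses.asdict(profile)
    d["theta_band"] = list(profile.theta_band)
    if profile.morphometry_z is not None:
        d["morphometry_z"] = np.asarray(profile.morphometry_z).tolist()
    if isinstance(profile.artifact_band, ArtifactBand):
        ab = dataclasses.asdict(profile.artifact_band)
        ab["band"] = list(profile.artifact_band.band)
        d["artifact_band"] = ab
    return d


def write_profiles(profiles: list[SubjectProfile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([_profile_to_dict(p) for p in profiles], indent=1))


def read_profiles(path: str | Path) -> list[SubjectProfile]:
    out = []
    for d in json.loads(Path(path).read_text()):
        if d.get("artifact_band"):
            ab = d["artifact_band"]
            d["artifact_band"] = ArtifactBand(ab["center_hz"], tuple(ab["band"]),
                                              ab["amplitude_threshold_uv"])
        if d.get("morphometry_z") is not None:
            d["morphometry_z"] = np.asarray(d["morphometry_z"])
        d["theta_band"] = tuple(d["theta_band"])
        out.append(SubjectProfile(**d))
    return out


def write_sessions(records: dict[str, list[SessionRecord]], path: str | Path) -> None:
    """Serialize per-subject session records to JSON."""
    payload = {}
    for subject, sessions in records.items():
        payload[subject] = [{
            "session_index": s.session_index,
            "segment_labels": list(s.segment_labels),
            "segment_amp_uv": s.segment_amp_uv.tolist(),
            "n_windows_used": s.n_windows_used.tolist(),
            "n_windows_rejected": s.n_windows_rejected.tolist(),
            "baseline_reference": dataclasses.asdict(s.baseline_reference),
            "low_quality_segments": list(s.low_quality_segments),
        } for s in sessions]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sessions(path: str | Path) -> dict[str, list[SessionRecord]]:
    payload = json.loads(Path(path).read_text())
    out: dict[str, list[SessionRecord]] = {}
    for subject, sessions in payload.items():
        out[subject] = [SessionRecord(
            session_index=s["session_index"],
            segment_labels=tuple(s["segment_labels"]),
            segment_amp_uv=np.asarray(s["segment_amp_uv"]),
            n_windows_used=np.asarray(s["n_windows_used"], dtype=int),
            n_windows_rejected=np.asarray(s["n_windows_rejected"], dtype=int),
            baseline_reference=BaselineReference(**s["baseline_reference"]),
            low_quality_segments=tuple(s["low_quality_segments"]),
        ) for s in sessions]
    return out
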