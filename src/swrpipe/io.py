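"""Readers and writers for the pipeline's on-disk formats.

Signals travel as flat binary ``.dat`` files (signed 16-bit little-endian,
channel-interleaved) with a JSON metadata sidecar carrying the sampling rate,
channel roles and scaling — the convention of the NDManager/neurosuite
ecosystem. Hypnograms, event lists, rate bins and behavior records are plain
CSV with documented headers. All interval outputs use half-open ``[start,
end)`` seconds, 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    Bout,
    FormatError,
    Hypnogram,
    ParameterError,
    RateBin,
    RippleEvent,
    SignalRecording,
    ValidationError,
)

INT16_MIN, INT16_MAX = -32768, 32767

HYPNOGRAM_COLUMNS = ["start", "end", "state"]
EVENT_COLUMNS = ["onset", "offset", "peak_time", "duration_ms", "freq_hz", "norm_power"]
BIN_COLUMNS = ["label", "start", "end", "sws_seconds", "count", "rate", "excluded"]


def _sidecar_path(dat_path: str | Path) -> Path:
    return Path(dat_path).with_suffix(".json")


def write_dat(
    rec: SignalRecording, path: str | Path, units_per_sample: float = 1.0
) -> Path:
    """Write a recording as interleaved int16 plus a JSON sidecar.

    Samples are divided by ``units_per_sample`` before rounding to int16;
    values that do not fit the int16 range raise a range error. Returns the
    sidecar path.
    """
    scaled = np.asarray(rec.samples, dtype=float) / units_per_sample
    rounded = np.round(scaled)
    if rounded.size and (rounded.min() < INT16_MIN or rounded.max() > INT16_MAX):
        raise ParameterError(
            "samples exceed the int16 range after scaling; "
            "increase units_per_sample"
        )
    interleaved = rounded.astype("<i2").T.reshape(-1)  # time-major, interleaved
    path = Path(path)
    interleaved.tofile(path)
    sidecar = _sidecar_path(path)
    meta = {
        "fs": rec.fs,
        "channel_roles": rec.channel_roles,
        "units_per_sample": units_per_sample,
        "t0": rec.t0,
        "n_channels": len(rec.channel_roles),
        "dtype": "int16-le",
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_dat(path: str | Path, metadata: dict | str | Path | None = None) -> SignalRecording:
    """Read an interleaved int16 ``.dat`` file back into a SignalRecording.

    ``metadata`` may be a dict or a path to the JSON sidecar; by default the
    sidecar next to ``path`` is used. Required keys: ``fs``,
    ``channel_roles``; optional: ``units_per_sample`` (default 1), ``t0``.
    """
    path = Path(path)
    if metadata is None:
        metadata = _sidecar_path(path)
    if not isinstance(metadata, dict):
        meta_path = Path(metadata)
        if not meta_path.exists():
            raise FormatError(f"missing metadata sidecar {meta_path}")
        metadata = json.loads(meta_path.read_text())
    for key in ("fs", "channel_roles"):
        if key not in metadata:
            raise FormatError(f"metadata missing required field {key!r}")
    roles = list(metadata["channel_roles"])
    n_ch = len(roles)
    raw = np.fromfile(path, dtype="<i2")
    if raw.size % n_ch:
        raise FormatError(
            f"{path} holds {raw.size} samples, not divisible by {n_ch} channels"
        )
    samples = raw.reshape(-1, n_ch).T.astype(float)
    samples *= float(metadata.get("units_per_sample", 1.0))
    return SignalRecording(
        samples=samples,
        fs=float(metadata["fs"]),
        channel_roles=roles,
        t0=float(metadata.get("t0", 0.0)),
    )


def _validate_intervals(df: pd.DataFrame, start: str = "start", end: str = "end") -> None:
    if len(df) == 0:
        return
    if not (df[start] < df[end]).all():
        raise ValidationError("interval with end <= start")
    if not df[start].is_monotonic_increasing:
        raise ValidationError("intervals are not sorted by start")


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        [(b.start, b.end, b.state) for b in hyp], columns=HYPNOGRAM_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    missing = set(HYPNOGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"hypnogram CSV missing columns {sorted(missing)}")
    _validate_intervals(df)
    return Hypnogram(Bout(r.state, r.start, r.end) for r in df.itertuples())


def write_events(events: list[RippleEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.onset, e.offset, e.peak_time, e.duration_ms, e.freq_hz, e.norm_power)
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> list[RippleEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event CSV missing columns {sorted(missing)}")
    _validate_intervals(df, "onset", "offset")
    return [
        RippleEvent(
            onset=r.onset,
            offset=r.offset,
            peak_time=r.peak_time,
            norm_power=r.norm_power,
            duration_ms=r.duration_ms,
            freq_hz=r.freq_hz,
        )
        for r in df.itertuples()
    ]


def write_bins(bins: list[RateBin], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (b.label, b.start, b.end, b.sws_seconds, b.count, b.rate, b.excluded)
            for b in bins
        ],
        columns=BIN_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_bins(path: str | Path) -> list[RateBin]:
    df = pd.read_csv(path)
    missing = set(BIN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"bin CSV missing columns {sorted(missing)}")
    return [
        RateBin(
            label=r.label,
            start=r.start,
            end=r.end,
            sws_seconds=r.sws_seconds,
            count=int(r.count),
            rate=r.rate,
            excluded=bool(r.excluded),
        )
        for r in df.itertuples()
    ]


def read_neurosuite_xml(path: str | Path) -> dict:
    """Best-effort import of NDManager/neurosuite XML metadata.

    Extracts what :func:`read_dat` needs — sampling rate and channel count —
    from the ``acquisitionSystem`` block (falling back to ``lfp``
    ``samplingRate`` if present). Channel roles are not encoded in that
    dialect, so every channel defaults to LFP; override as needed.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(Path(path)).getroot()
    acq = root.find("acquisitionSystem")
    if acq is None:
        raise FormatError(f"{path}: no <acquisitionSystem> block")
    try:
        n_channels = int(acq.findtext("nChannels"))
        fs = float(acq.findtext("samplingRate"))
    except (TypeError, ValueError) as err:
        raise FormatError(f"{path}: missing nChannels/samplingRate") from err
    lfp = root.find("fieldPotentials")
    lfp_rate = lfp.findtext("lfpSamplingRate") if lfp is not None else None
    meta = {
        "fs": fs,
        "channel_roles": ["LFP"] * n_channels,
        "units_per_sample": 1.0,
    }
    if lfp_rate:
        meta["lfp_fs"] = float(lfp_rate)
    bits = acq.findtext("nBits")
    if bits is not None and int(bits) != 16:
        raise FormatError(f"{path}: only 16-bit recordings are supported")
    return meta


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — it is a YAML subset) parameter file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
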