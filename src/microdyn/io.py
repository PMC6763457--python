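"""On-disk formats.

Native recording container: a flat little-endian float64 binary matrix
(channels × samples, C order) plus a JSON sidecar describing channels,
positions, sampling rate, units, and annotations — portable and
language-neutral. Standard EEG interchange formats (BrainVision, EDF) are
read through MNE adapters. Templates are serialised as CSV (channels × k)
plus JSON metadata; tabular results as tidy CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Montage, Recording, TemplateSet


def write_recording(rec: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.bin`` (float64 LE, C-order) and ``<stem>.json``."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    data = np.ascontiguousarray(rec.data, dtype="<f8")
    data.tofile(bin_path)
    sidecar = {
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f8",
        "order": "C",
        "fs": rec.fs,
        "units": "uV",
        "channel_names": list(rec.montage.names),
        "positions": rec.montage.pos.tolist(),
        "montage_name": rec.montage.name,
        "annotations": [[label, a, b] for (label, a, b) in rec.annotations],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path, json_path


def read_recording(stem: str | Path) -> Recording:
    """Read a native container written by :func:`write_recording`."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    sidecar = json.loads(json_path.read_text())
    n_ch, n_samp = sidecar["n_channels"], sidecar["n_samples"]
    raw = np.fromfile(bin_path, dtype=sidecar.get("dtype", "<f8"))
    if raw.size != n_ch * n_samp:
        raise ValueError(
            f"container/sidecar mismatch: {bin_path.name} holds {raw.size} values, "
            f"sidecar expects {n_ch} × {n_samp}"
        )
    montage = Montage(
        names=tuple(sidecar["channel_names"]),
        pos=np.asarray(sidecar["positions"], dtype=float),
        name=sidecar.get("montage_name", "custom"),
    )
    return Recording(
        data=raw.reshape(n_ch, n_samp),
        fs=float(sidecar["fs"]),
        montage=montage,
        annotations=[(a[0], float(a[1]), float(a[2])) for a in sidecar["annotations"]],
    )


def _recording_from_mne(raw) -> Recording:
    import mne  # noqa: F401  (adapter layer)

    picks = [i for i, t in enumerate(raw.get_channel_types()) if t == "eeg"]
    data = raw.get_data(picks=picks) * 1e6  # Volts → µV
    names = [raw.ch_names[i] for i in picks]
    # positions may be absent in interchange files; fall back to a unit circle
    pos = None
    if raw.get_montage() is not None:
        ch_pos = raw.get_montage().get_positions()["ch_pos"]
        if all(n in ch_pos and np.isfinite(ch_pos[n]).all() for n in names):
            xy = np.array([ch_pos[n][:2] for n in names])
            r = np.linalg.norm(xy, axis=1).max()
            pos = xy / r if r > 0 else xy
    if pos is None:
        ang = 2 * np.pi * np.arange(len(names)) / max(len(names), 1)
        pos = np.column_stack([np.cos(ang), np.sin(ang)])
    montage = Montage(names=tuple(names), pos=pos, name="imported")
    annotations = [
        (desc, float(onset), float(onset + dur))
        for desc, onset, dur in zip(
            raw.annotations.description, raw.annotations.onset, raw.annotations.duration
        )
    ]
    return Recording(data=data, fs=float(raw.info["sfreq"]), montage=montage,
                     annotations=annotations)


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision ``.vhdr/.eeg/.vmrk`` triplet (µV, EEG channels only)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _recording_from_mne(raw)


def read_edf(edf_path: str | Path) -> Recording:
    """Read an EDF/EDF+ file (µV, EEG channels only)."""
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return _recording_from_mne(raw)


def write_templates(ts: TemplateSet, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` (channels × k, one column per class) + ``<stem>.json``."""
    stem = Path(stem)
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    index = list(ts.montage.names) if ts.montage is not None else None
    pd.DataFrame(ts.maps.T, columns=list(ts.labels), index=index).to_csv(
        csv_path, index_label="channel" if index else None, index=index is not None
    )
    json_path.write_text(json.dumps({
        "labels": list(ts.labels),
        "level": ts.level,
        "gev_percent": ts.gev_percent,
    }, indent=1))
    return csv_path, json_path


def read_templates(stem: str | Path, montage: Montage | None = None) -> TemplateSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"))
    if "channel" in df.columns:
        df = df.set_index("channel")
    return TemplateSet(
        maps=df[meta["labels"]].to_numpy().T,
        labels=tuple(meta["labels"]),
        level=meta["level"],
        gev_percent=meta["gev_percent"],
        montage=montage,
    )
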