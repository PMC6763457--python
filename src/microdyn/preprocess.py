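"""Preprocessing chain: band-pass filter, average reference, epoching, rejection.

Mirrors a conventional resting-EEG microstate preprocessing chain: zero-phase
2–20 Hz band-pass, re-derivation to average reference, segmentation of the
eyes-closed spans into 2-s epochs, and automatic amplitude-based artifact
rejection at ±100 µV. Ocular-artifact correction (ICA) is intentionally not
implemented; the amplitude criterion alone handles the synthetic data this
package generates, which contain no ocular artifacts.
"""
from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording


def bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Design the band-pass as second-order sections (Butterworth, per-pass order
    ``order`` on each skirt; applied forward-backward for zero phase)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low ({low_hz}) < high ({high_hz}) < fs/2 ({fs / 2})"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: Recording, low_hz: float = 2.0, high_hz: float = 20.0, order: int = 4
) -> Recording:
    """Zero-phase band-pass (forward-backward Butterworth) per channel."""
    sos = bandpass_sos(low_hz, high_hz, rec.fs, order)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def average_reference(rec: Recording) -> Recording:
    """Re-derive to average reference: subtract the per-sample channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def segment_epochs(rec: Recording, epoch_s: float = 2.0) -> EpochSet:
    """Cut the eyes-closed spans into consecutive non-overlapping epochs.

    Only annotation spans labelled ``"eyes_closed"`` are segmented; a trailing
    remainder shorter than ``epoch_s`` is dropped. A recording without any
    eyes-closed annotation yields an empty EpochSet with a warning.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be > 0")
    n_per = int(round(epoch_s * rec.fs))
    spans = [(a, b) for (label, a, b) in rec.annotations if label == "eyes_closed"]
    chunks = []
    for a, b in spans:
        i0, i1 = int(round(a * rec.fs)), min(int(round(b * rec.fs)), rec.n_samples)
        n_full = (i1 - i0) // n_per
        for e in range(n_full):
            chunks.append(rec.data[:, i0 + e * n_per : i0 + (e + 1) * n_per])
    if not chunks:
        warnings.warn("no eyes-closed spans found; returning empty EpochSet")
        epochs = np.empty((0, rec.n_channels, n_per))
    else:
        epochs = np.stack(chunks)
    return EpochSet(epochs=epochs, fs=rec.fs, montage=rec.montage)


def reject_artifacts(ep: EpochSet, max_abs_uv: float = 100.0) -> EpochSet:
    """Drop epochs containing any sample exceeding ±``max_abs_uv`` µV."""
    if max_abs_uv <= 0:
        raise ValueError("max_abs_uv must be > 0")
    if ep.n_epochs == 0:
        raise ValueError("no epochs to screen")
    keep = np.abs(ep.epochs).max(axis=(1, 2)) <= max_abs_uv
    if not keep.any():
        raise ValueError("all epochs exceeded the amplitude criterion")
    return EpochSet(
        epochs=ep.epochs[keep], fs=ep.fs, montage=ep.montage, kept_mask=keep
    )


def preprocess_recording(
    rec: Recording,
    low_hz: float = 2.0,
    high_hz: float = 20.0,
    order: int = 4,
    epoch_s: float = 2.0,
    max_abs_uv: float = 100.0,
) -> EpochSet:
    """The full chain: filter → average reference → segment → reject."""
    rec = bandpass_filter(rec, low_hz, high_hz, order)
    rec = average_reference(rec)
    ep = segment_epochs(rec, epoch_s)
    if ep.n_epochs == 0:
        return ep
    return reject_artifacts(ep, max_abs_uv)
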