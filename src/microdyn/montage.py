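"""Standard electrode layouts, backed by MNE's bundled montage definitions."""
from __future__ import annotations

import warnings

import numpy as np

from .containers import Montage

#: The classic 19-electrode 10–20 set.
NAMES_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


def _from_mne(mne_name: str, subset: tuple[str, ...] | None, name: str) -> Montage:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage(mne_name)
    ch_pos = std.get_positions()["ch_pos"]
    names = subset if subset is not None else tuple(std.ch_names)
    pos3d = np.array([ch_pos[n] for n in names], dtype=float)
    # Head-plane projection: drop z, rescale to max radius 1. Adequate for
    # gradient construction and 2-D map rendering (no source modelling here).
    xy = pos3d[:, :2].copy()
    r = np.linalg.norm(xy, axis=1).max()
    xy /= r
    return Montage(names=tuple(names), pos=xy, pos3d=pos3d, name=name)


def standard_montage(layout: str | int = 64) -> Montage:
    """Return a standard EEG montage.

    Parameters
    ----------
    layout
        ``64`` / ``"biosemi64"`` for a 64-channel 10-10 layout,
        ``19`` / ``"standard_1020_19"`` for the classic 19-channel 10-20 set.
    """
    if layout in (64, "biosemi64"):
        return _from_mne("biosemi64", None, "biosemi64")
    if layout in (19, "standard_1020_19"):
        return _from_mne("standard_1020", NAMES_1020_19, "standard_1020_19")
    raise ValueError(f"unknown montage {layout!r}; use 64/'biosemi64' or 19/'standard_1020_19'")
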