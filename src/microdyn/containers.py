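"""Shared in-memory containers for the microstate pipeline.

All voltages are in microvolts (µV) and all topographies are average-referenced
(zero mean across channels). Microstate classes follow the conventional A–D
labelling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical microstate class names, in sorted order.
CLASSES: tuple[str, ...] = ("A", "B", "C", "D")

#: Integer code used for samples that could not be assigned to any class.
UNASSIGNED: int = -1


@dataclass(frozen=True)
class Montage:
    """Electrode layout: channel names plus 2-D (and optionally 3-D) positions.

    ``pos`` holds head-plane coordinates (x = left→right, y = posterior→anterior)
    normalised so that max radius ≈ 1; this is what the canonical template
    gradients and the topographic plots use.
    """

    names: tuple[str, ...]
    pos: np.ndarray  # (n_channels, 2)
    pos3d: np.ndarray | None = None
    name: str = "custom"

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def __post_init__(self) -> None:
        if self.pos.shape != (len(self.names), 2):
            raise ValueError("montage positions must be (n_channels, 2)")


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    data : (n_channels, n_samples) array, µV
    annotations : list of ``(label, start_s, stop_s)`` spans; the pipeline only
        analyses spans labelled ``"eyes_closed"``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels × samples)")
        if self.montage is not None and self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage lists "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")


@dataclass
class EpochSet:
    """Equal-length epochs cut from a recording.

    epochs : (n_epochs, n_channels, n_samples_per_epoch) array
    kept_mask : acceptance flag per *candidate* epoch (before rejection the
        mask is all-True; `reject_artifacts` records its decisions here).
    """

    epochs: np.ndarray
    fs: float
    montage: Montage | None = None
    kept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs × channels × samples)")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]

    @property
    def retained_seconds(self) -> float:
        return self.n_epochs * self.epoch_len / self.fs


@dataclass
class TemplateSet:
    """K microstate template topographies (unit-norm, average-referenced)."""

    maps: np.ndarray  # (k, n_channels)
    labels: tuple[str, ...]
    level: str = "subject"  # subject | group | grand | canonical | planted
    gev_percent: float | None = None
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("template maps must be 2-D (k × channels)")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per template map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels must be unique")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels, one row per epoch.

    labels : (n_epochs, n_samples) int array with values in ``0..k-1`` or
        :data:`UNASSIGNED`. Runs never span epoch boundaries because rows are
        independent.
    """

    labels: np.ndarray
    fs: float
    class_names: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D (epochs × samples)")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def k(self) -> int:
        return len(self.class_names)


@dataclass
class TemporalStats:
    """Per-class microstate timing characteristics for one subject.

    duration_ms : mean run duration per class over *interior* runs (runs that
        touch an epoch boundary are truncated and excluded); NaN when a class
        has no interior run.
    occurrence_per_s : interior run onsets per second of labelled time.
    coverage_percent : share of labelled samples, per class (sums to 100).
    """

    duration_ms: dict[str, float]
    duration_overall_ms: float
    occurrence_per_s: dict[str, float]
    coverage_percent: dict[str, float]
    n_runs: dict[str, int]
    labelled_seconds: float

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        rows = []
        for c in self.duration_ms:
            rows.append(
                {
                    "class": c,
                    "duration_ms": self.duration_ms[c],
                    "occurrence_per_s": self.occurrence_per_s[c],
                    "coverage_percent": self.coverage_percent[c],
                    "n_runs": self.n_runs[c],
                }
            )
        df = pd.DataFrame(rows)
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


@dataclass
class TransitionTable:
    """Observed vs. expected microstate transition percentages.

    All three tables are (k, k) with zero diagonal; off-diagonal observed and
    expected percentages each sum to 100, so ``delta_percent`` sums to 0.
    """

    observed_percent: np.ndarray
    expected_percent: np.ndarray
    delta_percent: np.ndarray
    class_names: tuple[str, ...] = CLASSES
    n_transitions: int = 0

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        rows = []
        k = len(self.class_names)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "from": self.class_names[i],
                        "to": self.class_names[j],
                        "observed": self.observed_percent[i, j],
                        "expected": self.expected_percent[i, j],
                        "delta": self.delta_percent[i, j],
                    }
                )
        df = pd.DataFrame(rows)
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


@dataclass
class CohortTable:
    """Tidy per-subject results feeding the group-level statistics.

    subjects : one row per subject (id, group, trait scores, summary stats).
    stats_long : subject × class rows of duration/occurrence/coverage.
    transitions_long : subject × ordered-class-pair rows of observed/expected/Δ.
    """

    subjects: pd.DataFrame
    stats_long: pd.DataFrame
    transitions_long: pd.DataFrame

    def long(self, dv: str) -> pd.DataFrame:
        """Return a tidy frame (subject_id, group, level, value) for ``dv``.

        ``dv`` is one of ``duration``, ``occurrence``, ``coverage`` (within
        factor = microstate class) or ``transitions`` (within factor = the 12
        ordered class pairs, value = Δ%).
        """
        if dv == "transitions":
            df = self.transitions_long.copy()
            df["level"] = df["from"] + "→" + df["to"]
            out = df[["subject_id", "level", "delta"]].rename(columns={"delta": "value"})
        else:
            col = {
                "duration": "duration_ms",
                "occurrence": "occurrence_per_s",
                "coverage": "coverage_percent",
            }.get(dv)
            if col is None:
                raise ValueError(f"unknown characteristic {dv!r}")
            out = self.stats_long[["subject_id", "class", col]].rename(
                columns={"class": "level", col: "value"}
            )
        groups = self.subjects.set_index("subject_id")["group"]
        out = out.assign(group=out["subject_id"].map(groups))
        return out


def demean(maps: np.ndarray) -> np.ndarray:
    """Remove the channel mean (re-derive to average reference) along the last axis."""
    maps = np.asarray(maps, dtype=float)
    return maps - maps.mean(axis=-1, keepdims=True)


def as_class_array(values: Sequence[float] | dict[str, float] | float,
                   class_names: Sequence[str] = CLASSES) -> np.ndarray:
    """Broadcast a scalar / sequence / per-class dict to an array over classes."""
    if isinstance(values, dict):
        return np.array([float(values[c]) for c in class_names])
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 1:
        return np.full(len(class_names), float(arr[0]))
    if arr.size != len(class_names):
        raise ValueError("per-class value must be scalar or match class count")
    return arr
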