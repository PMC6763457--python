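"""Backfitting and temporal microstate characteristics.

Backfitting assigns every GFP peak to its best-matching template and spreads
the peak labels to the surrounding samples (each sample takes the label of its
temporally nearest peak, with the boundary between two peaks at their
midpoint), yielding a continuous microstate label stream per epoch. From that
stream the four characteristics are derived: mean duration, occurrence rate,
coverage, and observed-vs-expected transition percentages.

Boundary rule: runs touching an epoch edge are truncated by the epoching and
would bias durations downward, so they are excluded from duration and
occurrence (run onsets) but included in coverage, which is a pure time share.
The rule is switchable via ``include_boundary_runs``.
"""
from __future__ import annotations

import numpy as np

from .containers import CLASSES, EpochSet, LabelSequence, TemporalStats, TransitionTable, UNASSIGNED, demean
from .topoclust import compute_gfp, extract_gfp_peaks


def _rle(row: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode one epoch row → (starts, lengths, values)."""
    n = row.size
    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(row[1:], row[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    lengths = np.diff(np.append(starts, n))
    return starts, lengths, row[starts]


def backfit_labels(
    epochs: EpochSet,
    templates,
    min_separation_ms: float | None = None,
    min_duration_ms: float = 0.0,
) -> LabelSequence:
    """Label every sample of every epoch by its nearest best-fitting GFP peak.

    Each GFP peak is assigned the template with the highest polarity-invariant
    spatial correlation; every non-peak sample inherits the label of the
    nearest labelled peak of its epoch (the first sample of the later peak's
    span is ``(p_i + p_{i+1} + 1) // 2``, i.e. an exactly equidistant sample
    joins the later peak; samples before the first / after the last peak
    inherit that peak's label). Epochs without any GFP peak stay unassigned.

    ``min_duration_ms`` > 0 enables a crude short-run filter: runs shorter than
    the threshold are merged into their preceding run (the first run merges
    forward). Off by default.
    """
    T = demean(np.asarray(templates.maps, dtype=float))
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    n_epochs, n_ch, n_samp = epochs.epochs.shape
    out = np.full((n_epochs, n_samp), UNASSIGNED, dtype=np.int8)
    for e in range(n_epochs):
        data = epochs.epochs[e]
        gfp = compute_gfp(data)
        peaks = extract_gfp_peaks(gfp, min_separation_ms, epochs.fs)
        if peaks.size == 0:
            continue
        pm = demean(data[:, peaks].T)
        corr = np.abs(pm @ T.T)  # (n_peaks, k); norms cancel in the argmax
        peak_labels = np.argmax(corr, axis=1).astype(np.int8)
        bounds = (peaks[:-1] + peaks[1:] + 1) // 2
        seg_lengths = np.diff(np.concatenate([[0], bounds, [n_samp]]))
        out[e] = np.repeat(peak_labels, seg_lengths)
        if min_duration_ms > 0:
            out[e] = _suppress_short_runs(out[e], min_duration_ms, epochs.fs)
    return LabelSequence(labels=out, fs=epochs.fs,
                         class_names=tuple(templates.labels))


def _suppress_short_runs(row: np.ndarray, min_duration_ms: float, fs: float) -> np.ndarray:
    min_len = int(np.ceil(min_duration_ms * fs / 1000.0))
    starts, lengths, values = _rle(row)
    vals = list(values)
    lens = list(lengths)
    i = 0
    while i < len(vals):
        if lens[i] < min_len and len(vals) > 1:
            j = i - 1 if i > 0 else i + 1
            lens[j] += lens[i]
            del lens[i], vals[i]
            # merging may fuse equal neighbours
            if 0 < j < len(vals) and vals[j - 1] == vals[j]:
                lens[j - 1] += lens[j]
                del lens[j], vals[j]
            i = 0
        else:
            i += 1
    return np.repeat(np.array(vals, dtype=row.dtype), np.array(lens))


def compute_temporal_stats(
    ls: LabelSequence, include_boundary_runs: bool = False
) -> TemporalStats:
    """Duration, occurrence, coverage, and run counts per microstate class.

    duration_ms : mean run length (ms) over interior runs, per class; NaN for
        a class without interior runs. ``duration_overall_ms`` is the
        unweighted mean over classes with a defined duration.
    occurrence_per_s : interior run onsets per second of labelled time.
    coverage_percent : per-class share (%) of all labelled samples (boundary
        runs included — coverage is a pure time share).
    """
    names = ls.class_names
    k = len(names)
    run_len: dict[int, list[np.ndarray]] = {c: [] for c in range(k)}
    cov_samples = np.zeros(k)
    total_labelled = 0
    for e in range(ls.n_epochs):
        row = ls.labels[e]
        mask = row != UNASSIGNED
        if not mask.any():
            continue
        total_labelled += int(mask.sum())
        starts, lengths, values = _rle(row)
        keep = values != UNASSIGNED
        starts, lengths, values = starts[keep], lengths[keep], values[keep]
        np.add.at(cov_samples, values, lengths)
        if not include_boundary_runs and len(values) > 0:
            interior = slice(1, -1) if len(values) > 1 else slice(0, 0)
            lengths, values = lengths[interior], values[interior]
        for c in range(k):
            sel = lengths[values == c]
            if sel.size:
                run_len[c].append(sel)
    if total_labelled == 0:
        raise ValueError("label sequence contains no assigned samples")

    ms_per_sample = 1000.0 / ls.fs
    labelled_seconds = total_labelled / ls.fs
    duration, occurrence, n_runs = {}, {}, {}
    for c, name in enumerate(names):
        if run_len[c]:
            lens = np.concatenate(run_len[c])
            duration[name] = float(lens.mean() * ms_per_sample)
            n_runs[name] = int(lens.size)
        else:
            duration[name] = float("nan")
            n_runs[name] = 0
        occurrence[name] = n_runs[name] / labelled_seconds
    coverage = {name: 100.0 * cov_samples[c] / total_labelled for c, name in enumerate(names)}
    defined = [d for d in duration.values() if np.isfinite(d)]
    overall = float(np.mean(defined)) if defined else float("nan")
    return TemporalStats(
        duration_ms=duration,
        duration_overall_ms=overall,
        occurrence_per_s=occurrence,
        coverage_percent=coverage,
        n_runs=n_runs,
        labelled_seconds=labelled_seconds,
    )


def compute_transition_stats(ls: LabelSequence) -> TransitionTable:
    """Observed, expected, and Δ transition percentages between classes.

    observed(i→j) = 100 × count(i→j) / total within-epoch transitions.
    expected(i→j) = 100 × p_i p_j / (1 − p_i), where p_c is class c's share of
    run onsets — the transition distribution expected if switches were driven
    only by how often each class occurs, never by which class precedes which.
    Both tables sum to 100 over the k(k−1) ordered pairs, so Δ sums to 0.
    """
    names = ls.class_names
    k = len(names)
    counts = np.zeros((k, k))
    onsets = np.zeros(k)
    for e in range(ls.n_epochs):
        row = ls.labels[e]
        _, _, values = _rle(row)
        values = values[values != UNASSIGNED]
        if values.size == 0:
            continue
        np.add.at(onsets, values, 1)
        if values.size > 1:
            np.add.at(counts, (values[:-1], values[1:]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no transitions in the label sequence")
    observed = 100.0 * counts / total
    p = onsets / onsets.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = 100.0 * np.outer(p, p) / (1.0 - p)[:, None]
    expected[~np.isfinite(expected)] = 0.0
    np.fill_diagonal(expected, 0.0)
    return TransitionTable(
        observed_percent=observed,
        expected_percent=expected,
        delta_percent=observed - expected,
        class_names=names,
        n_transitions=int(total),
    )
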