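"""Microstate template identification.

GFP computation and peak extraction, polarity-invariant spatial correlation,
atomize-agglomerate hierarchical clustering (AAHC), global explained variance
(GEV), two-level (subject → group → grand) template aggregation, and sorting
of templates onto a reference labelling.

Polarity invariance is fundamental here: for spontaneous EEG a topography and
its sign-flipped version express the same generator configuration, so cluster
templates are principal spatial eigenvectors of their members' second-moment
matrix rather than plain means, and all correlations are compared in absolute
value.

A convenient identity keeps AAHC fast: for average-referenced maps the GEV
contribution of map ``x`` assigned to unit-norm template ``t`` is
``(GFP·corr)² = (x·t)²/C``, so a cluster's summed contribution is
``tᵀ(Σ xxᵀ)t``, maximised by the principal eigenvector — the cluster quality
used to pick the next cluster to atomize is simply the leading eigenvalue of
its member second-moment matrix.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import CLASSES, EpochSet, TemplateSet, demean


def compute_gfp(data: np.ndarray) -> np.ndarray | float:
    """Global field power: the spatial standard deviation across channels.

    Accepts one topography ``(C,)`` (returns a scalar) or a matrix ``(C, T)``
    (returns one value per sample). The population convention (divide by the
    channel count, not C−1) is used.
    """
    data = np.asarray(data, dtype=float)
    return data.std(axis=0, ddof=0)


def extract_gfp_peaks(
    values: np.ndarray,
    min_separation_ms: float | None = None,
    fs: float | None = None,
) -> np.ndarray:
    """Indices of local GFP maxima within one epoch.

    A peak is a sample ``t`` with ``g[t-1] < g[t] >= g[t+1]`` (plateaus yield
    their first sample; endpoints are never peaks). With ``min_separation_ms``,
    peaks closer than that are thinned keeping the larger one.
    """
    g = np.asarray(values, dtype=float)
    if g.ndim != 1 or g.size < 3:
        return np.empty(0, dtype=np.int64)
    interior = g[1:-1]
    mask = (g[:-2] < interior) & (interior >= g[2:])
    peaks = np.flatnonzero(mask) + 1
    if min_separation_ms and peaks.size > 1:
        if fs is None:
            raise ValueError("fs is required when min_separation_ms is set")
        min_gap = min_separation_ms * fs / 1000.0
        order = np.argsort(g[peaks])[::-1]  # tallest first
        kept: list[int] = []
        for idx in peaks[order]:
            if all(abs(idx - kpt) >= min_gap for kpt in kept):
                kept.append(int(idx))
        peaks = np.array(sorted(kept), dtype=np.int64)
    return peaks


def spatial_correlation(a: np.ndarray, b: np.ndarray, polarity_invariant: bool = True) -> float:
    """Pearson correlation of two topographies across channels.

    With ``polarity_invariant`` the absolute value is returned (range [0, 1]),
    treating a map and its mirror-polarity version as identical.
    """
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a zero-variance map")
    r = float(a @ b / (na * nb))
    return abs(r) if polarity_invariant else r


def correlation_matrix(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Signed Pearson correlations between two stacks of maps, (n_a, n_b)."""
    a = demean(np.asarray(maps_a, dtype=float))
    b = demean(np.asarray(maps_b, dtype=float))
    a_n = np.linalg.norm(a, axis=1, keepdims=True)
    b_n = np.linalg.norm(b, axis=1, keepdims=True)
    if (a_n == 0).any() or (b_n == 0).any():
        raise ValueError("spatial correlation undefined for a zero-variance map")
    return (a / a_n) @ (b / b_n).T


def _principal_template(moment: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector/eigenvalue of a channel-space second-moment matrix,
    with a deterministic sign convention."""
    w, v = np.linalg.eigh(moment)
    t, lam = v[:, -1], float(w[-1])
    t = t * np.sign(t[np.argmax(np.abs(t))]) if np.any(t) else t
    return t, lam


def aahc(
    maps: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """Atomize-agglomerate hierarchical clustering of topographies.

    Starting from singleton clusters, repeatedly identify the cluster whose
    members contribute least to the global explained variance, dissolve it,
    and reassign each member to the cluster whose template it matches best by
    polarity-invariant correlation, until ``k`` clusters remain. Ties for the
    worst cluster break by smaller size, then lower index. Deterministic for
    a fixed input ordering.

    Returns ``(templates (k, C) unit-norm, assignment (n,), gev_path)`` where
    ``gev_path[K]`` is the GEV (%) when K clusters remained.
    """
    X = demean(np.asarray(maps, dtype=float))
    n, n_ch = X.shape
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-variance map in clustering input")
    total = float((norms**2).sum())

    templates = X / norms[:, None]
    crit = norms.astype(float) ** 2  # singleton λ1 = ||x||²
    members: list[list[int]] = [[i] for i in range(n)]
    moments: list[np.ndarray | None] = [None] * n  # lazily created for multi-member
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    gev_path: dict[int, float] = {n: 100.0}

    n_active = n
    while n_active > k:
        act = np.flatnonzero(active)
        # worst cluster: smallest summed GEV contribution; ties → smaller, then lower index
        c = crit[act]
        w_candidates = act[c == c.min()]
        if w_candidates.size > 1:
            s = sizes[w_candidates]
            w_candidates = w_candidates[s == s.min()]
        w = int(w_candidates[0])

        active[w] = False
        n_active -= 1
        act = np.flatnonzero(active)
        mem = members[w]
        members[w] = []
        moments[w] = None

        A = X[mem] @ templates[act].T
        tgt = act[np.argmax(np.abs(A), axis=1)]
        changed: dict[int, list[int]] = {}
        for m_idx, g in zip(mem, tgt):
            changed.setdefault(int(g), []).append(m_idx)
        for g, new in changed.items():
            if moments[g] is None:
                xg = X[members[g][0]]
                moments[g] = np.outer(xg, xg)
            Xn = X[new]
            moments[g] += Xn.T @ Xn
            members[g].extend(new)
            sizes[g] = len(members[g])
            templates[g], crit[g] = _principal_template(moments[g])
        gev_path[n_active] = 100.0 * float(crit[active].sum()) / total

    act = np.flatnonzero(active)
    out_templates = templates[act].copy()
    assignment = np.empty(n, dtype=np.int64)
    for out_idx, g in enumerate(act):
        assignment[members[g]] = out_idx
    return out_templates, assignment, gev_path


def aahc_cluster(
    peak_maps: np.ndarray,
    k: int = 4,
    level: str = "subject",
    montage=None,
    labels: Sequence[str] | None = None,
) -> TemplateSet:
    """AAHC down to ``k`` templates; returns a TemplateSet carrying the GEV (%)
    of the clustered maps under the final assignment."""
    templates, assignment, gev_path = aahc(peak_maps, k)
    lab = tuple(labels) if labels is not None else tuple(
        CLASSES[i] if k == len(CLASSES) else f"M{i + 1}" for i in range(k)
    )
    return TemplateSet(
        maps=templates, labels=lab, level=level,
        gev_percent=gev_path[k], montage=montage,
    )


def gev_from_samples(samples: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> float:
    """GEV (%) of labelled samples under unit-norm templates.

    GEV = Σ_t (GFP_t · corr(x_t, template_{label_t}))² / Σ_t GFP_t² × 100 with
    polarity-invariant correlation; samples labelled < 0 are excluded entirely.
    """
    X = demean(np.asarray(samples, dtype=float))
    lab = np.asarray(labels)
    keep = lab >= 0
    if not keep.any():
        raise ValueError("GEV undefined for an empty assignment")
    X, lab = X[keep], lab[keep]
    T = demean(np.asarray(templates, dtype=float))
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    num = float(((X * T[lab]).sum(axis=1) ** 2).sum())
    den = float((X**2).sum())
    return 100.0 * num / den


def compute_gev(epochs: EpochSet, templates: TemplateSet, label_rows: np.ndarray) -> float:
    """GEV (%) over all labelled samples of an EpochSet.

    ``label_rows`` is the (n_epochs, n_samples) label array of a backfit
    LabelSequence (UNASSIGNED samples are ignored).
    """
    X = np.transpose(epochs.epochs, (0, 2, 1)).reshape(-1, epochs.n_channels)
    lab = np.asarray(label_rows).reshape(-1)
    return gev_from_samples(X, templates.maps, lab)


def aggregate_templates(
    subject_sets: Sequence[TemplateSet], k: int = 4, level: str = "grand"
) -> TemplateSet:
    """Pool subject templates (equal weight: one unit-norm map per subject and
    class) and re-run AAHC to ``k`` clusters."""
    if not subject_sets:
        raise ValueError("no template sets to aggregate")
    n_ch = subject_sets[0].n_channels
    pooled = np.concatenate([ts.maps for ts in subject_sets], axis=0)
    if pooled.shape[1] != n_ch or any(ts.n_channels != n_ch for ts in subject_sets):
        raise ValueError("all template sets must share the montage")
    return aahc_cluster(pooled, k=k, level=level, montage=subject_sets[0].montage)


def sort_templates(ts: TemplateSet, reference: TemplateSet) -> TemplateSet:
    """Reorder, relabel, and sign-align templates against a reference set.

    Solves the one-to-one label assignment maximising the summed
    polarity-invariant correlation to the reference exactly (Hungarian
    algorithm; for k = 4 this equals exhaustive search over the 24
    permutations), then flips signs so each map correlates positively with its
    reference.
    """
    if ts.k != reference.k or ts.n_channels != reference.n_channels:
        raise ValueError("template sets must share k and montage")
    r = correlation_matrix(ts.maps, reference.maps)  # signed (k, k)
    row, col = linear_sum_assignment(-np.abs(r))
    order = np.empty(ts.k, dtype=int)
    order[col] = row  # position j of output ← input map matched to reference j
    maps = ts.maps[order].copy()
    signs = np.sign(r[order, np.arange(ts.k)])
    signs[signs == 0] = 1.0
    maps *= signs[:, None]
    return TemplateSet(
        maps=maps, labels=tuple(reference.labels), level=ts.level,
        gev_percent=ts.gev_percent, montage=ts.montage,
    )
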