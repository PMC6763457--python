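"""Synthetic two-group resting-EEG cohorts with planted microstate structure.

The generator emulates the design of a placebo-controlled intranasal-oxytocin
resting-EEG study: two arms of ``n_per_group`` subjects, ~200 s of eyes-closed
EEG per subject, an alpha-band-dominated signal whose scalp topography switches
among four planted templates with semi-Markov dwell times, white sensor noise,
and anxiety-trait scores that modulate the planted treatment effect in the
active arm only.

Every quantity the downstream pipeline estimates (templates, label sequence,
dwell means, trait couplings) is recorded as ground truth, so recovery can be
checked exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .containers import CLASSES, Montage, Recording, TemplateSet, as_class_array, demean
from .montage import standard_montage

TRAITS = ("neuroticism", "anx_attach", "dep_attach")

DEFAULT_GROUPS = ("treatment", "placebo")


class SynthConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort.

    Dwell means default to the two-arm design of the emulated study: mean
    microstate dwell ~81 ms in the treated arm vs ~75 ms under placebo, 43
    subjects per arm, 64-channel EEG at 500 Hz, 200 s eyes-closed per subject.
    """

    model_config = ConfigDict(extra="forbid")

    n_channels: int = 64
    montage_name: str | None = None  # default: derived from n_channels
    sampling_rate: float = 500.0
    record_seconds: float = 200.0
    n_per_group: int = 43
    group_names: tuple[str, str] = DEFAULT_GROUPS
    # per group: scalar mean dwell (ms) applied to all classes, or per-class dict
    dwell_mean_ms: dict[str, float | dict[str, float]] = {
        "treatment": 81.0,
        "placebo": 75.0,
    }
    dwell_shape: float = 2.0  # gamma shape; CV = 1/sqrt(shape)
    subject_dwell_sd_ms: float = 7.0  # between-subject SD of the dwell offset
    dwell_floor_ms: float = 20.0  # per-subject class means are clipped here
    envelope_freq_hz: float = 10.0  # alpha carrier of the rectified envelope
    envelope_phase_jitter_rad: float = 0.15
    quantize_runs: bool = True  # align run lengths to the carrier half-period
    noise_sd: float = 0.2  # sensor noise SD relative to unit-GFP signal
    amplitude_uv: float = 8.0  # signal GFP at envelope maxima, in µV
    moderator_trait: str = "dep_attach"
    moderator_coupling: float = 5.0  # ms of extra dwell per SD of the trait (treated arm)
    substance_coupling: float = 0.5  # links the rating to the subject's planted effect
    # optional per-group 4×4 switch-weight matrices (diagonal ignored)
    transition_bias: dict[str, list[list[float]]] | None = None
    seed: int = 0

    @field_validator("n_per_group")
    @classmethod
    def _n_per_group_ok(cls, v: int) -> int:
        if v < 2:
            raise ValueError("n_per_group must be >= 2")
        return v

    @field_validator("noise_sd")
    @classmethod
    def _noise_ok(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
        return v

    @field_validator("dwell_shape")
    @classmethod
    def _shape_ok(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("dwell_shape must be > 0")
        return v

    @model_validator(mode="after")
    def _dwell_ok(self) -> "SynthConfig":
        for g in self.group_names:
            if g not in self.dwell_mean_ms:
                raise ValueError(f"dwell_mean_ms missing group {g!r}")
            if (as_class_array(self.dwell_mean_ms[g]) <= 0).any():
                raise ValueError("all dwell means must be > 0")
        if self.moderator_trait not in TRAITS:
            raise ValueError(f"moderator_trait must be one of {TRAITS}")
        return self

    def group_dwell(self, group: str) -> np.ndarray:
        return as_class_array(self.dwell_mean_ms[group])

    def montage(self) -> Montage:
        if self.montage_name is not None:
            return standard_montage(self.montage_name)
        return standard_montage(self.n_channels)


@dataclass
class GroundTruth:
    """Planted truth for one synthetic subject."""

    subject_id: str
    group: str
    true_labels: np.ndarray  # per-sample class codes 0..3
    true_subject_dwell_ms: np.ndarray  # planted per-class mean dwell
    trait_scores: dict[str, float]
    substance_rating: float
    true_templates: TemplateSet


def make_canonical_templates(montage: Montage, k: int = 4) -> TemplateSet:
    """Construct the four archetypal reference topographies on a montage.

    Orientation follows the standard labelling of resting microstates:
    A, a left-posterior ↔ right-anterior diagonal gradient; B, the mirrored
    diagonal; C, an anterior ↔ posterior gradient; D, a fronto-central
    extremum. Maps are average-referenced and unit-norm; the diagonal tilt and
    the width of the fronto-central bump are set so that all pairwise
    polarity-invariant correlations stay clearly below 0.7 on standard layouts.
    """
    if montage.n_channels < k:
        raise ValueError("montage has fewer channels than the requested k")
    if k != 4:
        raise ValueError("canonical templates are defined for k = 4")
    x, y = montage.pos[:, 0], montage.pos[:, 1]
    # normalise coordinates to comparable scale
    x = x / np.abs(x).max()
    y = y / np.abs(y).max()
    a = x + 0.6 * y
    b = x - 0.6 * y
    c = y
    d = np.exp(-((x**2) + (y - 0.25) ** 2) / (2 * 0.33**2))
    maps = demean(np.stack([a, b, c, d]))
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return TemplateSet(maps=maps, labels=CLASSES, level="canonical", montage=montage)


def _quantized_gamma_mean(mu: float, shape: float, quantum: float) -> float:
    """Mean of ``quantum × max(1, round(L/quantum))`` for L ~ gamma(shape, mean mu)."""
    from scipy.stats import gamma as gamma_dist

    scale = mu / shape
    k = np.arange(1, 80)
    upper = gamma_dist.cdf((k + 0.5) * quantum, shape, scale=scale)
    lower = gamma_dist.cdf(np.maximum((k - 0.5) * quantum, 0.0), shape, scale=scale)
    lower[0] = 0.0  # the first lattice point absorbs everything below 1.5 quanta
    return float(quantum * (k * (upper - lower)).sum())


def _compensated_mean(target: float, shape: float, quantum: float) -> float:
    """Gamma mean whose half-period-quantized run lengths average ``target`` ms."""
    from scipy.optimize import brentq

    lo_val = _quantized_gamma_mean(1e-3, shape, quantum)
    if target <= lo_val + 1e-9:  # unreachable: lattice floor is one quantum
        raise ValueError(
            f"dwell mean {target:.1f} ms not representable on a {quantum:.1f} ms "
            f"run-length lattice (floor ≈ {lo_val:.1f} ms)"
        )
    return float(brentq(
        lambda mu: _quantized_gamma_mean(mu, shape, quantum) - target,
        1e-3, 4.0 * target + 8.0 * quantum, xtol=1e-6,
    ))


def simulate_state_sequence(
    dwell_mean_ms: Sequence[float] | dict[str, float] | float,
    dwell_shape: float,
    n_samples: int,
    fs: float,
    rng: np.random.Generator | int,
    transition_bias: np.ndarray | None = None,
    quantum_ms: float | None = None,
) -> np.ndarray:
    """Draw a semi-Markov microstate label sequence.

    Run lengths are gamma(shape=``dwell_shape``, mean=the class's dwell mean),
    truncated below at one sample; successive runs never repeat a class. With
    ``transition_bias`` (k×k weights, diagonal ignored) the switch distribution
    departs from uniform-over-alternatives.

    With ``quantum_ms`` set (the cohort generator passes the carrier
    half-period), run lengths are quantized to that lattice (minimum one
    quantum) and the gamma mean is internally compensated so the quantized run
    lengths still average the configured dwell mean; state switches then fall
    on carrier zero crossings, where real microstate transitions sit (GFP
    minima).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    means = np.atleast_1d(np.asarray(dwell_mean_ms, dtype=float)) if not isinstance(
        dwell_mean_ms, dict
    ) else as_class_array(dwell_mean_ms)
    if (means <= 0).any():
        raise ValueError("all dwell means must be > 0")
    k = means.size
    mean_samples = means * fs / 1000.0
    if n_samples < mean_samples.min():
        raise ValueError(
            f"n_samples={n_samples} is shorter than one mean dwell "
            f"({mean_samples.min():.1f} samples)"
        )
    if k == 1:
        return np.zeros(n_samples, dtype=np.int8)

    # class sequence (no immediate repeats)
    n_runs = int(n_samples / mean_samples.mean() * 1.5) + 16
    if transition_bias is None:
        # uniform over the k-1 alternatives: vectorised offset trick
        classes = np.empty(n_runs, dtype=np.int64)
        classes[0] = rng.integers(k)
        steps = rng.integers(1, k, size=n_runs - 1)
        classes[1:] = steps
        classes = np.mod(np.cumsum(classes), k)
    else:
        bias = np.asarray(transition_bias, dtype=float)
        if bias.shape != (k, k) or (bias < 0).any():
            raise ValueError("transition_bias must be a non-negative k×k matrix")
        probs = bias.copy()
        np.fill_diagonal(probs, 0.0)
        probs /= probs.sum(axis=1, keepdims=True)
        cdf = np.cumsum(probs, axis=1)
        classes = np.empty(n_runs, dtype=np.int64)
        classes[0] = rng.integers(k)
        u = rng.random(n_runs - 1)
        for i in range(1, n_runs):
            classes[i] = np.searchsorted(cdf[classes[i - 1]], u[i - 1], side="right")

    draw_means = means
    if quantum_ms is not None:
        draw_means = np.array(
            [_compensated_mean(m, dwell_shape, quantum_ms) for m in means]
        )

    def _lengths(cls_seq: np.ndarray) -> np.ndarray:
        ms = rng.gamma(dwell_shape, scale=draw_means[cls_seq] / dwell_shape)
        if quantum_ms is not None:
            ms = quantum_ms * np.maximum(1, np.rint(ms / quantum_ms))
        return ms

    lengths_ms = _lengths(classes)
    ends_ms = np.cumsum(lengths_ms)
    total_ms = 1000.0 * n_samples / fs
    while ends_ms[-1] < total_ms + 1000.0 / fs:  # pragma: no cover - generous overdraw
        extra_cls = np.mod(classes[-1] + rng.integers(1, k, size=16).cumsum(), k)
        classes = np.concatenate([classes, extra_cls])
        lengths_ms = np.concatenate([lengths_ms, _lengths(extra_cls)])
        ends_ms = np.cumsum(lengths_ms)
    # place run boundaries on the sample grid from cumulative times, so
    # quantized runs stay aligned with the carrier even when the quantum is a
    # non-integer number of samples; each run keeps >= 1 sample
    ends = np.rint(ends_ms * fs / 1000.0).astype(np.int64)
    ends = np.maximum.accumulate(ends)
    ends = np.maximum(ends, np.arange(1, ends.size + 1))
    last = int(np.searchsorted(ends, n_samples))
    ends = np.minimum(ends[: last + 1], n_samples)
    ends[-1] = n_samples
    lengths = np.diff(np.r_[0, ends])
    classes = classes[: last + 1]
    keep = lengths > 0
    return np.repeat(classes[keep], lengths[keep]).astype(np.int8)


def render_recording(
    labels: np.ndarray,
    templates: TemplateSet,
    config: SynthConfig,
    rng: np.random.Generator | int,
) -> Recording:
    """Render a label sequence into a voltage matrix.

    Each sample equals its class template (scaled to unit GFP) times a signed
    sinusoidal carrier at ``envelope_freq_hz``, plus white sensor noise; the
    result is average-referenced and scaled so the signal GFP reaches
    ``amplitude_uv`` µV at carrier crests. The GFP envelope is therefore the
    rectified sinusoid — the waxing/waning that makes GFP-peak extraction
    meaningful. The carrier keeps a global phase (switches of the quantized
    label sequence fall on its zero crossings, where real microstate
    transitions sit) with a random sign and a small phase jitter per run;
    polarity is irrelevant downstream, and the jitter leaves a slight GFP
    notch at each transition.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.asarray(labels)
    n = labels.size
    n_ch = templates.n_channels
    unit_gfp_maps = demean(templates.maps)
    unit_gfp_maps /= unit_gfp_maps.std(axis=1, keepdims=True)  # GFP = 1 per map

    change = np.empty(n, dtype=bool)
    change[0] = True
    np.not_equal(labels[1:], labels[:-1], out=change[1:])
    run_id = np.cumsum(change) - 1
    n_runs = int(run_id[-1]) + 1
    phase = config.envelope_phase_jitter_rad * rng.standard_normal(n_runs)
    sign = rng.choice([-1.0, 1.0], size=n_runs)
    t = np.arange(n)
    carrier = sign[run_id] * np.sin(
        2 * np.pi * config.envelope_freq_hz * t / config.sampling_rate + phase[run_id]
    )
    data = unit_gfp_maps[labels].T * carrier
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal((n_ch, n))
    data *= config.amplitude_uv
    data -= data.mean(axis=0, keepdims=True)  # average reference
    montage = templates.montage if templates.montage is not None else config.montage()
    return Recording(
        data=data,
        fs=config.sampling_rate,
        montage=montage,
        annotations=[("eyes_closed", 0.0, n / config.sampling_rate)],
    )


@dataclass
class Cohort:
    """A simulated cohort: per-subject metadata plus lazily rendered recordings.

    Recordings are rendered on demand (`subject_recording`) from per-subject
    seed streams, so iterating the cohort twice yields bit-identical data
    without holding all voltage matrices in memory.
    """

    config: SynthConfig
    montage: Montage
    templates: TemplateSet  # the planted templates
    table: pd.DataFrame  # one row per subject (id, group, traits, planted dwell)
    _subject_seeds: list[np.random.SeedSequence] = field(repr=False, default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def subject_recording(self, i: int) -> tuple[Recording, GroundTruth]:
        row = self.table.iloc[i]
        rng = np.random.default_rng(self._subject_seeds[i])
        dwell = np.array([row[f"dwell_{c}_ms"] for c in CLASSES])
        bias = None
        if self.config.transition_bias is not None:
            bias = np.asarray(self.config.transition_bias[row["group"]], dtype=float)
        n_samples = int(round(self.config.record_seconds * self.config.sampling_rate))
        quantum = (
            1000.0 / (2.0 * self.config.envelope_freq_hz)
            if self.config.quantize_runs else None
        )
        labels = simulate_state_sequence(
            dwell, self.config.dwell_shape, n_samples, self.config.sampling_rate,
            rng, transition_bias=bias, quantum_ms=quantum,
        )
        rec = render_recording(labels, self.templates, self.config, rng)
        gt = GroundTruth(
            subject_id=row["subject_id"],
            group=row["group"],
            true_labels=labels,
            true_subject_dwell_ms=dwell,
            trait_scores={t: row[t] for t in TRAITS},
            substance_rating=row["substance_rating"],
            true_templates=self.templates,
        )
        return rec, gt

    def __iter__(self) -> Iterator[tuple[Recording, GroundTruth]]:
        for i in range(self.n_subjects):
            yield self.subject_recording(i)


def simulate_cohort(config: SynthConfig) -> Cohort:
    """Simulate the two-arm cohort design.

    Subject ``i`` of group ``g`` gets per-class dwell means equal to the group
    means, plus ``moderator_coupling × z(moderator trait)`` in the treated arm,
    plus a subject-level Gaussian offset (``subject_dwell_sd_ms``), clipped at
    ``dwell_floor_ms``. The substance-effect rating is a 1–7 Likert analogue
    coupled to the subject's planted dwell deviation in the treated arm.
    """
    montage = config.montage()
    templates = make_canonical_templates(montage, k=4)
    templates = TemplateSet(
        maps=templates.maps, labels=templates.labels, level="planted", montage=montage
    )
    dwell_floor = config.dwell_floor_ms
    if config.quantize_runs:
        # quantized run lengths cannot average below one carrier half-period
        dwell_floor = max(dwell_floor, 1000.0 / (2.0 * config.envelope_freq_hz) + 1.0)
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *subject_seeds = root.spawn(2 * config.n_per_group + 1)
    rng = np.random.default_rng(cohort_ss)

    treated, control = config.group_names
    rows = []
    n_total = 2 * config.n_per_group
    traits = rng.standard_normal((n_total, len(TRAITS)))
    offsets = config.subject_dwell_sd_ms * rng.standard_normal(n_total)
    rating_noise = rng.standard_normal(n_total)
    placebo_base = config.group_dwell(control).mean()
    for i in range(n_total):
        group = treated if i < config.n_per_group else control
        dwell = config.group_dwell(group).copy()
        z_mod = traits[i, TRAITS.index(config.moderator_trait)]
        if group == treated:
            dwell = dwell + config.moderator_coupling * z_mod
        dwell = np.maximum(dwell + offsets[i], dwell_floor)
        rows.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "group": group,
                **{t: traits[i, j] for j, t in enumerate(TRAITS)},
                **{f"dwell_{c}_ms": dwell[j] for j, c in enumerate(CLASSES)},
                "planted_effect_ms": dwell.mean() - placebo_base,
            }
        )
    table = pd.DataFrame(rows)

    # substance rating: in the treated arm, coupled to the planted effect size
    effect = table["planted_effect_ms"].to_numpy()
    is_treated = (table["group"] == treated).to_numpy()
    raw = rating_noise.astype(float)
    e_t = effect[is_treated]
    if is_treated.any() and e_t.std() > 0:
        z_eff = (effect - e_t.mean()) / e_t.std()
        raw = np.where(is_treated, config.substance_coupling * z_eff + rating_noise, raw)
    table["substance_rating"] = np.clip(np.rint(4 + 1.5 * raw), 1, 7).astype(int)

    return Cohort(
        config=config,
        montage=montage,
        templates=templates,
        table=table,
        _subject_seeds=list(subject_seeds),
    )


def paper_like_config(**overrides) -> SynthConfig:
    """A cohort configuration planting the full qualitative effect pattern.

    Beyond the global dwell lengthening in the treated arm, it plants a lower
    switch rate into class C (and out of B into C in particular) and a higher
    rate into class D for treated subjects, so that the end-to-end pipeline
    should find: longer durations under treatment, reduced class-C occurrence
    and coverage, increased class-D coverage, and a negative shift of the
    B→C transition Δ%.
    """
    base = dict(
        dwell_mean_ms={
            "treatment": {"A": 80.0, "B": 81.0, "C": 78.0, "D": 85.0},
            "placebo": {"A": 74.0, "B": 74.0, "C": 77.0, "D": 76.0},
        },
        transition_bias={
            # columns = target class A..D; diagonal ignored
            "treatment": [
                [0.0, 1.0, 0.7, 1.3],
                [1.0, 0.0, 0.45, 1.3],
                [1.0, 1.0, 0.0, 1.3],
                [1.0, 1.0, 0.7, 0.0],
            ],
            "placebo": [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.1, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [1.0, 1.0, 1.0, 0.0],
            ],
        },
    )
    base.update(overrides)
    return SynthConfig(**base)
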