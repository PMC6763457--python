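# Methods

This note documents the models and numerical choices behind `microdyn`: what
the pipeline computes, what the synthetic cohort generator does and does not
emulate, and which design decisions were genuinely open.

## The microstate model

Resting EEG is modelled as a sequence of quasi-stable scalp topographies
("microstates"). At any time t the average-referenced topography x_t ∈ R^C is
summarised by its Global Field Power, GFP(t) = population SD of x_t across
channels. Local GFP maxima are moments of maximal signal-to-noise; the maps at
those peaks are the clustering substrate.

**Polarity invariance.** For spontaneous EEG, x and −x express the same
generator configuration. All spatial correlations are therefore compared in
absolute value, and a cluster's template is the first principal eigenvector of
its members' channel-space second-moment matrix Σ xxᵀ, not the plain mean
(which would cancel under sign flips).

**AAHC.** For average-referenced maps and a unit-norm template t, the GEV
contribution of map x assigned to t is (GFP·corr)² = (x·t)²/C, so a cluster's
summed contribution is tᵀ(Σ xxᵀ)t — maximised by the principal eigenvector
and equal to the leading eigenvalue λ₁. The implementation exploits this:
cluster quality = λ₁ of its second-moment matrix, maintained incrementally
(rank-one updates plus a C×C `eigh` per gaining cluster per atomization).
Worst-cluster ties break by smaller size, then lower input index; output is
deterministic for a fixed input ordering. GEV(K) along the agglomeration path
is non-increasing as K falls, and GEV = 100% when every map is its own
cluster.

**Two-level aggregation and sorting.** Subject templates (one unit-norm map
per class, so subjects are equally weighted) are pooled and re-clustered per
treatment group, then across the sample. Label assignment onto a reference is
solved exactly (Hungarian algorithm on the |corr| matrix, equivalent to
exhaustive search over the 24 permutations at k = 4; the exhaustive search is
kept as a test oracle), with signs flipped to positive correlation with the
reference. Sorting runs down the hierarchy grand → group → subject; grand maps
are anchored to canonical A–D gradients (A: left-posterior↔right-anterior
diagonal, B: mirrored, C: anterior↔posterior, D: fronto-central extremum)
constructed on the montage with pairwise |corr| < 0.6.

**Backfitting.** Each GFP peak takes the template with the highest
polarity-invariant correlation; every other sample takes the label of its
nearest peak within the epoch. Between peaks p_i < p_{i+1} the later peak's
span starts at (p_i + p_{i+1} + 1)//2, i.e. an exactly equidistant sample
joins the *later* peak (the convention the worked fixtures pin down); samples
before the first/after the last peak inherit that peak's label; runs never
cross epoch boundaries. No temporal smoothing or minimum-duration rejection is
applied by default (a configurable filter exists, default off).

**Temporal characteristics.** Duration and occurrence are computed over
*interior* runs only — runs touching an epoch edge are truncated by epoching
and would bias durations downward — while coverage is a pure time share over
all labelled samples (switchable via `backfit.include_boundary_runs`). The
transition expectation under independence from the occurrence marginals is
expected(i→j) = 100·p_i·p_j/(1−p_i) with p_c the class share of run onsets;
both observed and expected tables sum to 100 over the 12 ordered pairs, so Δ
sums to 0 exactly.

## Group-level statistics

- **TANOVA** (per class): subject maps are normalised to unit GFP; the effect
  is the GFP of the difference between group-mean maps; the null permutes
  group labels (vectorised index permutations), the observed partition is
  counted into the null, so p ≥ 1/(n_perm+1); 5000 permutations by default,
  seeded. A small numerical tolerance keeps permutations tied with the
  observed statistic counted (identical groups then give exactly p = 1).
  The permutation p is exactly valid; its type-I error measured over 10⁴
  null simulations is 5.1% at α = 0.05.
- **Split-plot ANOVA** (between: treatment; within: class, or the 12
  transitions): implemented directly — between stratum as a one-way ANOVA on
  subject means, within stratum on subject-centred data via Type-III effect
  coding — because the Greenhouse–Geisser correction must be applied to the
  interaction term as well as the within main effect (the library
  cross-check, `pingouin.mixed_anova`, corrects only the latter). Mauchly's
  W and GG ε come from pingouin; GG-corrected p-values are reported when
  Mauchly p < 0.05 (the conventional direction). Effect sizes are partial η².
  Note the sample GG-ε estimator is biased downward at moderate n (~0.93 at
  n = 200, k = 4 under exact sphericity); the sphericity-limit test therefore
  runs at n = 1000.
- **Follow-ups**: two-group one-way ANOVAs per cell; Bonferroni (m = 12) for
  the transition cells, for which no a-priori hypothesis exists; follow-ups
  are flagged at p < 0.10 as "marginal".
- **Moderation**: outcome ~ group(0/1) + grand-mean-centred trait, then
  + group×trait; ΔR² with F(1, n−4), plus within-group Pearson r with
  df = n_group − 2. Group is coded 0/1 and the moderator centred before the
  product (the usual simple-moderation convention).

## The synthetic cohort generator

The generator emulates a randomized two-arm design: `n_per_group` = 43
subjects per arm, 200 s eyes-closed EEG each (64 channels at 500 Hz by
default), four planted templates, semi-Markov dwell dynamics, and trait
scores. Its defaults are the study conditions the tests assume.

**State sequence.** Dwell times are gamma(shape 2, CV ≈ 0.7) with per-class
means; successive runs never repeat a class; switch targets are uniform over
the three alternatives unless a per-group transition-bias matrix is
configured (used to plant, e.g., suppressed B→C switching). The geometric
alternative was rejected for its implausibly many one-sample runs.

**Rendering.** Each sample equals its class template (unit GFP) times a
signed sinusoidal carrier at 10 Hz (the alpha dominance of eyes-closed EEG;
the 2–20 Hz analysis band motivates an in-band carrier), plus white sensor
noise, scaled to 8 µV signal GFP at carrier crests and average-referenced.
The *GFP envelope* is therefore the rectified sinusoid, giving ~20 GFP peaks
per second (40 per 2-s epoch on an uninterrupted run). Run lengths are
quantized to the carrier half-period (50 ms), with the gamma mean internally
compensated (1-D root find on the analytic quantized mean) so quantized runs
still average the configured dwell mean; state switches then fall on carrier
zero crossings — where real microstate transitions sit (GFP minima) — every
run contains at least one GFP peak, and midpoint backfitting recovers run
boundaries near-exactly. Each run carries a random carrier sign (irrelevant
under polarity invariance) and 0.15 rad of phase jitter, which leaves a
slight GFP notch at transitions.

This design was not the first attempt, and the alternatives matter for
interpreting the recovery results: a *rectified* per-run-restarting envelope
has strong DC content that the 2 Hz high-pass converts into long
opposite-polarity tails, degrading GFP-peak label accuracy to ~60–70% and
biasing measured durations ≈ −16 ms; a free-running signed carrier without
run quantization leaves ~9–16% of gamma-distributed runs without any GFP
peak, merging neighbours and biasing durations upward by +12–20 ms. With the
final design the end-to-end group-mean duration bias is ≈ −1 ms at default
noise.

**Subjects and moderation.** Subject i of group g gets per-class dwell means
= group means + (treated arm only) coupling × z(moderator trait) + a subject
offset ~ N(0, 7 ms), clipped at the lattice floor. Defaults: group means 81
(treatment) vs 75 ms (placebo); subject SD 7 ms places the planted 6 ms
group effect near d ≈ 0.75, so a 43 + 43 cohort detects it with ~95% power —
deliberately cleaner than the in-vivo effect size (d ≈ 0.5), which could not
satisfy an ≥80%-power recovery requirement; moderator coupling 5 ms per trait
SD on dependent attachment (within-treated r ≈ 0.55, interaction power
≈ 88% — again slightly above the in-vivo correlation ≈ 0.42 for the same
reason). Trait scores are independent standard normals; the substance-effect
rating is a 1–7 Likert analogue coupled (0.5 SD) to the subject's planted
dwell deviation in the treated arm. Noise SD defaults to 0.2 of unit signal
GFP (raw peak SNR 5, post-filter peak SNR ≈ 3), keeping peak mislabeling
below ~1%; it is the main dial for studying degradation.

**What the generator does not emulate.** No volume conduction or source
modelling (templates are abstract scalp gradients); no ocular/muscle
artifacts, drifts, or bad channels (white noise only — hence the pipeline's
ICA-free, amplitude-only artifact rejection); no 1/f background or
cross-frequency structure; dwell times on a 50 ms lattice rather than a
continuum; eyes-open segments are not generated (recordings are annotated as
one eyes-closed span). Passing recovery tests therefore show the *analysis
chain* is faithful under an idealised alpha-dominated signal model; they do
not certify performance under real artifact regimes.

## Pipeline, sizes, and reproducibility

Preprocessing follows filter (zero-phase forward-backward Butterworth,
order 4 per pass — the realization is recorded in the run report since only
the cutoffs are conventionally reported) → average reference → 2-s epochs of
eyes-closed spans → ±100 µV rejection; subjects retaining under 50% of their
candidate epochs are excluded and logged. Filtering and referencing are both
linear and commute (tested).

Per-subject AAHC runs on the pooled GFP-peak maps of all artifact-free
epochs; when a subject has more peaks than `cluster.max_gfp_maps` (default
1000), a seeded random subsample is clustered — backfitting always uses all
peaks. GEV per subject is evaluated over all labelled samples of the retained
epochs.

The test suite and the acceptance script use a scaled-down condition chosen
to keep full-cohort replicates cheap while preserving the design: 19-channel
10–20 montage, 250 Hz, 100 s per subject, 43 + 43 subjects, 128 peak maps
clustered per subject. At that scale one end-to-end cohort takes a few
seconds, recovered group-mean durations sit within ~1.5 ms of the planted
means, and the treatment effect, the planted C/D occurrence–coverage pattern,
the B→C transition shift, and the trait moderation are all recovered.

Everything stochastic flows from explicit seeds (`SeedSequence` spawning per
subject), so identical configs give bit-identical recordings and reports; the
run report records the config hash, per-subject retained seconds and GEV, all
statistical tables, and the decision log of the toggles actually used.

## Known limitations

- The split-plot ANOVA assumes balanced groups after listwise deletion (the
  generator always produces balanced arms); heavily unbalanced real cohorts
  would need a mixed-model route instead.
- GEV magnitudes on synthetic data (~93% subject-level at default noise) are
  higher than typical in-vivo values (~70–80%): the generator has no
  background activity outside the planted states.
- The canonical A–D gradients are montage-based abstractions; on sparse or
  unusual montages their pairwise separation should be re-checked (a test
  asserts |corr| < 0.7 on the bundled 19- and 64-channel layouts).
- `min_duration_ms` short-run filtering is a crude merge-into-neighbour pass,
  provided for exploration only and off by default.
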