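# microdyn

Spatio-temporal analysis of resting-state EEG **microstates** — the brief
(~60–120 ms) periods during which the scalp potential topography stays
quasi-stable before switching to another configuration — with a synthetic
two-group cohort generator that plants known ground truth under every stage.

The package is aimed at EEG researchers who want a tested, scriptable
re-implementation of the classic two-level microstate workflow and at
methodologists who want to study how well that workflow recovers known
dynamics: it targets the kind of study in which two treatment arms (e.g. a
neuropeptide vs. placebo) are compared on the temporal dynamics of the four
archetypal microstate classes A–D.

## What it computes

Given multichannel resting EEG (or a simulated cohort):

1. **Preprocessing** — zero-phase 2–20 Hz Butterworth band-pass, average
   reference, segmentation of eyes-closed spans into 2-s epochs, automatic
   ±100 µV artifact rejection, and a "<50 % retained" subject-exclusion rule.
2. **Template identification** — maps at the momentary peaks of the Global
   Field Power, GFP(t) = spatial SD of the topography, are clustered with
   polarity-invariant **AAHC** (atomize–agglomerate hierarchical clustering):
   starting from singletons, the cluster contributing least to the global
   explained variance is dissolved and its members reassigned, until k = 4
   templates remain. Cluster templates are principal spatial eigenvectors, so
   a map and its sign-flipped version count as the same state. Subject
   templates are re-clustered per treatment group and across the whole sample
   (grand means), then sorted hierarchically (grand → canonical A–D labels,
   group → grand, subject → group).
3. **Backfitting & dynamics** — each GFP peak takes the best-matching
   template; intervening samples take the label of the nearest peak. From the
   resulting label stream come the four characteristics, per class:
   mean **duration** (ms), **occurrence** (runs/s), **coverage** (% of time),
   and the **transition** table Δ% = observed − expected, where
   expected(i→j) = 100·p_i·p_j/(1−p_i) from the occurrence marginals.
4. **Inference** — per-class **TANOVA** (randomization test on group-mean
   topographies, effect = GFP of the difference map on unit-GFP subject maps);
   split-plot ANOVA (between: treatment; within: class or the 12 transitions)
   with Mauchly's test, Greenhouse–Geisser correction and partial η²;
   two-group follow-ups with Bonferroni correction for transitions; and
   simple-moderation regression (ΔR² for the group × trait interaction, with
   within-group Pearson correlations).

The **synthetic cohort generator** plants all of this: four canonical
templates on a standard montage, semi-Markov state sequences with
gamma-distributed dwell times (group-dependent means, e.g. 81 vs 75 ms),
an alpha-band carrier whose GFP envelope is a rectified sinusoid, sensor
noise, and anxiety-trait scores that modulate the planted treatment effect in
the treated arm only.

## Worked example

```python
import microdyn as md

synth = md.SynthConfig(
    n_channels=19, montage_name="standard_1020_19",
    sampling_rate=250.0, record_seconds=100.0, seed=7,
)  # 43 + 43 subjects, planted dwell 81 ms (treatment) vs 75 ms (placebo)
cfg = md.PipelineConfig(simulate=synth, cluster={"max_gfp_maps": 128},
                        stats={"n_perm": 199}, seed=7)
res = md.run_pipeline(cfg)
rep = res.report

print(rep.per_subject.groupby("group")["duration_overall_ms"].mean())
print(rep.anovas["duration"][["term", "F", "p"]])
```

prints (exactly, for this seed):

```
group
placebo      73.625025
treatment    80.181830
Name: duration_overall_ms, dtype: float64
                term          F         p
0          treatment  18.802992  0.000040
1              class   0.646149  0.541995
2  treatment × class   0.274636  0.784339
```

The recovered group-mean durations sit ~1 ms below the planted 81/75 ms
(nearest-peak backfitting slightly truncates runs at default noise), and the
split-plot ANOVA detects the planted treatment effect
(F(1, 84) = 18.8, p < 0.001). `rep.tanova_p` shows no spurious topographic
group difference, and `rep.moderations` recovers the planted trait coupling
(within-treated correlation r = 0.44 for the coupled trait).

The same pipeline runs from the shell:

```bash
microdyn simulate --out cohort/ --config synth.yaml --seed 7
microdyn run --config pipeline.yaml --out results/
microdyn report results/
```

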