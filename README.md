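# oscistate

Band-limited M/EEG **oscillatory microstate analysis**: polarity-invariant
modified k-means clustering of sensor topographies, two-level group
templates, backfitting, temporal microstate parameters, and the cohort
statistics that compare them across age groups.

## The problem and who this is for

Resting-state electrophysiological activity is well described as a sequence
of *microstates*: quasi-stable sensor topographies that persist for tens of
milliseconds before abruptly switching. For MEG this analysis is done per
frequency band — delta (1–3 Hz), theta (4–7 Hz), alpha (8–13 Hz), beta
(14–30 Hz), gamma (31–40 Hz) and a broadband 1–40 Hz "overall" band — on a
204-channel array of 102 magnetometers plus 102 combined planar
gradiometers at 250 Hz. This package is for researchers who want that
pipeline as tested, scriptable Python: from raw sensor matrices (or the
built-in synthetic generator with planted ground truth) to group template
maps, per-subject temporal parameters and cohort statistics.

## The method

1. **GFP peaks.** Global field power `GFP(t) = std_channels(x(t))`; its
   strict local maxima are the samples of best topographic signal-to-noise
   and form the clustering input.
2. **Modified k-means** (K = 4, 20 restarts). Maps are assigned to the
   centroid of highest squared cosine similarity — polarity is ignored —
   and each centroid is updated as the first principal eigenvector of its
   members' outer-product sum (the polarity-invariant mean). The restart
   with the highest **global explained variance**

   `GEV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t²`,

   with `r_t` the spatial Pearson correlation between sample *t* and its
   assigned map, is kept.
3. **Two-level group templates.** Subject maps are pooled per age group ×
   band and re-clustered; group maps are re-ordered (all K! permutations,
   maximizing Σ|r|) against the young-adult broadband templates so MS1–MS4
   are comparable across every cell.
4. **Backfitting and parameters.** Every sample is labelled with its
   best-matching template (by default the GFP peaks are labelled and
   intermediate samples take the nearest peak's label); per state this
   yields **duration** (mean stable-run length, s), **occurrence** (runs
   per second) and **coverage** (fraction of time), with
   `coverage = duration × occurrence` by construction.
5. **Cohort statistics.** Per band × state × parameter: one-way ANOVA
   across the five age groups with a Levene homogeneity gate choosing
   Tukey's HSD or Tamhane's T2 post hocs, Pearson age correlations,
   Bonferroni correction, standardized regression of age on the parameter
   grid, and paired *t* for the gradiometer-vs-magnetometer GEV contrast.

## Worked example

```python
import numpy as np, pandas as pd
from oscistate import (RunConfig, SyntheticTruth, analyze_cohort, make_topographies,
                       reorder_to_template, simulate_recording, simulate_state_sequence)

# plant four topographies shared by eight subjects in two age groups
topo = make_topographies(n_channels=204, K=4, max_abs_corr=0.3, seed=42)
recordings, rows = {}, []
for i in range(8):
    segments = simulate_state_sequence(total_s=30.0, K=4, mean_dur_s=0.08,
                                       min_dur_s=0.02, seed=100 + i)
    truth = SyntheticTruth(topo, segments, band="alpha", snr=3.0, seed=i)
    rec, _ = simulate_recording(truth, fs=250.0, noise_sigma=0.1, seed=200 + i)
    sid = f"sub{i}"
    recordings[sid] = rec
    rows.append({"subject": sid, "path": "", "age": 25 if i < 4 else 80,
                 "group": "YA" if i < 4 else "EA", "sex": "F", "handedness": "R"})

config = RunConfig(bands=("alpha",), seed=7)
results = analyze_cohort(recordings, pd.DataFrame(rows), config)

tpl = results.templates[("YA", "alpha")]
_, corrs, _ = reorder_to_template(tpl.maps, topo)
print("template |r| to planted maps:", np.round(corrs, 3))
print(results.params.groupby("state")[["duration_s", "occurrence_hz", "coverage"]]
      .mean().round(3))
```

prints

```
template |r| to planted maps: [1. 1. 1. 1.]
       duration_s  occurrence_hz  coverage
state
0           0.083          2.938     0.245
1           0.084          2.892     0.242
2           0.088          2.988     0.262
3           0.084          2.979     0.251
```

The recovered young-adult alpha templates correlate perfectly with the
planted maps, each of the four states covers about a quarter of the
recording, and the backfitted mean dwell time (~0.084 s) matches the
planted 0.08 s mean within a few percent — with
`coverage = duration × occurrence` holding row by row.

A command-line interface mirrors the stages
(`oscistate simulate | preprocess | cluster | group | backfit | stats |
run-all`); `oscistate run-all --band alpha manifest.csv` runs everything
over a manifest of recording files and writes templates, parameters and
statistics tables as CSV.

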