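# axotrack

Quantification of long-range axonal transport from live-cell
single-particle imaging: photobleaching step counting, track kinetics,
two-channel colocalization, first-arrival transport models, and
replicate-level statistics — together with seeded synthetic-data
generators that emulate the imaging regime, so the whole pipeline is
testable without any microscope data.

## Who this is for

Labs imaging endogenously tagged motor proteins (dynein, dynactin and
their regulators) or organelles in neurons grown in microfluidic
devices: axons cross a ~500-µm groove, particles are tracked at 2 Hz in
a ~110-µm imaging window, and immobilized spots are photobleached at
30 Hz to count fluorophores. The package consumes TrackMate-style CSV
exports (spots / edges / tracks tables) and plain columnar intensity
traces.

## What it computes

- **Photobleaching stoichiometry** (`bleach`): a spot with k labeled
  fluorophores loses intensity in k discrete steps of ~26 AU. Traces are
  fitted by penalized piecewise-constant least squares,
  `min RSS + penalty·k`, with change points proposed by binary
  segmentation and refined by exhaustive coordinate descent. A dimeric
  tag (two tagged copies per molecule) yields a modal step count of 2,
  a monomeric tag a mode of 1.
- **Track kinetics** (`kinetics`): net speed `|x_end − x_start| / Δt`,
  run length, windowed instantaneous velocity, pauses (speed below
  0.1 µm/s for ≥ 1 s), percent pausing, the 10-µm motile filter,
  directionality (retrograde = decreasing x), motile-event frequency
  per movie, and first-arrival time after labeling onset.
- **Colocalization** (`coloc`): one-to-one greedy matching of tracks
  across two channels by sustained sub-0.5-µm separation, with percent
  colocalization against each channel and per-subgroup speeds.
- **Arrival models** (`arrival`): stable binding predicts a first
  arrival of `T = L / (v(1−p))` — under 5 min for L = 500 µm at
  v = 1.76 µm/s — while motor exchange (runs of mean ℓ, rebinding waits
  of mean τ) predicts `T = L/v + (L/ℓ)τ`, an order of magnitude slower
  at ℓ ≈ 2 µm, τ ≈ 5 s.
- **Replicate statistics** (`repstats`): per-track values are averaged
  per biological replicate; Shapiro–Wilk gates between one-way ANOVA +
  Tukey HSD and Kruskal–Wallis + Dunn (Holm-adjusted).

## Worked example

```python
import axotrack as ax

# 200 simulated particles, 5 movies, 2 Hz, retrograde-biased
ts = ax.simulate_tracks(ax.SimTrackConfig(n_tracks=200, n_movies=5, seed=7))
print(ax.population_summary(ts).summary())

# 300 bleaching traces under a dimeric labeling model, step detection
trs = ax.simulate_bleach_traces(ax.SimTraceConfig(n_traces=300, seed=7))
print(ax.summarize_population([ax.fit_steps(t) for t in trs]).summary())

# which transport model explains an observed 3.49-min first arrival?
print(ax.compare_models(ax.ArrivalModelConfig(), observed_minutes=3.49))
```

prints

```
Population: 192 tracks, 117 motile
  retrograde: 53.1%
  anterograde: 7.8%
  stationary: 39.1%
                metric  mean_over_tracks  sem_over_tracks  n_tracks ...
0           mean_speed          1.646204         0.068484       117
3      percent_pausing         10.542762         1.435838       117

Step population: 300 spots, 785 steps
  step-count histogram: {0: 4, 1: 52, 2: 132, 3: 29, 4: 51, 5: 14, 6: 18}
  modal step count:     2
  |step size| (AU):     26.22 +/- 4.97

   model  mean_minutes  ratio_to_stable  consistent_with_observation
  stable      4.734848              1.0                         True
exchange     25.568182              5.4                        False
```

117 of 192 emitted tracks pass the 10-µm motile filter; their mean net
speed (1.65 µm/s) sits below the configured 1.76 µm/s run speed because
net speed averages over paused time. The step histogram peaks at 2 —
the signature of a dimeric tag — with a per-step drop of ~26 AU. The
observed 3.49-min arrival is consistent with stable cargo binding
(predicted 4.7 min), not with motor exchange (25.6 min).

The same stages are available from the shell:

```sh
axotrack simulate-tracks --seed 7 --out run/
axotrack analyze-tracks run/tracks_spots.csv --out run/
axotrack stats run/per_track.csv --out run/
axotrack full-pipeline --seed 7 --out run/
```

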