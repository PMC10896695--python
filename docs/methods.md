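# Methods

This note documents the models implemented in `axotrack`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Coordinate and unit conventions

One convention is used everywhere: x = 0 at the somatodendritic end of
the microfluidic groove, x = groove_length (default 500 µm) at the
axonal end; retrograde transport means decreasing x. Frames are
0-based, times in seconds, positions in µm, intensities in arbitrary
camera units (AU). Unit conversion happens only at the I/O boundary.

## Synthetic track generator

Particles follow a two-state (run/pause) continuous-time Markov
process: per-track speed is drawn once from a normal truncated to
[0.3, 5.0] µm/s (defaults: mean 1.76, sd 0.8 µm/s — the retrograde
speed regime of dynein-driven cargo in these neurons), runs end at an
exponential rate (`pause_entry_rate`, default 0.05 s⁻¹) and pauses
last an exponential time (mean 4 s). This is the minimal model that
reproduces run/pause statistics without inventing richer dynamics
(no state-dependent speeds, no reversals).

Observation model: particles are sampled at the frame clock (default
2 Hz) only while inside the imaging window ([0, 110] µm by default),
with i.i.d. Gaussian localization error (default sd 0.05 µm, a typical
near-single-molecule HILO precision; configurable because it is not a
measured quantity). Tracks additionally terminate after an exponential
*visible length* (mean 35 µm, matching the observed mean run length,
which is limited by spots defocusing rather than detaching). This
termination is censoring, not detachment, and is flagged as such in the
ground-truth table. With `label_onset` the experiment starts at dye
application: motile particles depart from x = groove_length at t = 0,
which is what makes first-arrival times meaningful.

Each generator records a complete ground-truth table (direction, run
speed, pause fraction over the emitted interval, censoring flags) and
is bit-reproducible from a single seed; sub-streams are derived with
`numpy.random.SeedSequence`. An `n_movies` field distributes particles
uniformly over movies, giving per-movie event counts with the
binomial≈Poisson spread that per-movie frequency estimates assume.

What the generator does *not* emulate: spot detection and linking
errors (tracks are emitted directly), photophysics beyond presence
(tracks carry a nominal intensity), axon curvature or 3-D geometry,
and motion heterogeneity within a track (speed changes, reversals).
Passing recovery tests therefore demonstrates correctness of the
measurement pipeline under the stated model, not robustness to
tracking artifacts in real movies.

## Bleaching-trace generator

A spot holds n molecules (n from a configurable pmf, default
{1: 0.6, 2: 0.25, 3: 0.15}), each with c taggable copies (c = 2 for a
dimeric subunit such as the dynein heavy chain, 1 for a monomeric one
such as ARP11), each copy labeled with probability ε (default 0.9, a
near-saturating labeling). Every labeled fluorophore contributes a
plateau drawn once from N(26, 4) AU — the measured single-fluorophore
step intensity — that switches off at an exponential bleaching time
(rate 0.1 s⁻¹), on a constant background (20 AU) with additive Gaussian
read noise (sd 6 AU). Noise is additive Gaussian only, not Poisson
shot noise, so that exact least-squares oracles exist for the fitter;
the sd is configurable. Default trace length is 900 frames at 30 Hz
(30 s), long enough that >95 % of fluorophores bleach within the trace.

The fluorophore count per spot is a mixture of binomials
Σₙ pmf(n)·Binomial(nc, ε); under the defaults its mode is 2 for c = 2
and 1 for c = 1, which is the stoichiometric signature the step
detector must recover end to end.

## Photobleaching step detection

A trace is modeled as piecewise-constant plus Gaussian noise. The fit
minimizes `RSS + penalty · k` over k = 0..max_steps:

1. **Proposal** — greedy binary segmentation with a max-gain heap,
   respecting a minimum segment length (default 5 frames at 30 Hz,
   which rejects single-frame blinking artifacts). On noiseless data
   binary segmentation is exact.
2. **Refinement** — coordinate descent: each change point is re-placed
   at its exhaustive single-point optimum holding the others fixed,
   until stable. For the small step counts relevant here (≤ 7) this
   attains the exhaustive-enumeration optimum in all tested regimes
   (verified against an independent segmented-least-squares DP oracle).
3. **Selection** — the penalty defaults to `3 σ̂² log n` with σ̂ a
   robust noise estimate (MAD of first differences / √2), a BIC-style
   choice that admits 26-AU steps at ~6 AU noise while rejecting noise
   excursions; a tiny floor (1e-9) breaks ties toward fewer steps on
   noiseless data.
4. **Sign constraint** — by default only decreasing steps are kept
   (bleaching semantics): non-decreasing change points are merged away
   iteratively, weakest first. An option admits increases (blinking
   back), but such steps never enter step-size statistics.

The modal step count of a population breaks ties toward the smaller
count (conservative stoichiometry), with the full histogram always
reported. Spot intensity above background uses the pre-bleach plateau;
background precedence is: explicit argument, trace metadata, then the
post-bleach tail level. Implied fluorophore counts use floor
semantics — a 200 AU ceiling at 26 AU per fluorophore implies at most
seven.

Known limitation: two fluorophores bleaching within one minimum
segment (≈ 0.17 s) merge into a single double-height step, so detected
counts are a lower bound at high stoichiometries; under the default
rates this affects a few percent of multi-fluorophore spots.

## Track kinetics

- **Speed**: net displacement over duration (`|x_end − x_start| / Δt`)
  by default — the start-to-end convention — with path speed
  (Σ|Δx| / Δt) always computed alongside; for near-unidirectional runs
  the two nearly coincide. Net speed ≤ path speed always.
- **Instantaneous velocity**: central difference over a 3-frame window
  (1-s baseline at 2 Hz); endpoints use one-sided differences over the
  same span. Unsmoothed per-frame velocities at 2 Hz with 0.05-µm
  localization noise have sd ≈ 0.14 µm/s — larger than the pause
  threshold — so some smoothing is mandatory.
- **Pauses**: maximal runs of frames with |v| < 0.1 µm/s lasting
  ≥ 1 s (2 frames at 2 Hz; suppresses single-frame crossings). Because
  the windowed velocity at a pause boundary mixes paused and moving
  displacement, every detected run is dilated by the window radius on
  both sides before measuring its duration (touching runs merge). This
  de-erosion is exact for noiseless step-like pauses and removes the
  systematic ~1 s/pause underestimate the smoothing window would
  otherwise cause; recovered percent pausing is within half a point of
  generator truth at n = 500 tracks.
- **Motile filter**: net displacement ≥ 10 µm, applied before any
  population statistic; direction is the sign of net displacement for
  motile tracks, "stationary" otherwise.
- **Event frequency**: motile-track count per movie divided by movie
  minutes, averaged over movies (per movie, not per axon or per µm).
- **First arrival**: start time of the earliest motile track in the
  requested direction, in minutes from label onset; an empty result is
  an explicit "not observed", not zero.

Aggregates report mean ± SEM both over tracks and over replicate
means; the replicate-level numbers are what the statistics stage
consumes.

## Colocalization

Candidate pairs must share a movie and ≥ 3 frames; a pair matches when
≥ 50 % of co-visible frames have Euclidean separation < 0.5 µm
(sub-diffraction proximity sustained over most of the co-visible
interval). Assignment is one-to-one, greedy by ascending mean
separation with deterministic id tie-breaks; at realistic densities
conflicts are rare enough that greedy and globally optimal matching
coincide. All three thresholds are exposed on the CLI because no
community-standard criterion exists. Percentages are reported against
both channels' motile-track counts (they differ whenever the channels
have different track numbers; both are meaningful). Pixel-level
intensity correlation (Pearson/Manders) is out of scope.

## Arrival models

Stable binding: `T = L / (v (1 − p))` with pause fraction p. The
5-min benchmark is evaluated at p = 0 (the arithmetic of the
prediction); pause-adjusted values are available by setting p.

Motor exchange: runs of exponential mean ℓ (memoryless, the
single-molecule convention) at speed v, separated by stationary
exponential rebinding waits of mean τ; the motor neither advances nor
diffuses while unbound (diffusion would add parameters nothing
constrains; the flag exists but defaults off). For exponential runs
the number of completed waits over distance L is Poisson(L/ℓ), so the
exact mean is `T = L/v + (L/ℓ) τ`; `mean(approx=True)` returns the
commonly quoted `L/v + (L/ℓ − 1) τ`, exact for deterministic run
lengths — at L = 500, ℓ = 2 the two differ by a single τ (0.3 %).
Simulation means agree with the exact closed form within 2 SE.
Model classification of an observed arrival time is by proximity in
log time, reported next to the exchange/stable ratio (≈ 5.4 under
defaults).

## Replicate statistics

All inference runs on biological-replicate means (one value per
replicate). Shapiro–Wilk at α = 0.05 gates each group; only if every
group is consistent with normality does the parametric family run
(Student's t for two groups, one-way ANOVA + Tukey HSD otherwise), else
Kruskal–Wallis + Dunn. The gate is joint by design — one non-normal
group switches the entire family — and groups too small to test
(< 3 values) or with zero variance force the rank branch. Dunn uses
pooled mid-ranks with tie correction and two-sided normal p values;
Holm adjustment is the default (conservative and order-preserving),
with `none` available, and both raw and adjusted p are always printed.
All-identical data short-circuits to an explicit degenerate-variance
status rather than an exception. A `family` override bypasses the gate
when a specific branch is wanted. The gated pipeline's empirical
type-I error under a normal null is 0.03–0.07 at nominal 0.05
(seeded simulation, 1,000 datasets).

## Problem sizes

The shipped tests and the acceptance script use 300 traces per
stoichiometry condition, 500 tracks per recovery experiment over 10–20
movies, 1,000 null datasets for calibration, and 3,000–4,000 arrival
replicates — sizes at which every 3-SE/2-SE criterion is already
decisive while the whole suite completes in about a minute.

## Known limitations

- Step counting underestimates at high fluorophore numbers (merged
  near-simultaneous bleaching events; see above).
- The track simulator's constant per-track speed means instantaneous
  velocity distributions are narrower than real data's.
- Greedy colocalization can mismatch when two co-running particles in
  the same channel cross a partner's path; on the 1-D axon axis two
  genuinely co-travelling but unrelated particles are indistinguishable
  from a true pair at any threshold.
- The exchange model is a renewal approximation: no tug-of-war,
  mechanochemistry, or cargo-level motor number dynamics.
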