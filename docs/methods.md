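# Methods

`smoketop` quantifies smoking topography — per-puff durations (PD) and
interpuff intervals (IPI), both in milliseconds — from wrist accelerometry,
and compares that measurement against mouthpiece-device topography logs and
visual puff counts. This note documents the models, conventions, defaults and
known limitations; everything numerical stated here is computed by the test
suite or `scripts/acceptance.py`, not asserted from memory.

## The gesture model

A cigarette puff seen from a wrist-worn 3-axis accelerometer is a
hand-to-mouth gesture: from a resting wrist pose the y axis drops by about
4 m/s² and the z axis by about 8 m/s² (the x change is negligible), the
signal then holds an equilibrated plateau near (9, −5, −3) m/s² while the
cigarette is at the mouth, and finally returns to rest. The synthetic
generator and the detector share this model but are implemented
independently: the generator writes a trapezoidal pose trajectory (linear
transition ramps, default `transition_ms = 500`); the detector is a
hysteresis state machine that knows nothing about ramp shape.

**Boundary convention.** A puff's start and end are defined at the
*half-amplitude crossings* of the transition: the instants at which the pose
is halfway between rest and plateau. This convention is used symmetrically by
the generator (truth events) and the detector (onset/offset thresholds at
`onset_fraction = 0.5` of the nominal deltas). The payoff is that measured PD
is unbiased with respect to the ramp length: an asymmetric convention (e.g.
closing the event only once the signal has settled back inside the rest band)
would inflate every PD by a ramp-dependent constant. With this choice, on
noise-free synthetic sessions the detector reproduces truth boundaries to
within one 33 ms sample period.

**Detector stages** (`puff_segmentation`):

1. *Resting pose*: per-axis median over the lowest-motion window of
   `baseline_window_s = 30` s (the window minimising summed rolling
   variance); dispersion is the per-axis MAD. A session that is one long
   plateau would lock onto the plateau — a documented hazard, implausible
   under a 20-minute protocol with several rest blocks.
2. *Onset*: first sample where the smoothed (centred 5-sample moving
   average, ~167 ms) y and z drops both exceed half their nominal deltas
   (2 and 4 m/s²).
3. *Plateau confirmation*: within the supra-threshold region there must be a
   contiguous run of ≥ `min_plateau_ms = 500` in which smoothed y and z stay
   within `plateau_tolerance = 1.5` m/s² of the region median (the running
   plateau estimate).
4. *Offset*: first sample where the drops recover below the onset
   thresholds, confirmed by all axes holding within
   `offset_return_tolerance = 1.5` m/s² of rest for `min_return_ms = 300`.
   Re-onsets arriving before the rest hold completes are merged into one
   event: rapid multi-puffs cannot be separated by wrist motion (or video),
   only by airflow.

Raising `min_plateau_ms` can only remove detections (monotonicity), and all
emitted events are sorted, non-overlapping, and at least `min_plateau_ms`
long.

## The synthetic session generator

`synthetic_session` emulates a 20-minute laboratory protocol: 6 minutes of
smoking split evenly between hands, a 52 s cigarette-pack packing block, and
480 s of other unscripted movements, with rest elsewhere. The two 3-minute
smoking blocks are adjacent — one cigarette with a mid-session hand switch —
so the gap between the last left-hand puff and the first right-hand puff is
an ordinary IPI rather than an artificial multi-minute silence. Only
watch-hand puffs shape the trace; the other hand's puffs exist in the truth
list (and therefore in the mouthpiece log) but not in the watch-visible
window.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `sampling_rate` | 30 Hz | the watch platform's accelerometer rate |
| `n_puffs_per_hand` | 6 | ~12 puffs/cigarette, ~2 puffs/min |
| `pd_median_ms`, `pd_sigma` | 1500, 0.25 | log-normal; typical 1–3 s puffs, right-skewed |
| `ipi_median_ms`, `ipi_sigma` | 20000, 0.3 | tens of seconds between puffs |
| `min_pd_ms`, `min_ipi_ms` | 1100, 3000 | truncation floors: every drawn gesture must contain a ≥500 ms plateau after the 500 ms ramp, and every gap must fit the return hold |
| `rest_pose` | (9, −1, 5) | back-derived from the plateau and the onset deltas; configurable, and estimated per-session by the detector anyway |
| `noise_sd` | 0.2 m/s² | additive white Gaussian sensor noise |

Confounder blocks are stylised, not biomechanically realistic: packing is a
2 m/s² sinusoid on z (never touching y, hence never matching the
two-axis onset signature), other movement is band-limited Gaussian noise on
all axes. Their only contract is *not matching the puff signature at zero
noise* — passing tests therefore show robustness to this noise model, not to
arbitrary real-world gestures (eating, drinking, face-touching), which is
exactly the gap the original laboratory validation is for.

PD/IPI draws are rounded to integer ms before event placement, so topography
recomputed from truth events equals the drawn values exactly. Puff trains
that do not fit their segment are redrawn (bounded retries, then a
configuration error). All randomness flows from `numpy` `SeedSequence`s:
identical config ⇒ bit-identical output.

**Mouthpiece-log artifacts** (`CressArtifactConfig`): record *i* carries the
IPI *preceding* puff *i*, with record 1 holding the device-on→first-puff
interval (default 65 s, matching the over-a-minute leading intervals such
devices report). With probability `split_probability = 0.15` a true puff is
reported as two records — a main record and a 5 ms fragment separated by a
sub-second gap (log-normal, median 330 ms) — conserving the puff's total
time. Gaussian jitter (default 50 ms) models measurement noise. Volume and
flow fields are filled with plausible values and carried opaquely; puff
volume is the one topography measure a wrist sensor cannot produce, so
nothing downstream consumes it.

## Cleaning and the corrected series

`cress_processing.clean_cress` removes the leading interval (by default only
when it exceeds 60 s) and handles implausibly short records
(`min_plausible_pd_ms = 300`, chosen well below any credible inhalation —
the devices' characteristic fragments are milliseconds long). The default is
to *merge* a fragment back into the preceding puff together with its flanking
IPI, which conserves `sum(PD) + sum(IPI)` to the millisecond; deletion mode
(time reassigned to the following gap) is retained for sensitivity analysis.

`correct_ipis` implements outlier substitution: IPIs flagged as abnormally
short or long are replaced by the arithmetic mean of the remaining IPIs. Two
flagging rules are provided — a fixed range (default 1–120 s, the default
rule) and a robust raw-MAD rule (`k = 3`, inert below 3 IPIs or at zero
dispersion) — because the field's practice is a manual judgment with no
published selection rule; every flag is logged and no fidelity to any
particular annotator is claimed. The substituted mean necessarily lies inside
the accepted range, so the operation is idempotent. When no unflagged IPI
remains (including the empty-IPI case produced by a fully implausible log)
there is no reference set and the operation raises rather than guessing.

`ccress_pipeline` composes clean → topography (leading interval dropped) →
substitute, tagging the result `cress_corrected`. Only IPIs are substituted;
implausible PDs are handled in cleaning. On seeded corrupted logs the
corrected series agrees with truth at least as well as the raw series in
≥ 95 of 100 replicates (measured on the index-paired PD+IPI profile r²).

## Agreement analysis

Individual puffs from two sources are paired *by index after window
restriction*, truncating to the shorter list; no alignment is attempted,
and the truncation is logged. Since the mouthpiece log lists both hands'
puffs in order and the watch window is the watch-hand block, index pairing
aligns the overlapping prefix. Agreement is the squared Pearson correlation
(via `scipy.stats.pearsonr`; undefined below 2 pairs or at zero variance —
an error, not a silent NaN). Pooled agreement correlates per-participant
*median* PD and IPI across the cohort; puff-count agreement with the visual
gold standard is the proportion of participants within ±2 counts.
Correlation p-values are deliberately not reported; the statistic of
interest is the agreement itself.

## Problem sizes

The validation suite and the acceptance script use: 100 seeded 20-minute
sessions for the zero-noise detection check (precision = recall = 1,
boundary error ≤ 1 sample), 100 sessions at `noise_sd = 0.5` m/s² for the
robustness check (median F1 ≥ 0.95) and parameter recovery (drawn medians
within 1 sample at zero noise, within 10% under noise), 100 corrupted-log
replicates for correction efficacy, and one simulated cohort of 35
participants (5 device-incomplete, 3 watch-incomplete, 27 analytic) for the
pooled agreement statistics. These sizes give stable statistics while the
whole suite runs in seconds.

## Known limitations

- Confounders are stylised; no claim is made about real-world false-positive
  rates for other hand-to-mouth behaviours.
- Puffs closer together than the return hold merge into one event by design.
- Index pairing across devices breaks down if either source drops or invents
  puffs mid-sequence; the corrected pipeline repairs splits, but a genuinely
  missed puff would misalign everything after it.
- Left/right hand cannot be disambiguated from the signal; hand attribution
  comes from the protocol schedule.
- No machine-learned session classifier and no gyroscope fusion: this
  package quantifies topography within a known smoking session.
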