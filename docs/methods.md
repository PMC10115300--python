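# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `harborsound`.

## Calibration and band SPLs

The recording chain is inverted as `p[µPa] = s · V_fs · 10^{−(S+G)/20}`,
with `s` the PCM sample normalized to [−1, 1), hydrophone sensitivity
`S` (default −201 dB re 1 V/µPa), amplifier gain `G` (default 33 dB) and ADC
full-scale voltage `V_fs` (default 1.0 V — recorder datasheets rarely state
it, so it is config-exposed and all closed forms are written against the
formula, not the hardware). The dB reference is 1 µPa throughout.

Band SPL has two estimators that agree within 0.5 dB on stationary signals:

* **Welch integration** (default, canonical): Hann window, 50 % overlap,
  segment length 2¹⁴ samples at 96 kHz and scaled proportionally at other
  rates so the bin width is unchanged; the PSD is summed over bins whose
  center lies inside the band. Files shorter than one segment fall back to
  a single-segment periodogram with a logged warning.
* **Filter method**: 4th-order Butterworth bandpass applied
  forward–backward (zero-phase), then `20·log10(rms)`.

Digitally silent input is flagged and assigned a −300 dB sentinel instead of
−∞. One SPL is produced per whole file (the review protocol's per-file
average); sub-file windowing is out of scope.

## Synthetic scene generator

The simulator emulates a duty-cycled estuarine deployment: 2-minute files
every 20 minutes per station, a 20-minute environment logger, and a
ground-truth event log standing in for manual spectrogram review.

**Environment.** Water temperature is an annual sinusoid between a
configured envelope (default 9–30 °C, coldest mid-January) plus a 0.5 °C
daily cycle; depth is a clean semidiurnal sinusoid (12.42-h period, 1.8 m
peak-to-trough, the local tidal range). Real tides are mixed and weather-
modulated; a single harmonic is used so the tidal-phase classifier has an
analytic oracle.

**Producers.** Each sound producer has a frequency band, a base Poisson
event rate per active file, hard gates (season months, local-hour window,
temperature range) and multiplicative modifiers per lunar/tidal/diel
category. Vessel presence is Bernoulli per file with separate day/night
rates and a weekend multiplier; when a vessel is present every producer's
rate is multiplied by its `noise_response` (<1 plants suppression, >1 a
boost, 1 the null). Species bands follow published call bands (black drum
70–90 Hz, oyster toadfish 190–200 Hz, spotted seatrout 200–270 Hz, silver
perch 1000–1280 Hz, red drum 120–160 Hz); snapping-shrimp snaps are
broadband and carry the high band. Event source levels are drawn log-normal
around the configured level (σ = 3 dB) — no amplitude distribution is
documented for these scenes, so a standard one was chosen once.

The default scene — the package's study condition — is 60 days from mid-
March, two stations, day-biased vessels (day rate 0.40, night 0.06, weekend
×1.4, recreational spectrum) over night-biased biology (night-leaning shrimp
diel modifier; fish calling windows reaching into the night). The test
profile runs at 8 kHz with the high analysis band rescaled to 2.8–3.8 kHz;
the full 96 kHz field profile (high band 7–40 kHz) is a config switch.

**Intensity scores.** Event counts map to the 0–3 calling-intensity scale
as 0 → 0, 1 → 1, 2–4 → 2, ≥5 → 3. The scale's interior boundary ("multiple
calls" vs "chorusing") is not pinned down by the review protocol, so the
thresholds are config-exposed; only the endpoints (1 call → 1; overlapping
calls → 3) are fixed semantics.

**Two SPL paths.** `render_waveform` synthesizes the pressure series of one
file (snaps as exponentially damped broadband clicks, fish calls as
band-limited 8 Hz pulse trains, dolphin whistles as FM sweeps and
clicks/bursts as upper-band click trains, vessels and the ambient floor as
spectrally shaped noise) and converts to counts with hard clipping at full
scale (a fixed-gain recorder clips; it does not renormalize).
`spl_table_from_truth` instead computes each file's expected in-band SPL
directly from the event energies: an event of rms level L and duration d
contributes `10^{L/10}·d/T` mean-square pressure spread uniformly over its
band, plus the vessel's class-dependent in-band levels and the ambient
floor, with the log-normal jitter entering through its mean power factor
`exp((ln10·σ/10)²/2)`. Season-scale replicate studies use the analytic path
(8,640 files per replicate; rendering them all would be pointless audio
synthesis); the two paths are cross-checked on single files in the tests
(within 1.5–2 dB in the event's band). Enveloped noise is bandpassed
*after* enveloping so ≥90 % of each event's energy stays in its declared
band.

**Ambient floor convention.** `ambient_floor_db` is defined as the in-band
ambient level of *each* analysis band (a zero-event file measures the floor
in both bands). The rendered ambient is noise shaped to a piecewise PSD —
flat densities inside the two analysis bands, log-interpolated between —
rather than white noise, which cannot put equal totals into bands of
unequal width. Vessel spectra reuse the same shaping with class offsets:
commercial (peak 20–200 Hz) contributes (0, −15) dB and recreational
(peak 100 Hz–7 kHz, radiating into the tens of kHz) (0, −5) dB relative to
`level_db` in the (low, high) bands.

**What the simulator does not emulate** — and hence what passing tests do
not show about field data: propagation and detection ranges, mixed/real
tides, weather, overlapping-station detections of the same source, observer
error in manual review (ground truth is exact), realistic snap or click
spectra, and clipping-induced bias at extreme source levels. The planted
effect sizes are chosen to be recoverable at desk scale; field effect sizes
are unknown.

## Covariates

* **Lunar phase**: phase fraction of the 29.530588-d synodic month from a
  reference new moon, split into four equal windows centered on the new,
  first-quarter, full and third-quarter moments.
* **Tidal phase**: high/low extrema located by peak-finding on the depth
  record (minimum spacing 0.4 × 12.42 h); each half-cycle between extrema is
  split so that the quarter-cycle centered on a high is `high`, the
  descending core `falling`, and symmetrically `low`/`rising`. The
  quarter-cycle scheme for both cycles is this package's documented
  stand-in for a prior field protocol that is not restated anywhere usable;
  boundaries are config-exposed.
* **Day/night**: sunrise ≤ t < sunset (closed–open), from a NOAA-style
  solar-position calculation (zenith 90.833°) in station-local civil time.
  Timestamps are stored UTC; each station carries a fixed UTC offset
  (default −5 h) that drives hour-of-day, weekday and diel.
* **Season**: astronomical starts — Mar 20, Jun 21, Sep 22, Dec 21,
  year-wrapped.
* **Temperature**: nearest logger sample, accepted within 10 minutes
  (nearest-neighbor, not interpolated, mirroring 20-minute logger
  alignment); unmatched files are flagged and excluded from models.

## Inference stack

**Random forests.** scikit-learn forests with the R-randomForest-style
defaults the field's workflows assume: regression mtry = p/3 and node size
5, classification mtry = √p and node size 1; 500 trees and seed 42 by
default, exposed in `ModelSpec`. Scores are out-of-bag: percent variance
explained for regression, prediction accuracy (100 − OOB error) for
classification. Categorical predictors are ordinal-encoded over their
sorted observed levels — one column per predictor so importances map
one-to-one. Month and water temperature are collinear and are never fit
together: both variants are fit and the higher-scoring one reported, with
ties broken to the temperature variant.

**Shadow-feature ranking.** Each iteration draws a fresh 2/3 row subsample,
appends a shuffled (shadow) copy of every live predictor (padded to ≥5
shadow columns), fits a forest, and computes OOB permutation-importance
Z-scores (per-tree increase in OOB error after permuting a column, mean
divided by its standard error). A predictor "hits" when its Z beats the
best shadow Z; hits are tested against a fair coin by one-sided binomial
tests at α = 0.01, Bonferroni-corrected over predictors: reliably above
half → confirmed, below → rejected and dropped. Predictors undecided at the
iteration budget (default 100) are tentative; the standard tentative rough
fix (median Z vs median best-shadow Z) is available as an option and used
by the calibration studies. Two choices deserve emphasis: impurity (Gini)
importances are *not* used — their bias lets fixed noise columns with
chance correlations beat freshly-shuffled shadows persistently — and the
per-iteration row subsample decorrelates those chance associations between
iterations, which is what gives the procedure its measured type-I control
(false confirmations at the α level on all-noise designs) without losing
power.

**DTK post-hoc.** All-pairs Dunnett–Tukey–Kramer comparisons: for groups
i, j the simultaneous interval is `(m_i − m_j) ± q/√2 · √(s_i²/n_i +
s_j²/n_j)` with q the studentized-range quantile (default 95 % confidence)
at the pairwise Welch–Satterthwaite degrees of freedom; a pair is
significant iff its interval excludes 0. No further multiplicity correction
is applied beyond the test itself. Noise effects are reported in the
`0 > 1` / `1 > 0` / `0 = 1` notation (0 = no noise, 1 = noise present).

**Targeted species models** restrict rows to a species' calling season and
circadian window (black drum Mar–Apr 15:00–0:00; oyster toadfish Mar–Jun
all hours; silver perch Mar–Jun 15:00–5:00; spotted seatrout Mar–Sep
14:00–2:00; red drum Aug–Oct 13:00–20:00; bottlenose dolphins Nov–Feb all
hours — a config-extensible registry), rerun the shadow ranking with the
noise flag among the predictors, and label the noise direction from the DTK
comparison. The ranking can be skipped (`rank=False`) when only the
direction is needed, as in the replicate studies — the direction comes from
the DTK step alone.

**Contribution models** regress band SPL on the sound producers within each
season × day/night stratum (low band: every fish species' intensity, the
dolphin vocalization count, and the noise flag; high band: dolphins and
noise only), rank confirmed contributors by mean Z, and move contributors
whose presence/absence DTK comparison is significantly *negative* to a
removed list — lower SPL when calling occurred means the producer did not
contribute to the band. Strata under 50 rows are skipped (a guard for OOB
stability; the protocol is silent on a minimum).

## Replicate studies and problem sizes

The calibration studies in `harborsound.study` use desk-scale sizes chosen
once as the package's standard conditions: 60-day two-station scenes
(8,640 files per replicate, analytic SPL path), 20 seeded replicates per
question, and 300-row design matrices with 50-tree forests and a
60-iteration shadow budget for the ranking calibrations. On the default
scene the day/night DTK ordering inverts under noise exclusion in both
bands, planted suppression/boost directions are recovered, and null
producers stay at `0 = 1` — with the null-producer windows deliberately
given flat diel modifiers so the day-biased vessel schedule cannot
confound the null through the diel cycle.

## Numerical details and edge cases

* Round-half-up to one decimal for prevalence percentages (decimal
  arithmetic, not banker's rounding), matching every independently
  checkable printed cell.
* Detection threshold intensity ≥1; calling-date threshold ≥2; chorusing
  day = a calendar day containing ≥1 intensity-3 file; a timeline is
  open-ended when the last calling date falls within 7 days of the end of
  the station record (the recording stopped before calling did), and its
  end date/temperature are then withheld.
* The total-fish prevalence row counts a file once however many species
  called (union, not sum).
* Heat maps pivot to a noon-to-noon layout (72 rows on the 20-minute grid,
  24 hourly) so overnight chorusing is contiguous; gaps stay blank, never
  imputed; duplicate cells are an error.
* Schedule slots start at duty-period boundaries aligned to the scene
  start; a slot is dropped when its start lies inside a service gap.
* All simulator randomness flows from one integer seed; per-file event
  detail and rendering use CRC-derived per-file substreams, so schedules,
  truths and waveforms are bit-for-bit reproducible.

## Known limitations

* The analytic SPL path ignores clipping and spectral leakage between
  analysis bands (a rendered snap leaks a little low-band energy that the
  analytic path does not model); the two paths therefore agree in the
  event's own band but not necessarily far out of band.
* The solar calculator is a NOAA-style approximation (minute-level
  accuracy), not an ephemeris; lunar phase is a uniform synodic cycle.
* Ordinal encoding of unordered factors (station) is a deliberate
  simplification; with few levels, tree ensembles recover the grouping.
* OOB permutation importance is computed per tree from its out-of-bag rows;
  forests with very few trees leave some rows never out-of-bag, so small
  `n_trees` values degrade the Z-scores before they degrade the fit.
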