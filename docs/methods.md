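# Methods

This note documents the models behind `burrowcall`, the choices made where
the design was genuinely open, and what the synthetic data do and do not
show about real colonies.

## The monitoring problem

A colony is monitored two ways over one breeding season (June–August):

* **Observer-based.** A playback survey walks each plot (a stretch of stone
  wall) once per day for `T = 7` days, broadcasting adult purr calls and
  marking every nest that answers at least once (an Apparently Occupied
  Nest, AON). In August, endoscope checks of the marked nests count chicks;
  breeding success is chicks per AON.
* **Acoustic.** A recorder at each plot centre captures 22:00–02:00 nightly
  at 16 kHz. A detector converts each night into seconds of adult purr,
  adult chat and chick beg calls; the plot's *call rate* is the mean nightly
  seconds over retained nights.

The package asks whether the acoustic indices track the observer-based
measures, using synthetic colonies whose ground truth is known.

## Synthetic colony

Plots are points spaced 55 m apart along a collinear wall system; each
holds 10–30 nests placed uniformly within ±50 m of its centre. Occupied
nests carry a per-visit playback response probability drawn uniformly from
(0.20, 0.40) — averaging ≈0.3, so that ≈10% of nests go undetected over
seven visits — and respond independently per visit. Per-nest response
heterogeneity can be switched to plot-constant probabilities; nothing is
known empirically about which is right, so both are supported.

Nightly calling targets (voiced seconds per night) default to 20 s purr per
male, 3.5 s chat per occupied nest, and a chick begging peak of 60 s per
chick-night, chosen so detected plot-level rates land where field studies
report them (purr in excess of ~200 s/night, chat ~40 s/night for plots of
this size, after detection-range thinning). Rates are modulated
multiplicatively by lognormal night, plot×night and nest effects (σ = 0.35,
0.25, 0.5 on the log scale), a per-chick-night lognormal satiation factor
(σ = 0.4, mean 1), and a smooth moonlight suppression `1 − 0.5·moon³`.
Event voiced durations are uniform within each call type's tabulated range;
start times are uniform in the 4-h window.

The chick begging curve is a monotone-segment (PCHIP) interpolation through
fixed anchors: calling possible from day 0, a rise to a peak at 14 d, a
slight dip to ~0.8 of peak by day 20, then a plateau. A late rise after day
30 is implemented but disabled by default because the field evidence for it
rests on very few individuals.

Breeding outcomes: occupied nests succeed with the configured overall
probability (default 0.75). Failures split 60/40 into incubation-stage
(no hatch date) and chick-stage; chick-stage failure days follow an
exponential of scale 8.5 d truncated at 45 d, putting ≈94% of chick-stage
mortality before day 24 — the age at which the observer check treats a
present chick as a success. Hatch dates are normal around 28 July (SD 4 d).

Tarsus growth is a declared stand-in: a saturating curve
`tarsus(a) = 24 − 16·e^(−0.1a)` mm with 0.05 mm measurement noise, rounded
to 0.1 mm. Only its strict monotonicity (hence invertibility) up to ~30 d
matters; the observer check ages chicks by inverting it, and the round trip
age → tarsus → age is accurate to ±1 d over ages 5–30 d.

## Acoustic synthesis, rendering and detection

Calls are synthesized as band-limited Gaussian-noise bursts: one burst per
syllable, bandpassed to the call type's range (4th-order Butterworth,
zero-phase), Tukey-tapered, unit RMS while voiced. Syllable counts, voiced
durations and inter-syllable gaps follow the acoustic parameter table
(purr: 2 syllables, 1–2 s, gap < 0.05 s; chat: 3 syllables, 0.8–1.5 s, gap
0.1–0.3 s; beg: 1 syllable, 0.2–0.5 s).

Rendering mixes events over white background noise (default −40 dBFS RMS)
with amplitude falling 1 dB per metre of distance along the wall. Per-type
source levels are *calibrated*, not free: they are set so the in-band SNR
crosses the detector's onset threshold exactly at the type's detection
range (26/30/16 m), reproducing field detection-range behaviour by
construction. Rendering and detection are chunk-capable (overlapping
chunks, events attributed to the chunk that fully contains them) so a 4-h
night never needs to be held in memory; results are chunking-independent.

The detector replaces a trained classifier while preserving its output
contract (seconds per call type per plot-night). It computes band-energy
envelopes from an STFT (256-sample Hann window, 64-sample hop), smooths
over 3 frames, and segments syllables by hysteresis thresholds 6/3 dB above
the per-band median floor. A run must also sustain the onset level at its
median — without this, single-frame noise spikes drag in long sub-threshold
stretches and blur the range cutoff. Runs separated by ≤ 0.45 s merge into
candidate events; a candidate is accepted for a call type when its syllable
count matches, its voiced duration lies within the type's range (±30%), its
gaps are plausible (≤ 3× the tabulated maximum, allowing taper widening near
the detection limit), and at least 65% of its noise-subtracted energy lies
inside the type's band. The purr and beg bands overlap only at 2.6–3 kHz,
and their syllable structures differ, so purr↔beg confusion is structurally
excluded; measured confusion on labelled scenes is zero, recall at close
range 1.0, and detected call seconds agree with ground truth within a few
percent. Classification is deterministic for fixed audio and configuration.

Detection range from a playback sweep is the maximum detected |position| on
each side of the plot centre, averaged across sides, rounded to the 2-m test
grid; a side detected to the full test extent flags the estimate as
censored. The range boundary is *inclusive* (a source exactly at the range
is detected) — the field phrasing is ambiguous and this convention is
applied consistently in both the detector calibration and the event-level
rule. Ranges are treated as one-sided distances; this too is configurable.

## Night filters, period split, accumulation plateau

Nights are retained when usable and the moon is at most 75% full (exclusion
is strict: exactly 75% is kept). Adult rates use nights strictly before
14 July (one week before the earliest expected hatch); chick rates use
nights on or after it. Empty filtered series yield a missing value, never a
zero, to avoid deflating means.

The accumulation plateau: for each of 100 random night orderings (without
replacement), build the running mean against the number of nights included;
the plateau is the first count whose ordinary-least-squares slope over a
trailing window of 5 points falls below 0.1 (seconds per night, per added
night). None of window, units or ordering count is fixed by convention
elsewhere, so all three are configuration parameters reported in output.
Orderings that never reach the threshold are censored at the series length
when averaging — averaging only successful orderings would favour lucky
early hits and make noisier series look *faster*, inverting the quantity's
meaning as minimum survey effort.

## Playback abundance estimation

Let `C` be discovered AONs over `T` visits and `r = mean(matrix)` the
observed response rate (mean proportion of discovered nests responding per
visit). Discovered nests are a zero-truncated sample — a nest that never
responded is never found — so `r` estimates `p / (1 − (1 − p)^T)`, not the
per-visit response probability `p`. The estimator inverts that relation
(monotone; Brent's method) and corrects `N̂ = C / (1 − (1 − p̂)^T)`. The
raw plug-in of `r` would underestimate N by ~9% at `p = 0.2, T = 7`.

Two stabilisations, both vanishing in large samples:

* the observed rate is shrunk by one pseudo-response over two pseudo-trials
  (in the spirit of Carle–Strub removal estimation) before inversion, since
  the inversion diverges as the rate approaches `1/T`; an exactly all-ones
  history is kept exact (`N̂ = C`, zero-width CI);
* the 999-replicate bootstrap resamples nest rows with replacement from the
  observed rows *augmented with* the estimated number of undetected
  (all-zero) rows, so replicates vary both in response rate and in how many
  nests were discovered. Resampling observed rows alone holds `C` fixed and
  omits its binomial variance — at high response probabilities that CI is
  a sliver above `C` and can never contain the truth.

CI bounds are reported at whole-nest resolution (floor/ceil of the 2.5/97.5
percentiles); point estimates stay real-valued. Simulation over
`p ∈ {0.2, 0.4, 0.6} × N ∈ {10, 20, 30}` gives per-condition bias within
~3% and pooled 95%-CI coverage ≈98%. At `p = 0.6, T = 7` the per-nest
detection probability is 0.998, so essentially every replicate observes all
nests and coverage is pinned near 100% by discreteness; the coverage of the
procedure is meaningful pooled across conditions, not per saturated cell.

The percentage of nests left undetected is `100·(1 − r)^T` exactly, with
`r` the per-visit response probability.

## Comparative models

Continuous predictors are mean-centred and scaled to unit sample standard
deviation (ddof = 1, matching R's `scale`). Effects are significant when
the Wald 95% CI excludes zero. Population-size models are Poisson with log
link (AON counts on one adult call rate at a time — the two adult rates
covary, so they are never entered together); chick abundance is Poisson on
chick call rate; breeding success is binomial-logit on (successes,
failures) per plot. For every model, quadratic and cubic alternatives are
fit on QR-orthogonalized polynomial columns (stable at 10 plots) and a more
complex model is adopted only when its AIC beats the simpler one by more
than 2. The reported estimate is always the linear-term coefficient.
Complete or quasi-separation in binomial fits is flagged and refit with a
Haldane 0.5 correction. Pseudo-R² is the squared Pearson correlation of
observed and fitted responses; a deviance-based R² is reported alongside,
since the conventional choice is not fixed.

The chick-age model is a functional reconstruction of a Gaussian log-link
GAMM: on `z = log(rate + 1)` (the +1 s offset makes zero-call nights
well-defined; configurable), a penalized cubic B-spline in age with 8 basis
functions (knots at age quantiles, second-difference penalty, smoothing
parameter by GCV) plus a per-chick random intercept and an AR(1) residual
term over consecutive nights, iterated with moment estimates of the
variance components and the lag-1 autocorrelation. Marginal R² uses the
smooth alone and conditional R² adds the random intercept
(Nakagawa-style, on the link scale), so conditional ≥ marginal always.
A single chick drops the random effect with a warning. The fit agrees with
`mgcv::gamm` (the independent oracle in the test suite) to curve
correlation > 0.9 on simulated data; the moment-based AR(1) estimate is
conservative (part of the short-range correlation is absorbed by the chick
intercepts), which the package accepts as the price of a dependency-free
fit.

Pearson correlation is reported with `df = n − 2` and a two-sided t-test.

## Orchestration and reproducibility

The end-to-end runner uses the event-level fast path (true events →
detection-range rule → nightly seconds) by default; the audio path is
exercised on short scenes in the test suite. Observer measures are
restricted to nests within the adult purr detection range (the playback
survey broadcasts purr calls); a nest audible from two plot centres is
assigned to the nearer one. Note the chick acoustic index samples a
narrower span (16 m) than the observer measures it is compared against — a
deliberate asymmetry mirroring the field setup, and one reason the
autonomous chick/adult ratio is a weak predictor of observer breeding
success.

All randomness derives from one master seed via spawned seed sequences;
identical configuration and seed give byte-identical reports. Dates are
ISO-8601, times are seconds from 22:00, one timezone throughout. Stage
tables cross boundaries as schema-validated CSVs with row/column-addressed
errors; the manifest records the configuration snapshot, stage seeds,
library versions and SHA-256 digests of written files.

Default problem sizes (10 plots, one season of ~84 nights, 100 plateau
orderings, 999 bootstrap replicates, 200 Monte-Carlo replicates per
recovery condition) keep a full run in seconds and the calibration studies
in tens of seconds.

## What the synthetic data do not show

The generator encodes the statistical structure the analysis assumes —
independent per-visit responses, multiplicative night effects, a shared
chick ontogeny, 1-D geometry, calls as band-limited noise bursts. Passing
tests therefore demonstrate that the pipeline recovers truth *under those
assumptions*, not that the assumptions hold in the field: real colonies add
non-stationary weather and noise, correlated response behaviour,
individually distinctive and harmonically structured calls, detection
ranges that vary with conditions, and 2-D/3-D habitats (boulder beaches)
that this package explicitly does not model. Rate saturation — recorders
overwhelmed in very dense colonies — is likewise out of scope, as are real
lunar ephemerides (moon fraction is an input), predator covariates and
multi-year trends.
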