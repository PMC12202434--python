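# Methods

This note documents the models and procedures implemented in `glucodiy`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that a maintainer
would want on record.

## Data model and inclusion criteria

A subject's data is a timestamped sequence of interstitial glucose readings
in mg/dl at a nominal 15-min sampling period (the LibreView CSV dialect;
column names, timestamp format and units are configurable, and mmol/L
columns are converted by ×18.016). Rows whose timestamp cannot be parsed or
whose glucose is non-numeric or outside a [20, 600] mg/dl plausibility
window are kept as *invalid* readings: they are never used as values, but
they break preprocessing blocks exactly like a sensor interruption.
Duplicate timestamps keep the first occurrence.

Personal model generation requires (i) at least 365 days between the first
and last valid reading and (ii) a sampling period whose median
consecutive-reading gap rounds to 15 min. The median is used so that
isolated delays and interruptions do not disqualify a regular sensor.

## Preprocessing

Two readings are consecutive when their gap is strictly below twice the
sampling period; equivalently, a delay of up to 29:59 min is attributed to
the next time slot and a gap of exactly 30:00 starts a new block. Blocks
shorter than N + h samples are discarded. No interpolation is performed
anywhere: models only ever see real readings, at the cost of losing data
around interruptions.

Normalization is min–max over the subject's full provided year (the
"global" subject range). This implies a mild train/validation leakage —
the validation trimester contributes to the min/max — which is accepted as
part of the design being reproduced and is documented here rather than
silently changed. New readings outside the fitted range at prediction time
pass through the affine map unclamped.

The input window has two channels: the normalized glucose and its first
difference. The difference is computed on the *normalized* signal and the
window's leading element is padded with 0 so the channel has length N.
(Whether to difference before or after normalization, and the padding
convention, are underdetermined choices; these are the package's own.)

Defaults: N = 96 samples (24 h — one full circadian cycle), step 1,
h = 2 (30-min PH) or 4 (60-min PH). The `step` parameter thins instances
for scaled-down runs; counts follow ceil(max(0, L−(N+h)+1)/step) per block.

## Trimester cross-validation

Fold boundaries are t0, t0+3mo, …, t0+12mo with t0 the oldest instance
start, using calendar-month arithmetic with day-of-month clamping
(an alternative fixed 91.3125-day trimester is available via
`calendar_months=False`). An instance belongs to a fold only if its entire
span — input and target — lies inside the trimester; boundary-straddling
instances are discarded (the strictest reading of the discard rule; the
alternative of judging by input span only would retain a handful more
instances per boundary). Each split trains on three folds, shuffled with a
recorded seed, and validates on the held-out fold.

## Losses and weighting

The ISO-normalized error is ε = ŷ − y when y < 100 mg/dl (strictly below)
and ε = (ŷ − y)·100/y otherwise, so the ISO 15197:2015 accuracy criterion
is exactly |ε| ≤ 15. The ISO-adapted loss adds a polynomial barrier:

    L_ISO(ε) = ε² + γ(ε),  γ(ε) = K·ε^(2n),  n = 40,  K = 0.1/14⁸⁰.

γ(14) = 0.1 by construction, γ(15) ≈ 24.9; the loss is even, smooth,
strictly increasing in |ε| and dominates ε² everywhere. γ is evaluated in
log space with the exponent clipped at ±700 so values stay finite in
float64 even for absurd errors. In the training gradient the per-sample
∂L/∂ŷ is additionally clipped at ±1e6: Adam's per-parameter normalization
makes updates scale-invariant, but unclipped barrier gradients could
overflow during accumulation in early epochs. MSE training operates on the
normalized scale; ISO training denormalizes inside the loss (an affine,
differentiable map), so the two losses are on different scales by design.

Range weighting: with p(hypo), p(hyper), p(inrange) the subject's empirical
fractions of samples below 70 / above 180 / in between, sequence weights
are W_hypo = 2/p(hypo), W_hyper = 1.1/p(hyper), W_inrange = 1/p(inrange),
applied per target sequence with hypo > hyper > in-range priority. A weight
whose range never occurs is undefined and can never be requested. The
inverse-probability form follows the weighting equations as printed; the
expected weight under the empirical distribution is 2 + 1.1 + 1 = 4.1
whenever all three ranges occur.

## Architectures and training

All networks run on `glucodiy.nn`, a minimal numpy engine (dense, LSTM with
full backpropagation through time, 1-D dilated convolution with same
padding, max-pooling, nearest-neighbour upsampling, inverted dropout, Adam)
whose analytic gradients are verified against central finite differences in
the test suite. Everything is float64 and seeded through
`numpy.random.Generator`, so initialization, dropout and training are
bit-reproducible single-threaded.

* **naive** — persistence: repeat the last observed value h times (default
  `hold`), or emit the final h input values (`literal`); both readings of
  "output the last values" are implemented, hold being the default.
* **lstm** — one LSTM layer with N = 96 units (Glorot input weights,
  orthogonal recurrent weights, forget bias 1) + dense h. 38,210 parameters
  at h = 2.
* **stacked_lstm** — LSTM layers of 96/48/48/24/24 units, dropout 0.05
  after each, + dense h (~96k parameters).
* **dil_unet** — encoder stages conv(k=3, dilation 1)+ReLU+dropout(0.1)
  with filters 8/16/32/64 (starting from 4× the 2 input features) and
  stride-2 max-pooling; two 128-filter bottleneck convolutions; decoder
  stages upsample + conv halving the filters, concatenate the matching
  encoder skip, merge conv; flatten + dense h (~150k parameters). The
  internal layer table beyond filters/dropout/dilation is this package's
  own: kernel 3, max-pool encoding, nearest-neighbour + conv decoding,
  ReLU activations, concatenation skips. Requires N divisible by 16.

Training: Adam (lr 0.001 — optimizer default, as the protocol leaves it
unstated), batch size 1 (the study setting; tests and scaled-down runs
override to 32–64 for runtime), max 50 epochs, early stopping when the
monitored loss fails to improve on the best seen so far by at least 1e-4
for 2 consecutive epochs. The monitored loss is the training loss — the
protocol describes no inner validation split — with `monitor="val"`
available. The per-instance weights multiply each sequence's loss term.

## Evaluation

RMSE and MAE in mg/dl, MAPE in percent, pooled over all predicted samples
of all validation instances (not per-sequence means). *ISOZone* is the
percentage of pairs with |ŷ−y| ≤ 15 for y < 100 and ≤ 0.15·y otherwise
(boundary inclusive). *ParkesAB* is the percentage falling in zones A∪B of
the consensus (Parkes) error grid for T1D.

The grid's zone geometry is the published consensus vertex table (Pfützner
et al. 2013 digitization of Parkes et al. 2000), shipped as
`data/ceg_t1d_vertices.csv`; alternative vertex tables load via
`CEGGrid.from_file`. Zones are shapely polygons assembled from the boundary
polylines over the [0, 550]² mg/dl domain; classification tests zones from
least to most severe, so boundary points take the less severe zone (the
standard-friendly convention; the source design is silent on ties).

The ISO-vs-grid crossover scan compares, at each reference value, the
vertical distance from the diagonal to the nearest zone-A boundary with
the ISO bound. With the vendored vertices the grid binds on ≈[165.4, 173.9]
mg/dl, i.e. integer endpoints (165, 174). The published range is 164–174;
the lower endpoint is sensitive to the exact vertex dialect at the
1–2 mg/dl level, and is reported as computed rather than forced.

## DIY workflow

First use: validate → preprocess → 4-fold cross-validated training of the
configured architecture (LSTM by default — the fastest with competitive
accuracy) → select the fold model with the best validation ISOZone (ties:
ParkesAB, then lower RMSE, then lowest fold; RMSE-first selectable) → store
model + manifest per (user, horizon). Refusals carry machine-readable
details and a user-facing explanation; a front end may hide the text, but
it is always generated. Generation additionally requires ≥ 1,500 retained
training instances for the 30-min PH and ≥ 5,000 for the 60-min PH — the
levels below which trained models stop beating the persistence baseline on
the diabetes-specific metrics. The gate counts *windowed instances* (what
bounds learnability), not raw readings, and the refusal message states the
count and threshold. Subsequent use loads the stored model, requires one
uninterrupted 96-reading window at the end of the data, and never retrains.
Alerts fire on strict threshold crossings (< 70, > 180 mg/dl), one per
entry into the range, earliest step first.

## Synthetic subjects

The simulator produces the statistical structure the pipeline consumes,
not physiology: basal + 24-h sinusoid + meal excursions (Poisson daily
counts at jittered breakfast/lunch/dinner anchors, log-normal amplitudes,
a two-compartment absorption kernel with ≈35-min rise and ≈150-min decay)
+ hypoglycemic dips (negative Gaussian bumps of 40–70 mg/dl over ≈1 h,
more frequent at night) + AR(1) sensor noise (stationary SD 5 mg/dl,
autocorrelation 0.7), clipped to the 40–400 mg/dl sensor range.
Interruptions are a Poisson process of gap starts with exponential
lengths. Defaults target a plausible T1D profile (time-in-range ≈ 70 %,
above ≈ 28 %, below ≈ 1 %); a 29-subject cohort battery varies basal,
meal behaviour, hypoglycemia propensity and interruption burden across
seeded parameterizations.

Not emulated: insulin–glucose dynamics, carbohydrate dose–response,
exercise, sensor drift/compression artifacts, or inter-day habit shifts
beyond what the random meal draws produce. Consequently, passing tests
demonstrate that the pipeline is implemented correctly and that the models
can learn structured traces — not that real-data accuracy matches any
particular figure. Scaled-down problem sizes used by the tests (30-day
subjects, instance steps 3–8, batches 32–64, 1–6 epochs) are the package's
choice of desk-scale defaults for its own verification.

## Known limitations

* Batch-size-1 training at the full study scale (a year at step 1,
  50-epoch ceiling) is faithful to the protocol but slow on the numpy
  engine; the scaled-down settings above are used for verification runs.
* The Dil-UNet internal layer table is underdetermined by its public
  description; parameter counts here (~150k) differ from the original's
  reported ratios.
* The lower crossover endpoint (165 vs 164) inherits the vertex-dialect
  sensitivity described above.
* Normalization leakage across folds is inherent to the global min/max
  design and kept for fidelity.
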