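# glucodiy

Do-it-yourself **personalized interstitial glucose forecasting** for people
with type 1 diabetes (T1D), from a raw continuous glucose monitoring (CGM)
export to a locally stored personal forecaster with diabetes-specific
evaluation.

A person wearing a FreeStyle-class sensor (15-min sampling) exports a year of
readings as CSV. `glucodiy` validates the export, segments it at sensor
interruptions, builds sequence-to-sequence training instances, trains a
forecaster **only on that person's data**, evaluates it with clinically
meaningful criteria, and then answers "what will my glucose be in 30/60
minutes?" from the last day of readings — with hypo-/hyperglycemia warnings
and plain-language refusals when the data cannot support a reliable model.

## The method

**Preprocessing.** Valid readings are split into contiguous blocks wherever
the gap between consecutive readings reaches twice the sampling period (a
29:59-min delay stays in the block; 30:00 starts a new one); corrupted rows
break blocks too, and no interpolation is ever applied. Values are min–max
normalized with the subject's global min/max (Eq. `i_norm = (i − S_min) /
(S_max − S_min)`). Each block is swept at step 1 into instances: an input
window of N = 96 samples (24 h) with two channels — normalized glucose and
its first difference — and a target of the next h samples (h = 2 or 4 for a
30- or 60-min prediction horizon, PH).

**Models.** A persistence (naive) baseline; an LSTM (one cell with N = 96
memory units + dense output); a stacked LSTM (96/48/48/24/24 units, dropout
0.05); and a dilated 1-D U-Net (four encode/decode stages, filters 8→64,
two 128-filter bottleneck layers, skip connections, dropout 0.1). Training:
Adam, batch size 1, early stopping after 2 epochs without a ≥ 1e-4 loss
improvement. All networks run on a small self-contained numpy engine
(`glucodiy.nn`) with analytic gradients.

**ISO-adapted loss.** With the ISO 15197:2015 normalized error
ε = (ŷ − y) for y < 100 mg/dl and ε = (ŷ − y)·100/y otherwise, training can
minimize either the MSE or

    L_ISO(ε) = ε² + K·ε^(2n),   n = 40,  K = 0.1/14⁸⁰,

a smooth barrier that is negligible (≤ 0.1) inside the admissible |ε| ≤ 14
region and explodes past the ±15 bound. Target sequences are weighted by
glycemic range with inverse-probability weights `W_hypo = 2/p(hypo)`,
`W_hyper = 1.1/p(hyper)`, `W_inrange = 1/p(inrange)` (hypo > hyper >
in-range priority), so rare hypoglycemic sequences matter most.

**Validation.** Trimester-wise 4-fold cross-validation over the year
(calendar trimesters anchored at the oldest timestamp; instances straddling
a fold boundary are discarded; folds shuffled before training). Metrics:
RMSE, MAE, MAPE plus *ParkesAB* (% of predictions in zones A∪B of the
consensus/Parkes error grid for T1D) and *ISOZone* (% within ±15 mg/dl
below 100 mg/dl, ±15 % at or above). The grid geometry is the published
consensus vertex set, vendored as a plain-text table.

**Synthetic cohort.** The study data behind the method are private, so
`glucodiy.synthetic` generates statistically realistic subjects — circadian
baseline, meal excursions, hypoglycemic dips, AR(1) sensor noise, reading
interruptions — for testing every stage end to end (see
`docs/methods.md` for what the simulator does and does not emulate).

## Worked example

```bash
# one synthetic subject, one year of 15-min readings with interruptions
glucodiy simulate --n-subjects 1 --n-days 366 --seed 7 --out cohort

# first use: validate, preprocess, 4-fold cross-validated training, store
glucodiy first-use cohort/subject-000.csv --store store --user demo \
    --ph 30 --config config.yaml
```

where `config.yaml` scales training down for a desk-scale run (the
production defaults are batch size 1, up to 50 epochs, instance step 1):

```yaml
training: {batch_size: 64, max_epochs: 1, loss: iso, seed: 7}
preprocess: {prediction_steps: 2, step: 8}
```

prints

```
model generated and stored (fold 1, 2009 instances)
  fold 1: RMSE 29.03 mg/dl, ParkesAB 99.44%, ISOZone 76.95%
  fold 2: RMSE 32.66 mg/dl, ParkesAB 99.73%, ISOZone 65.57%
  fold 3: RMSE 29.15 mg/dl, ParkesAB 99.69%, ISOZone 68.34%
  fold 4: RMSE 39.55 mg/dl, ParkesAB 99.72%, ISOZone 69.01%
```

Each line is one cross-validation fold: its held-out-trimester RMSE, the
percentage of predictions that are clinically benign on the consensus grid
(ParkesAB; the standard asks ≥ 99 %), and the percentage meeting the strict
ISO accuracy band (ISOZone; the standard asks ≥ 95 %, which short-horizon
CGM-only forecasters do not reach). The fold with the best ISOZone is
stored as the user's model. A subsequent use with a clean last day:

```bash
glucodiy predict lastday.csv --store store --user demo --ph 30
```

```
prediction (mg/dl, 30-min horizon in 15-min steps): 185.4, 189.9
Warning: predicted glucose 185 mg/dl (above 180 mg/dl) in 15 min.
```

With less than a year of data, too many interruptions (below ~1,500
training instances for the 30-min PH, ~5,000 for 60-min), or a gap in the
last 24 h at prediction time, the tool refuses and explains why instead.

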