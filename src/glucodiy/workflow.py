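"""The do-it-yourself user scenarios.

Four scenarios, all triggered by the user handing the tool a CGM export:

1. **First use with enough data** — validate the export, preprocess, train
   one model per cross-validation fold, select the best fold model and store
   it locally for this user and prediction horizon.
2. **First use without enough data** — no model is generated; the outcome
   carries an explanation of which criterion failed (duration, sampling
   period, or the minimum training-instance count).
3. **Subsequent use with a clean last day** — load the stored model, predict
   from the last 24 h window, attach hypo/hyper alerts.
4. **Subsequent use with interrupted data** — no prediction; the outcome
   carries the explanation.

Explanations are always generated; a front end may choose not to display
them (the user's "skip" option suppresses display, never generation).

Gating: beyond the one-year/15-min inclusion criteria, model generation
requires a minimum number of training instances — about 1,500 for the
30-min horizon and about 5,000 for the 60-min horizon, the levels below
which trained forecasters stop beating the naive baseline on the
diabetes-specific metrics.  The count gated on is the number of retained
(non-discarded) windowed instances, the quantity that bounds learnability.
"""

from __future__ import annotations

import itertools
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from glucodiy.cgm_io import CSVDialect, read_cgm_csv, validate_series
from glucodiy.evaluation import CEGGrid, MetricsReport, evaluate
from glucodiy.models import (
    ModelSpec,
    TrainedModel,
    TrainingConfig,
    build_model,
    load_model,
    predict_window,
    save_model,
    train,
)
from glucodiy.objectives import GlycemicThresholds, compute_range_probabilities, instance_weights
from glucodiy.partitioning import N_FOLDS, assign_folds, make_split
from glucodiy.preprocessing import (
    PreprocessConfig,
    build_instances,
    denormalize,
    fit_normalization,
    normalize,
    segment_blocks,
)

#: Minimum retained training instances per prediction horizon (minutes).
INSTANCE_THRESHOLDS = {30: 1500, 60: 5000}

STATUS_MODEL_GENERATED = "model_generated"
STATUS_REFUSED_DATA = "refused_insufficient_data"
STATUS_PREDICTION = "prediction"
STATUS_REFUSED_PREDICTION = "refused_no_prediction"


@dataclass(frozen=True)
class AlertMessage:
    kind: str          # "hypo" | "hyper"
    step: int          # 1-based prediction step
    value: float       # predicted glucose, mg/dl

    def render(self, sampling_period: float = 15.0) -> str:
        minutes = int(self.step * sampling_period)
        direction = "below 70" if self.kind == "hypo" else "above 180"
        return (f"Warning: predicted glucose {self.value:.0f} mg/dl ({direction} mg/dl) "
                f"in {minutes} min.")


@dataclass
class DIYOutcome:
    status: str
    prediction: Optional[np.ndarray] = None
    alerts: list[AlertMessage] = field(default_factory=list)
    explanation: Optional[str] = None
    fold_reports: list[MetricsReport] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.prediction is not None) != (self.status == STATUS_PREDICTION):
            raise ValueError("prediction present iff status is 'prediction'")
        if self.status in (STATUS_REFUSED_DATA, STATUS_REFUSED_PREDICTION) and not self.explanation:
            raise ValueError("refusals must carry an explanation")


class UserStore:
    """Per-user on-disk store: one active model per (user, horizon)."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def model_dir(self, user: str, ph_minutes: int) -> Path:
        return self.root / user / f"ph{ph_minutes}"

    def has_model(self, user: str, ph_minutes: int) -> bool:
        return (self.model_dir(user, ph_minutes) / "manifest.json").exists()

    def store(self, user: str, ph_minutes: int, trained: TrainedModel, manifest: dict) -> Path:
        d = self.model_dir(user, ph_minutes)
        if d.exists():
            shutil.rmtree(d)
        save_model(trained, d)
        (d / "store.json").write_text(json.dumps(manifest, indent=2, default=str))
        return d

    def load(self, user: str, ph_minutes: int) -> TrainedModel:
        if not self.has_model(user, ph_minutes):
            raise FileNotFoundError(
                f"no stored model for user {user!r} at {ph_minutes}-min horizon; run first_use")
        return load_model(self.model_dir(user, ph_minutes))


def check_alerts(prediction, thresholds: GlycemicThresholds | None = None) -> list[AlertMessage]:
    """One alert per threshold crossing, earliest step first.

    A crossing is an entry into the hypo (< 70, strict) or hyper (> 180,
    strict) range from a non-alarmed state.
    """
    thresholds = thresholds or GlycemicThresholds()
    pred = np.asarray(prediction, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("prediction contains non-finite values")
    alerts: list[AlertMessage] = []
    prev_hypo = prev_hyper = False
    for step, v in enumerate(pred, start=1):
        hypo = v < thresholds.hypo
        hyper = v > thresholds.hyper
        if hypo and not prev_hypo:
            alerts.append(AlertMessage("hypo", step, float(v)))
        if hyper and not prev_hyper:
            alerts.append(AlertMessage("hyper", step, float(v)))
        prev_hypo, prev_hyper = hypo, hyper
    return alerts


def select_best_model(fold_reports: Sequence[MetricsReport],
                      fold_models: Sequence[TrainedModel],
                      criterion: str = "iso_zone") -> TrainedModel:
    """Pick the fold model with the best validation metrics.

    Default criterion is the diabetes-specific ISOZone (higher is better),
    with ties broken by ParkesAB, then lower RMSE, then lowest fold index.
    ``criterion="rmse"`` selects by lowest RMSE instead.
    """
    if len(fold_reports) < 1 or len(fold_reports) != len(fold_models):
        raise ValueError("need at least one (report, model) pair, aligned")
    if criterion == "iso_zone":
        keys = [(-r.iso_zone, -r.parkes_ab, r.rmse, i) for i, r in enumerate(fold_reports)]
    elif criterion == "rmse":
        keys = [(r.rmse, -r.iso_zone, -r.parkes_ab, i) for i, r in enumerate(fold_reports)]
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    best = min(range(len(keys)), key=lambda i: keys[i])
    return fold_models[best]


def first_use(csv_path: str | Path, ph_minutes: int = 30, store: UserStore | None = None,
              user: str | None = None, dialect: CSVDialect | None = None,
              architecture: str = "lstm",
              training: TrainingConfig | None = None,
              preprocess: PreprocessConfig | None = None,
              grid: CEGGrid | None = None,
              thresholds: GlycemicThresholds | None = None) -> DIYOutcome:
    """Scenario 1/2: generate, select and store a personalized model.

    Runs validate -> preprocess -> trimester-wise 4-fold cross-validated
    training with glycemic-range weighting -> best-model selection.  Refuses
    (with explanation) if the export fails the inclusion criteria or yields
    fewer training instances than the horizon's threshold.  The default
    architecture is the LSTM, the fastest of the three with competitive
    accuracy; others are selectable.
    """
    if ph_minutes not in INSTANCE_THRESHOLDS:
        raise ValueError(f"prediction horizon must be one of {sorted(INSTANCE_THRESHOLDS)} min")
    thresholds = thresholds or GlycemicThresholds()
    training = training or TrainingConfig()
    series = read_cgm_csv(csv_path, dialect)
    user = user or series.subject_id

    report = validate_series(series)
    if not report.eligible:
        reasons = []
        if not report.duration_ok:
            reasons.append(f"only {report.duration_days:.0f} days of readings were provided; "
                           f"at least 365 days are needed")
        if not report.sampling_period_ok:
            reasons.append("the sensor sampling period is not 15 min")
        return DIYOutcome(
            status=STATUS_REFUSED_DATA,
            explanation="A personal model could not be generated: " + "; ".join(reasons) + ".",
            details={"validation": report},
        )

    config = preprocess or PreprocessConfig(
        prediction_steps=max(1, int(round(ph_minutes / series.sampling_period))))
    blocks = segment_blocks(series, config)
    norm = fit_normalization(series)
    instances = build_instances(blocks, norm, config)
    if len(instances) == 0:
        return DIYOutcome(
            status=STATUS_REFUSED_DATA,
            explanation=("A personal model could not be generated: the readings contain too "
                         "many interruptions to form even one full training window."),
            details={"n_instances": 0},
        )
    partition = assign_folds(instances, t0=series.timestamps()[0])
    n_retained = int(np.sum(partition.fold_of_instance != 0))
    threshold = INSTANCE_THRESHOLDS[ph_minutes]
    if n_retained < threshold:
        return DIYOutcome(
            status=STATUS_REFUSED_DATA,
            explanation=(f"A personal model could not be generated: the year of readings "
                         f"yields {n_retained} training instances, below the ~{threshold} "
                         f"needed for a reliable {ph_minutes}-min forecaster (interruptions "
                         f"reduce the usable data)."),
            details={"n_instances": n_retained, "threshold": threshold},
        )

    range_weights = compute_range_probabilities(series.values(), thresholds)
    spec = ModelSpec(architecture=architecture, window_length=config.window_length,
                     prediction_steps=config.prediction_steps)
    grid = grid or CEGGrid.consensus_t1d()
    fold_models: list[TrainedModel] = []
    fold_reports: list[MetricsReport] = []
    for k in range(1, N_FOLDS + 1):
        train_ids, val_ids = make_split(partition, k, seed=training.seed + k)
        if len(train_ids) == 0 or len(val_ids) == 0:
            continue
        train_set = instances.subset(train_ids)
        w = instance_weights(denormalize(train_set.Y, norm), range_weights, thresholds)
        model = build_model(spec, seed=training.seed + k)
        trained = train(model, train_set, weights=w, config=training)
        trained.provenance.update({"fold": k, "architecture": architecture})
        rep = evaluate(trained, instances.subset(val_ids), grid,
                       provenance={"fold": k, "architecture": architecture,
                                   "loss": training.loss, "ph_minutes": ph_minutes})
        fold_models.append(trained)
        fold_reports.append(rep)
    best = select_best_model(fold_reports, fold_models)
    if store is not None:
        store.store(user, ph_minutes, best, manifest={
            "user": user,
            "ph_minutes": ph_minutes,
            "architecture": architecture,
            "loss": training.loss,
            "seed": training.seed,
            "n_instances": n_retained,
            "instance_threshold": threshold,
            "fold_reports": [vars(r) for r in fold_reports],
            "selected_fold": best.provenance.get("fold"),
        })
    return DIYOutcome(status=STATUS_MODEL_GENERATED, fold_reports=fold_reports,
                      explanation=None,
                      details={"n_instances": n_retained, "user": user,
                               "selected_fold": best.provenance.get("fold")})


def subsequent_use(csv_path: str | Path, store: UserStore, user: str,
                   ph_minutes: int = 30, dialect: CSVDialect | None = None,
                   thresholds: GlycemicThresholds | None = None) -> DIYOutcome:
    """Scenario 3/4: predict from the last day of readings, or refuse.

    Requires one uninterrupted window of the model's input length (96
    readings, 24 h) at the end of the provided data: every gap below twice
    the sampling period and no corrupted readings inside the window.  Never
    retrains.
    """
    trained = store.load(user, ph_minutes)   # raises if first_use never ran
    series = read_cgm_csv(csv_path, dialect)
    config = PreprocessConfig(window_length=trained.spec.window_length,
                              prediction_steps=trained.spec.prediction_steps,
                              sampling_period=series.sampling_period)
    blocks = segment_blocks(series, config)
    N = trained.spec.window_length
    if not blocks or blocks[-1].length < N:
        have = blocks[-1].length if blocks else 0
        return DIYOutcome(
            status=STATUS_REFUSED_PREDICTION,
            explanation=(f"No prediction: the last day of readings is interrupted — only "
                         f"{have} consecutive readings are available where {N} "
                         f"(24 h without gaps) are needed."),
            details={"needed": N, "available": have},
        )
    window_vals = blocks[-1].values()[-N:]
    vn = normalize(window_vals, trained.norm)
    x = np.empty((N, 2))
    x[:, 0] = vn
    x[:, 1] = np.diff(vn, prepend=vn[0])
    pred = predict_window(trained, x)
    alerts = check_alerts(pred, thresholds)
    return DIYOutcome(status=STATUS_PREDICTION, prediction=pred, alerts=alerts,
                      details={"ph_minutes": ph_minutes,
                               "window_end": str(blocks[-1].timestamps()[-1])})


def experiment_grid(subjects: Sequence[str],
                    architectures: Sequence[str] = ("lstm", "stacked_lstm", "dil_unet"),
                    losses: Sequence[str] = ("mse", "iso"),
                    folds: int = N_FOLDS,
                    ph_minutes: Sequence[int] = (30, 60)) -> list[dict]:
    """Enumerate the full training-job grid with provenance manifests.

    3 architectures x 2 losses x 4 folds x 2 horizons = 48 jobs per subject.
    """
    jobs = []
    for subject, arch, loss, fold, ph in itertools.product(
            subjects, architectures, losses, range(1, folds + 1), ph_minutes):
        jobs.append({"subject": subject, "architecture": arch, "loss": loss,
                     "fold": fold, "ph_minutes": ph})
    return jobs
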