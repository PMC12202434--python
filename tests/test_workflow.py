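"""DIY scenarios: gating, selection, alerts, refusals and the job grid."""

import numpy as np
import pytest

from glucodiy.cgm_io import drop_readings, write_cgm_csv
from glucodiy.evaluation import MetricsReport
from glucodiy.models import ModelSpec, TrainingConfig, build_model, train
from glucodiy.preprocessing import PreprocessConfig, preprocess_series
from glucodiy.synthetic import SimulationParams, simulate_subject
from glucodiy.workflow import (
    STATUS_REFUSED_DATA,
    STATUS_REFUSED_PREDICTION,
    STATUS_PREDICTION,
    AlertMessage,
    DIYOutcome,
    UserStore,
    check_alerts,
    experiment_grid,
    first_use,
    select_best_model,
    subsequent_use,
)
from tests.conftest import make_periodic_series


def report(iso=70.0, parkes=99.0, rmse=20.0, fold=1):
    return MetricsReport(rmse=rmse, mae=15.0, mape=10.0, parkes_ab=parkes,
                         iso_zone=iso, n_points=100, provenance={"fold": fold})


class TestCheckAlerts:
    def test_in_range_prediction_has_no_alerts(self):
        assert check_alerts([120.0, 130.0]) == []

    def test_hypo_alert_uses_strict_threshold(self):
        alerts = check_alerts([70.0, 65.0])
        assert [(a.kind, a.step) for a in alerts] == [("hypo", 2)]

    def test_hyper_alert_at_first_step(self):
        alerts = check_alerts([190.0, 150.0])
        assert [(a.kind, a.step) for a in alerts] == [("hyper", 1)]

    def test_one_alert_per_crossing(self):
        alerts = check_alerts([190.0, 185.0, 150.0, 190.0])
        assert [(a.kind, a.step) for a in alerts] == [("hyper", 1), ("hyper", 4)]

    def test_rendering_mentions_direction(self):
        msg = AlertMessage("hypo", 2, 60.0).render()
        assert "below 70" in msg and "30 min" in msg


class TestSelectBestModel:
    def test_single_candidate_is_returned(self):
        m = object()
        assert select_best_model([report()], [m]) is m

    def test_iso_zone_first_then_parkes(self):
        reports = [report(iso=70, parkes=99.0), report(iso=75, parkes=99.5),
                   report(iso=75, parkes=99.2), report(iso=60, parkes=98.0)]
        models = ["f1", "f2", "f3", "f4"]
        assert select_best_model(reports, models) == "f2"

    def test_all_identical_picks_first_fold(self):
        models = ["f1", "f2", "f3", "f4"]
        assert select_best_model([report()] * 4, models) == "f1"

    def test_rmse_criterion_option(self):
        reports = [report(rmse=25), report(rmse=19), report(rmse=22)]
        assert select_best_model(reports, ["a", "b", "c"], criterion="rmse") == "b"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([], [])


class TestExperimentGrid:
    def test_48_jobs_per_subject(self):
        assert len(experiment_grid(["s1"])) == 48

    def test_29_subject_cohort_is_1392(self):
        jobs = experiment_grid([f"s{i}" for i in range(29)])
        assert len(jobs) == 1392
        assert len({tuple(sorted(j.items())) for j in jobs}) == 1392

    def test_empty_cohort(self):
        assert experiment_grid([]) == []


class TestOutcomeInvariants:
    def test_refusal_requires_explanation(self):
        with pytest.raises(ValueError):
            DIYOutcome(status=STATUS_REFUSED_DATA, explanation=None)

    def test_prediction_requires_array(self):
        with pytest.raises(ValueError):
            DIYOutcome(status=STATUS_PREDICTION, prediction=None)


class TestFirstUseGating:
    def test_short_history_refused_citing_duration(self, tmp_path):
        series = simulate_subject(SimulationParams(n_days=10, seed=4))
        path = write_cgm_csv(series, tmp_path / "short.csv")
        store = UserStore(tmp_path / "store")
        outcome = first_use(path, ph_minutes=30, store=store)
        assert outcome.status == STATUS_REFUSED_DATA
        assert "365 days" in outcome.explanation
        assert not any((tmp_path / "store").rglob("manifest.json"))  # nothing stored

    def test_interrupted_year_refused_citing_instance_threshold(self, tmp_path):
        # a full-year span thinned to ~100-reading islands: eligible on
        # duration/period but far below the 1,500-instance gate
        series = simulate_subject(SimulationParams(n_days=366, noise_sd=0.0, seed=5))
        keep = np.array([(i % 450) < 100 for i in range(len(series))])
        keep[0] = keep[-1] = True
        path = write_cgm_csv(drop_readings(series, keep), tmp_path / "gappy.csv")
        store = UserStore(tmp_path / "store")
        outcome = first_use(path, ph_minutes=30, store=store)
        assert outcome.status == STATUS_REFUSED_DATA
        assert "1500" in outcome.explanation
        assert 0 < outcome.details["n_instances"] < 1500
        assert not any((tmp_path / "store").rglob("manifest.json"))

    def test_bad_horizon_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            first_use(tmp_path / "x.csv", ph_minutes=45)

    def test_unreadable_file_is_an_error_not_a_refusal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            first_use(tmp_path / "missing.csv", ph_minutes=30)


@pytest.fixture(scope="module")
def stored(tmp_path_factory):
    """A small stored model (24-sample window) for prediction scenarios."""
    root = tmp_path_factory.mktemp("store")
    cfg = PreprocessConfig(window_length=24, prediction_steps=2, step=2)
    inst = preprocess_series(make_periodic_series(6), cfg)
    spec = ModelSpec("lstm", window_length=24, prediction_steps=2)
    tm = train(build_model(spec, seed=0), inst,
               config=TrainingConfig(batch_size=32, max_epochs=2, loss="mse", seed=0))
    store = UserStore(root)
    store.store("alice", 30, tm, manifest={"user": "alice"})
    return store


class TestSubsequentUse:

    def test_no_stored_model_raises_pointing_to_first_use(self, stored, tmp_path):
        series = make_periodic_series(2)
        path = write_cgm_csv(series, tmp_path / "day.csv")
        with pytest.raises(FileNotFoundError, match="first_use"):
            subsequent_use(path, stored, "bob", ph_minutes=30)

    def test_clean_last_day_yields_prediction_and_alert_scan(self, stored, tmp_path):
        path = write_cgm_csv(make_periodic_series(2), tmp_path / "day.csv")
        outcome = subsequent_use(path, stored, "alice", ph_minutes=30)
        assert outcome.status == STATUS_PREDICTION
        assert outcome.prediction.shape == (2,)
        assert np.all(np.isfinite(outcome.prediction))

    def test_recent_gap_refuses_prediction(self, stored, tmp_path):
        series = make_periodic_series(2)
        keep = np.ones(len(series), dtype=bool)
        keep[-12:-9] = False  # 45-min hole ~3 h before the end
        path = write_cgm_csv(drop_readings(series, keep), tmp_path / "gap.csv")
        outcome = subsequent_use(path, stored, "alice", ph_minutes=30)
        assert outcome.status == STATUS_REFUSED_PREDICTION
        assert outcome.explanation is not None

    def test_too_few_readings_refuses(self, stored, tmp_path):
        path = write_cgm_csv(make_periodic_series(2).__class__(
            subject_id="x", readings=make_periodic_series(2).readings[:20]),
            tmp_path / "few.csv")
        outcome = subsequent_use(path, stored, "alice", ph_minutes=30)
        assert outcome.status == STATUS_REFUSED_PREDICTION
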