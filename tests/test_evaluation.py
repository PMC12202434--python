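"""Metrics, the consensus error grid, and the ISO/grid crossover."""

import numpy as np
import pytest

from glucodiy.evaluation import (
    CEGGrid,
    PredictionBatch,
    ceg_zone,
    classify_zones,
    evaluate,
    iso_ceg_crossover,
    iso_zone_percent,
    parkes_ab_percent,
    pointwise_metrics,
)


@pytest.fixture(scope="module")
def grid():
    return CEGGrid.consensus_t1d()


def brute_force_zone(grid, ref, pred):
    """Independent classifier: matplotlib path point-in-polygon over the
    same vertex table, testing zones from least to most severe."""
    from matplotlib.path import Path as MplPath

    for zone in ("A", "B", "C", "D", "E"):
        for poly in grid.zone_polygons[zone]:
            path = MplPath(np.asarray(poly.exterior.coords))
            if path.contains_point((ref, pred), radius=1e-9) or \
               path.contains_point((ref, pred), radius=-1e-9):
                return zone
    raise AssertionError(f"point ({ref}, {pred}) in no zone")


class TestPointwiseMetrics:
    def test_symmetric_errors(self):
        rmse, mae, mape = pointwise_metrics(PredictionBatch([110.0, 90.0], [100.0, 100.0]))
        assert (rmse, mae, mape) == (pytest.approx(10.0), pytest.approx(10.0), pytest.approx(10.0))

    def test_perfect_prediction(self):
        assert pointwise_metrics(PredictionBatch([120.0], [120.0])) == (0.0, 0.0, 0.0)

    def test_single_pair(self):
        rmse, mae, mape = pointwise_metrics(PredictionBatch([230.0], [200.0]))
        assert (rmse, mae) == (pytest.approx(30.0), pytest.approx(30.0))
        assert mape == pytest.approx(15.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            PredictionBatch([], [])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(50, 300, 100)
        pred = ref + rng.normal(0, 20, 100)
        perm = rng.permutation(100)
        a = pointwise_metrics(PredictionBatch(pred, ref))
        b = pointwise_metrics(PredictionBatch(pred[perm], ref[perm]))
        assert a == pytest.approx(b)


class TestIsoZone:
    @pytest.mark.parametrize("ref,pred,inside", [
        (90.0, 104.0, True),    # |14| <= 15, absolute branch
        (90.0, 106.0, False),
        (200.0, 230.0, True),   # 30 == 15% of 200, boundary inclusive
        (200.0, 230.1, False),
        (100.0, 115.0, True),   # at 100 the percentage branch applies
    ])
    def test_branch_rule(self, ref, pred, inside):
        assert iso_zone_percent(PredictionBatch([pred], [ref])) == (100.0 if inside else 0.0)

    def test_identical_pairs_are_100(self):
        assert iso_zone_percent(PredictionBatch([88.0] * 5, [88.0] * 5)) == 100.0


class TestCEGZones:
    def test_diagonal_is_zone_a(self, grid):
        assert ceg_zone(100.0, 100.0, grid) == "A"

    def test_severe_underestimate_is_worse_than_b(self, grid):
        assert ceg_zone(160.0, 20.0, grid) in ("C", "D", "E")

    def test_out_of_domain_rejected(self, grid):
        with pytest.raises(ValueError):
            ceg_zone(600.0, 100.0, grid)

    def test_partition_every_point_gets_one_zone(self, grid):
        rng = np.random.default_rng(12)
        ref = rng.uniform(0, 550, 20000)
        pred = rng.uniform(0, 550, 20000)
        labels = classify_zones(grid, ref, pred)
        assert set(np.unique(labels)) <= set("ABCDE")

    def test_matches_brute_force_oracle(self, grid):
        rng = np.random.default_rng(7)
        ref = rng.uniform(0, 550, 2000)
        pred = rng.uniform(0, 550, 2000)
        labels = classify_zones(grid, ref, pred)
        expect = [brute_force_zone(grid, r, p) for r, p in zip(ref, pred)]
        assert labels.tolist() == expect

    def test_parkes_ab_counts(self, grid):
        ref = np.full(100, 160.0)
        pred = ref.copy()
        pred[0] = 20.0  # one pair outside A∪B
        assert parkes_ab_percent(PredictionBatch(pred, ref), grid) == pytest.approx(99.0)

    def test_all_diagonal_is_100(self, grid):
        v = np.linspace(20, 500, 50)
        assert parkes_ab_percent(PredictionBatch(v, v), grid) == 100.0


class TestCrossover:
    def test_high_endpoint_is_174(self, grid):
        low, high = iso_ceg_crossover(grid)
        assert high == 174

    def test_low_endpoint_near_164(self, grid):
        low, _ = iso_ceg_crossover(grid)
        assert abs(low - 164) <= 2

    def test_below_100_iso_bound_is_binding(self, grid):
        r = np.arange(40.0, 100.0)
        assert np.all(grid.zone_a_deviation(r) > 15.0)

    def test_iso_zone_implies_zone_a_outside_crossover(self, grid):
        """Pairs passing the ISO criterion sit in zone A except possibly for
        references inside the crossover range."""
        low, high = iso_ceg_crossover(grid)
        rng = np.random.default_rng(3)
        ref = rng.uniform(40, 470, 4000)
        bound = np.where(ref < 100, 15.0, 0.15 * ref)
        pred = ref + rng.uniform(-1, 1, ref.shape) * bound
        labels = classify_zones(grid, ref, pred)
        outside = (ref < low) | (ref > high)
        assert np.all(labels[outside] == "A")
        assert np.any(labels[~outside] != "A")  # the crossover is real


class TestEvaluate:
    def test_naive_on_constant_windows_is_perfect(self):
        from glucodiy.models import ModelSpec, NaiveModel, TrainedModel, TrainingHistory
        from glucodiy.preprocessing import InstanceSet, NormalizationParams

        norm = NormalizationParams(100.0, 140.0)
        n, N, h = 5, 8, 2
        X = np.full((n, N, 2), 0.5)
        X[:, :, 1] = 0.0
        Y = np.full((n, h), 0.5)  # 120 mg/dl everywhere
        inst = InstanceSet(X=X, Y=Y, source_block=np.zeros(n, dtype=int), norm=norm)
        spec = ModelSpec("naive", window_length=N, prediction_steps=h)
        tm = TrainedModel(spec, NaiveModel(spec), norm, TrainingHistory())
        rep = evaluate(tm, inst)
        assert rep.rmse == 0.0 and rep.parkes_ab == 100.0 and rep.iso_zone == 100.0
        assert rep.n_points == n * h

    def test_report_matches_flat_dump_recomputation(self):
        from glucodiy.models import ModelSpec, NaiveModel, TrainedModel, TrainingHistory, predict_batch
        from glucodiy.preprocessing import InstanceSet, NormalizationParams, denormalize

        rng = np.random.default_rng(4)
        norm = NormalizationParams(40.0, 400.0)
        n, N, h = 40, 8, 2
        X = rng.uniform(0.1, 0.8, size=(n, N, 2))
        Y = rng.uniform(0.1, 0.8, size=(n, h))
        inst = InstanceSet(X=X, Y=Y, source_block=np.zeros(n, dtype=int), norm=norm)
        spec = ModelSpec("naive", window_length=N, prediction_steps=h)
        tm = TrainedModel(spec, NaiveModel(spec), norm, TrainingHistory())
        rep = evaluate(tm, inst)
        pred = predict_batch(tm, X).ravel()
        ref = denormalize(Y, norm).ravel()
        rmse, mae, mape = pointwise_metrics(PredictionBatch(pred, ref))
        assert rep.rmse == pytest.approx(rmse)
        assert rep.mae == pytest.approx(mae)
        assert rep.mape == pytest.approx(mape)
        assert rep.iso_zone == pytest.approx(iso_zone_percent(PredictionBatch(pred, ref)))

    def test_empty_validation_set_rejected(self):
        from glucodiy.models import ModelSpec, NaiveModel, TrainedModel, TrainingHistory
        from glucodiy.preprocessing import InstanceSet, NormalizationParams

        norm = NormalizationParams(40.0, 400.0)
        inst = InstanceSet(X=np.empty((0, 8, 2)), Y=np.empty((0, 2)), norm=norm)
        spec = ModelSpec("naive", window_length=8, prediction_steps=2)
        tm = TrainedModel(spec, NaiveModel(spec), norm, TrainingHistory())
        with pytest.raises(ValueError):
            evaluate(tm, inst)
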