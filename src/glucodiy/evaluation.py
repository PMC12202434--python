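"""Prediction evaluation: pointwise metrics and diabetes-specific criteria.

Pointwise metrics are the classical RMSE, MAE and MAPE over all predicted
samples.  The diabetes-specific criteria repurpose the two accuracy rules of
ISO 15197:2015 as prediction-error criteria:

* **ISOZone** — the percentage of predictions within ±15 mg/dl of the
  reference when the reference is below 100 mg/dl, or within ±15 % of it
  otherwise (boundary inclusive).  The standard requires 95 %.
* **ParkesAB** — the percentage of predictions falling in zones A or B of
  the consensus (Parkes) error grid for type 1 diabetes.  The standard
  requires 99 %.

The grid partitions the (reference, predicted) plane into risk zones A
(clinically benign) through E (dangerous).  Zone geometry comes from the
published consensus vertex table vendored with the package
(``data/ceg_t1d_vertices.csv``); alternative vertex tables can be loaded.
Points exactly on a boundary take the less severe zone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import shapely

from glucodiy.objectives import IsoLossParams

ZONES = ("A", "B", "C", "D", "E")
DOMAIN_MAX = 550.0


@dataclass
class CEGGrid:
    """Consensus error grid zone geometry for T1D.

    ``boundaries`` maps each boundary polyline name (``AB_upper`` etc.) to an
    (m, 2) array of (reference, predicted) vertices.  Zone polygons are built
    so that the five zones partition the [0, 550]^2 domain; boundary points
    are resolved to the less severe zone by testing zones in increasing
    severity.
    """

    boundaries: dict[str, np.ndarray]
    zone_polygons: dict[str, list] = field(default_factory=dict)

    @classmethod
    def consensus_t1d(cls) -> "CEGGrid":
        """The vendored published consensus grid for type 1 diabetes."""
        path = resources.files("glucodiy.data") / "ceg_t1d_vertices.csv"
        with path.open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "CEGGrid":
        with open(path) as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, fh) -> "CEGGrid":
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")))]
        boundaries: dict[str, list[tuple[float, float]]] = {}
        for r in rows:
            boundaries.setdefault(r["boundary"], []).append(
                (float(r["reference"]), float(r["predicted"])))
        grid = cls(boundaries={k: np.array(v) for k, v in boundaries.items()})
        grid._build_polygons()
        return grid

    def _build_polygons(self) -> None:
        b = self.boundaries
        M = DOMAIN_MAX

        def poly(points):
            return shapely.Polygon(points)

        def fwd(name):
            return [tuple(p) for p in b[name]]

        def rev(name):
            return [tuple(p) for p in b[name][::-1]]

        self.zone_polygons = {
            # A: band around the diagonal between the two A/B boundaries.
            "A": [poly([(0.0, 0.0)] + fwd("AB_lower") + [(M, M)] + rev("AB_upper"))],
            # B, C, D: upper and lower lobes between successive boundaries.
            "B": [
                poly(fwd("AB_upper") + rev("BC_upper")),
                poly(fwd("AB_lower") + rev("BC_lower")),
            ],
            "C": [
                poly(fwd("BC_upper") + rev("CD_upper")),
                poly(fwd("BC_lower") + rev("CD_lower")),
            ],
            "D": [
                poly(fwd("CD_upper") + rev("DE_upper")),
                poly(fwd("CD_lower") + [(M, 0.0)]),
            ],
            # E: the top-left corner beyond the D/E boundary (T1D grid only
            # has an E region above the diagonal).
            "E": [poly(fwd("DE_upper") + [(0.0, M)])],
        }

    # -- boundary geometry helpers -----------------------------------------

    def _boundary_y(self, name: str, ref: np.ndarray, fill: float) -> np.ndarray:
        """Predicted value of a boundary polyline at the given references.

        Outside the polyline's reference range the boundary does not exist
        and ``fill`` is returned (+inf for upper, -inf for lower).  Vertical
        segments take the extreme y at that reference.
        """
        pts = self.boundaries[name]
        x, y = pts[:, 0], pts[:, 1]
        ref = np.asarray(ref, dtype=float)
        out = np.full(ref.shape, fill)
        inside = (ref >= x.min()) & (ref <= x.max())
        # np.interp handles duplicate x (vertical segments) by taking a side;
        # resolve verticals explicitly to the extreme value.
        yi = np.interp(ref[inside], x, y)
        for xv in x[np.concatenate(([False], np.diff(x) == 0))]:
            at = ref[inside] == xv
            seg = y[x == xv]
            # take the end of the vertical segment nearest the diagonal
            yi[at] = seg.min() if fill == np.inf else seg.max()
        out[inside] = yi
        return out

    def zone_a_deviation(self, ref) -> np.ndarray:
        """Vertical distance from the diagonal to the nearest zone-A boundary."""
        ref = np.asarray(ref, dtype=float)
        up = self._boundary_y("AB_upper", ref, np.inf) - ref
        dn = ref - self._boundary_y("AB_lower", ref, -np.inf)
        return np.minimum(up, dn)


def classify_zones(grid: CEGGrid, reference, predicted) -> np.ndarray:
    """Zone label (A–E) of each (reference, predicted) pair.

    Zones are tested from least to most severe, so boundary points take the
    less severe zone.  Raises for points outside the [0, 550] domain.
    """
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    pred = np.atleast_1d(np.asarray(predicted, dtype=float))
    if np.any((ref < 0) | (ref > DOMAIN_MAX) | (pred < 0) | (pred > DOMAIN_MAX)):
        raise ValueError(f"points must lie in [0, {DOMAIN_MAX}] mg/dl")
    labels = np.full(ref.shape, "?", dtype="U1")
    todo = np.ones(ref.shape, dtype=bool)
    for zone in ZONES:
        for poly in grid.zone_polygons[zone]:
            if not todo.any():
                break
            hit = todo.copy()
            hit[todo] = shapely.intersects_xy(poly, ref[todo], pred[todo])
            labels[hit] = zone
            todo &= ~hit
    if todo.any():  # numerical slivers between polygons: snap to nearest zone
        for i in np.flatnonzero(todo):
            pt = shapely.Point(ref[i], pred[i])
            dists = {z: min(p.distance(pt) for p in grid.zone_polygons[z]) for z in ZONES}
            labels[i] = min(dists, key=dists.get)
    return labels


def ceg_zone(reference: float, predicted: float, grid: CEGGrid | None = None) -> str:
    """Zone label of a single (reference, predicted) pair."""
    grid = grid or CEGGrid.consensus_t1d()
    return str(classify_zones(grid, reference, predicted)[0])


@dataclass
class PredictionBatch:
    """Paired predicted/reference glucose values, mg/dl."""

    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        if self.predicted.shape != self.reference.shape:
            raise ValueError("predicted and reference must have equal length")
        if self.predicted.size == 0:
            raise ValueError("empty prediction batch")

    def __len__(self) -> int:
        return int(self.predicted.size)


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    mape: float
    parkes_ab: float
    iso_zone: float
    n_points: int
    provenance: dict = field(default_factory=dict, hash=False, compare=False)


def pointwise_metrics(batch: PredictionBatch) -> tuple[float, float, float]:
    """RMSE and MAE in mg/dl, MAPE in percent."""
    if np.any(batch.reference <= 0):
        raise ValueError("references must be positive for MAPE")
    err = batch.predicted - batch.reference
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / batch.reference) * 100.0)
    return rmse, mae, mape


def iso_zone_percent(batch: PredictionBatch, params: IsoLossParams | None = None) -> float:
    """Percentage of pairs meeting the ISO accuracy criterion (inclusive bound)."""
    params = params or IsoLossParams()
    ref, pred = batch.reference, batch.predicted
    if np.any(ref <= 0):
        raise ValueError("references must be positive")
    bound = np.where(ref < params.low_ref_bound, params.abs_tolerance,
                     params.abs_tolerance / 100.0 * ref)
    return float(np.mean(np.abs(pred - ref) <= bound) * 100.0)


def parkes_ab_percent(batch: PredictionBatch, grid: CEGGrid | None = None) -> float:
    """Percentage of pairs in consensus grid zones A or B."""
    grid = grid or CEGGrid.consensus_t1d()
    labels = classify_zones(grid, batch.reference, batch.predicted)
    return float(np.mean((labels == "A") | (labels == "B")) * 100.0)


def iso_ceg_crossover(grid: CEGGrid | None = None, iso_params: IsoLossParams | None = None,
                      lo: float = 40.0, hi: float = DOMAIN_MAX, step: float = 0.05) -> tuple[int, int]:
    """Reference range where the zone-A boundary is stricter than the ISO bound.

    Scans reference values at ``step`` resolution, compares the admissible
    vertical deviation to the nearest zone-A boundary with the ISO bound
    (15 mg/dl below 100, 15 % at or above), and returns the contiguous range
    where the grid is the binding constraint, endpoints rounded to the
    nearest mg/dl.
    """
    grid = grid or CEGGrid.consensus_t1d()
    iso_params = iso_params or IsoLossParams()
    r = np.arange(lo, hi + step / 2, step)
    a_dev = grid.zone_a_deviation(r)
    iso_bound = np.where(r < iso_params.low_ref_bound, iso_params.abs_tolerance,
                         iso_params.abs_tolerance / 100.0 * r)
    binding = a_dev < iso_bound
    if not binding.any():
        raise ValueError("zone A is never the binding constraint on this grid")
    idx = np.flatnonzero(binding)
    return int(round(r[idx[0]])), int(round(r[idx[-1]]))


def evaluate(trained, validation: "InstanceSet", grid: CEGGrid | None = None,
             provenance: dict | None = None) -> MetricsReport:
    """All five metrics of a trained model over a validation instance set.

    Predictions are denormalized to mg/dl and pooled over all predicted
    samples of all instances (not per-sequence means).
    """
    from glucodiy.models import predict_batch
    from glucodiy.preprocessing import denormalize

    if len(validation) == 0:
        raise ValueError("empty validation set")
    grid = grid or CEGGrid.consensus_t1d()
    pred = predict_batch(trained, validation.X)
    ref = denormalize(validation.Y, validation.norm)
    batch = PredictionBatch(predicted=np.clip(pred, 0.0, DOMAIN_MAX), reference=ref)
    rmse, mae, mape = pointwise_metrics(batch)
    return MetricsReport(
        rmse=rmse, mae=mae, mape=mape,
        parkes_ab=parkes_ab_percent(batch, grid),
        iso_zone=iso_zone_percent(batch),
        n_points=len(batch),
        provenance=provenance or {},
    )
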