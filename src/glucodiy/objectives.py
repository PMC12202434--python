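"""Training objectives and glycemic-range instance weighting.

The ISO 15197:2015 accuracy criterion allows a prediction error of up to
±15 mg/dl when the reference is below 100 mg/dl and ±15 % of the reference
otherwise.  Expressing the error on that normalized scale —

    eps = (pred - ref)            if ref < 100
    eps = (pred - ref) * 100/ref  if ref >= 100

— turns the criterion into a single bound |eps| <= 15.  The ISO-adapted loss
adds to the squared normalized error a steep, smooth polynomial barrier

    gamma(eps) = K * eps**(2n),     L_ISO(eps) = eps**2 + gamma(eps)

with n = 40 and K = 0.1 / 14**80: negligible (<= 0.1) inside |eps| <= 14 and
exploding just past the admissible bound, pushing training towards
ISO-compliant errors while staying differentiable and monotone in |eps|.

Because hypoglycemic samples are rare but clinically critical, target
sequences are weighted by glycemic range with inverse-probability weights:

    W_hypo = 2 / p(hypo),  W_hyper = 1.1 / p(hyper),  W_inrange = 1 / p(inrange)

where the probabilities are the subject's empirical fractions of samples
below 70, above 180, and in between.  A sequence takes the hypo weight if it
contains any hypo sample, else the hyper weight if any hyper sample, else
the in-range weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: log-space exponent clip keeping gamma and its gradient finite in float64.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class IsoLossParams:
    """Barrier parameters: gamma(eps) = K * eps**(2n)."""

    n: int = 40
    K: float = 0.1 / 14.0 ** 80
    low_ref_bound: float = 100.0   # mg/dl; below it the error is absolute
    abs_tolerance: float = 15.0    # mg/dl, the ISO admissible bound

    def __post_init__(self) -> None:
        if self.n < 1 or self.K <= 0:
            raise ValueError("n >= 1 and K > 0 required")


@dataclass(frozen=True)
class GlycemicThresholds:
    """Hypo/hyper boundaries of the 70–180 mg/dl target range."""

    hypo: float = 70.0
    hyper: float = 180.0

    def __post_init__(self) -> None:
        if not self.hypo < self.hyper:
            raise ValueError("hypo threshold must be below hyper threshold")


@dataclass(frozen=True)
class RangeWeights:
    """Per-subject empirical range probabilities and their weights.

    A weight is ``None`` when its range never occurs in the subject's data
    (it can then never be requested, since no such target sequence exists).
    """

    p_hypo: float
    p_hyper: float
    p_inrange: float
    w_hypo: Optional[float]
    w_hyper: Optional[float]
    w_inrange: Optional[float]


def normalized_error(predicted, reference, params: IsoLossParams | None = None):
    """ISO-normalized signed error: absolute below 100 mg/dl, percentage-scaled above.

    |eps| <= 15 is exactly the ISO accuracy criterion for the sample.
    """
    params = params or IsoLossParams()
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    err = pred - ref
    return np.where(ref < params.low_ref_bound, err, err * 100.0 / ref)


def iso_gamma(eps, params: IsoLossParams | None = None):
    """Barrier term K * eps**(2n), computed in log space to avoid overflow.

    Even and monotone in |eps|; gamma(14) = 0.1 exactly with the default K.
    """
    params = params or IsoLossParams()
    scalar = np.isscalar(eps) or np.ndim(eps) == 0
    e = np.atleast_1d(np.asarray(eps, dtype=float))
    out = np.zeros_like(e)
    nz = e != 0
    with np.errstate(divide="ignore"):
        log_g = np.log(params.K) + 2 * params.n * np.log(np.abs(e[nz]))
    out[nz] = np.exp(np.clip(log_g, -_EXP_CLIP, _EXP_CLIP))
    return float(out[0]) if scalar else out


def iso_gamma_grad(eps, params: IsoLossParams | None = None):
    """d(gamma)/d(eps) = 2n * K * eps**(2n-1), via the log-space gamma."""
    params = params or IsoLossParams()
    scalar = np.isscalar(eps) or np.ndim(eps) == 0
    e = np.atleast_1d(np.asarray(eps, dtype=float))
    g = np.atleast_1d(np.asarray(iso_gamma(e, params)))
    out = np.zeros_like(e)
    nz = e != 0
    out[nz] = 2 * params.n * g[nz] / e[nz]
    return float(out[0]) if scalar else out


def iso_loss(predicted, reference, params: IsoLossParams | None = None) -> float:
    """Mean ISO-adapted loss over paired sequences (mg/dl inputs).

    Reduces to the mean squared normalized error as K -> 0.
    """
    params = params or IsoLossParams()
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    eps = normalized_error(pred, ref, params)
    return float(np.mean(eps ** 2 + iso_gamma(eps, params)))


def compute_range_probabilities(samples, thresholds: GlycemicThresholds | None = None) -> RangeWeights:
    """Empirical range occupancy of the training samples and the derived weights."""
    thresholds = thresholds or GlycemicThresholds()
    v = np.asarray(samples, dtype=float)
    if v.size == 0:
        raise ValueError("need a non-empty sample list")
    p_hypo = float(np.mean(v < thresholds.hypo))
    p_hyper = float(np.mean(v > thresholds.hyper))
    p_in = 1.0 - p_hypo - p_hyper
    return RangeWeights(
        p_hypo=p_hypo,
        p_hyper=p_hyper,
        p_inrange=p_in,
        w_hypo=2.0 / p_hypo if p_hypo > 0 else None,
        w_hyper=1.1 / p_hyper if p_hyper > 0 else None,
        w_inrange=1.0 / p_in if p_in > 0 else None,
    )


def instance_weight(target_mgdl, weights: RangeWeights,
                    thresholds: GlycemicThresholds | None = None) -> float:
    """Weight of one target sequence: hypo dominates hyper dominates in-range."""
    thresholds = thresholds or GlycemicThresholds()
    y = np.asarray(target_mgdl, dtype=float)
    if np.any(y < thresholds.hypo):
        assert weights.w_hypo is not None
        return weights.w_hypo
    if np.any(y > thresholds.hyper):
        assert weights.w_hyper is not None
        return weights.w_hyper
    assert weights.w_inrange is not None
    return weights.w_inrange


def instance_weights(targets_mgdl: np.ndarray, weights: RangeWeights,
                     thresholds: GlycemicThresholds | None = None) -> np.ndarray:
    """Vectorized :func:`instance_weight` over an (n, h) array of targets."""
    thresholds = thresholds or GlycemicThresholds()
    Y = np.asarray(targets_mgdl, dtype=float)
    out = np.empty(Y.shape[0])
    any_hypo = np.any(Y < thresholds.hypo, axis=1)
    any_hyper = np.any(Y > thresholds.hyper, axis=1)
    for i in range(Y.shape[0]):
        if any_hypo[i]:
            out[i] = weights.w_hypo
        elif any_hyper[i]:
            out[i] = weights.w_hyper
        else:
            out[i] = weights.w_inrange
    return out
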