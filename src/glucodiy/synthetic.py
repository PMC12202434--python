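"""Statistical CGM simulator.

Real long-term CGM traces are private, so the simulator produces series with
the statistical structure the forecasting pipeline consumes: a circadian
basal rhythm, meal excursions at breakfast/lunch/dinner-like hours,
occasional hypoglycemic dips (so that the hypo-range instance weighting is
exercised), autocorrelated sensor noise, and reading interruptions.

This is deliberately *not* a physiological insulin–glucose model: no insulin
kinetics, no carbohydrate accounting.  The goal is a trace whose window
statistics (circadian periodicity, excursion shapes, occupancy of the
70–180 mg/dl target range) resemble a person with T1D wearing a 15-min
sensor for a year.

Determinism: all draws come from ``numpy.random.default_rng`` seeded from
``SimulationParams.seed``, so the same parameters give bitwise-identical
series on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta

import numpy as np

from glucodiy.cgm_io import CGMSeries, GlucoseReading

#: Default simulation start; an arbitrary fixed calendar anchor.
DEFAULT_START = datetime(2022, 1, 1, 0, 0, 0)

#: Daily meal anchors (hours) and their relative likelihood.
_MEAL_ANCHORS_H = np.array([8.0, 13.5, 20.0])
_MEAL_JITTER_H = 1.25


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic subject.

    Defaults target a plausible T1D profile on a 15-min sensor: basal around
    140 mg/dl with a ±20 mg/dl circadian swing, ~3 meals/day with ~55 mg/dl
    median excursions, a hypoglycemic dip every 2-3 days, mildly
    autocorrelated sensor noise, and about one multi-hour reading gap every
    two days.
    """

    n_days: int = 365
    sampling_period: float = 15.0           # minutes
    basal_mean: float = 140.0               # mg/dl
    circadian_amplitude: float = 20.0       # mg/dl
    meal_rate: float = 3.0                  # meals/day (Poisson)
    meal_amplitude_mean: float = 55.0       # mg/dl, log-normal location (median)
    meal_amplitude_sd: float = 20.0         # mg/dl, spread of the log-normal
    meal_rise_min: float = 35.0             # absorption time constant, minutes
    meal_decay_min: float = 150.0           # clearance time constant, minutes
    noise_sd: float = 5.0                   # stationary sensor-noise SD, mg/dl
    noise_autocorr: float = 0.7             # AR(1) coefficient, [0, 1)
    hypo_event_rate: float = 0.4            # events/day (Poisson)
    hypo_depth_range: tuple[float, float] = (40.0, 70.0)   # dip depth, mg/dl
    hypo_duration_min: float = 60.0         # full width of a dip, minutes
    interruption_rate: float = 0.5          # gaps/day (Poisson)
    interruption_mean_len: float = 120.0    # mean gap length, minutes (exponential)
    clip_range: tuple[float, float] = (40.0, 400.0)        # sensor clipping, mg/dl
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1 or self.sampling_period <= 0:
            raise ValueError("n_days >= 1 and sampling_period > 0 required")
        for name in ("meal_rate", "hypo_event_rate", "interruption_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_autocorr < 1:
            raise ValueError("noise_autocorr must be in [0, 1)")
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range low must be below high")


def _excursion_kernel(t_min: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Two-compartment absorption kernel, peak-normalized to 1.

    ``exp(-t/tau_decay) - exp(-t/tau_rise)`` for t >= 0: a smooth rise over
    roughly ``tau_rise`` and an exponential clearance over ``tau_decay``.
    """
    t = np.maximum(t_min, 0.0)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    k[t_min < 0] = 0.0
    return k / peak


def _add_bumps(trace: np.ndarray, t_min: np.ndarray, centers_min: np.ndarray,
               amplitudes: np.ndarray, kernel_fn, support_min: float) -> None:
    """Superpose ``amplitudes[i] * kernel_fn(t - centers[i])`` onto ``trace`` in place."""
    if len(centers_min) == 0:
        return
    dt = t_min[1] - t_min[0] if len(t_min) > 1 else 1.0
    half = int(np.ceil(support_min / dt))
    n = len(trace)
    for c, a in zip(centers_min, amplitudes):
        i0 = max(0, int((c - support_min) // dt))
        i1 = min(n, i0 + 2 * half + 2)
        trace[i0:i1] += a * kernel_fn(t_min[i0:i1] - c)


def simulate_subject(params: SimulationParams, subject_id: str | None = None,
                     start: datetime = DEFAULT_START) -> CGMSeries:
    """Generate one subject's CGM series at the nominal sampling period.

    The trace is basal + 24-h sinusoid + meal excursions (Poisson daily meal
    counts at jittered anchor hours, log-normal amplitudes) + hypoglycemic
    dips (negative Gaussian bumps) + AR(1) sensor noise, clipped to the
    sensor range.  Interruptions are *not* injected here; see
    :func:`inject_interruptions`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.n_days * 24 * 60 / params.sampling_period))
    t_min = np.arange(n) * params.sampling_period
    hours = (t_min / 60.0) % 24.0

    trace = params.basal_mean + params.circadian_amplitude * np.sin(2 * np.pi * (hours - 11.0) / 24.0)

    # Meals: Poisson count per day, times drawn around anchor hours.
    meal_t, meal_a = [], []
    for day in range(params.n_days):
        k = rng.poisson(params.meal_rate)
        for _ in range(k):
            anchor = rng.choice(_MEAL_ANCHORS_H)
            hour = anchor + rng.normal(0.0, _MEAL_JITTER_H)
            meal_t.append(day * 24 * 60 + hour * 60.0)
            # log-normal with median = meal_amplitude_mean
            sigma = params.meal_amplitude_sd / max(params.meal_amplitude_mean, 1e-9)
            meal_a.append(params.meal_amplitude_mean * rng.lognormal(0.0, sigma))
    _add_bumps(trace, t_min, np.array(meal_t), np.array(meal_a),
               lambda dt: _excursion_kernel(dt, params.meal_rise_min, params.meal_decay_min),
               support_min=8 * 60.0)

    # Hypoglycemic dips: negative Gaussian bumps, more likely at night.
    n_hypo = rng.poisson(params.hypo_event_rate * params.n_days)
    hypo_day = rng.uniform(0, params.n_days, size=n_hypo)
    hypo_hour = rng.normal(4.0, 4.0, size=n_hypo) % 24.0
    hypo_t = hypo_day.astype(int) * 24 * 60 + hypo_hour * 60.0
    lo, hi = params.hypo_depth_range
    hypo_depth = -rng.uniform(lo, hi, size=n_hypo)
    sd = params.hypo_duration_min / 2.355  # FWHM -> sigma
    _add_bumps(trace, t_min, hypo_t, hypo_depth,
               lambda dt: np.exp(-0.5 * ((dt - 2 * sd) / sd) ** 2),
               support_min=4 * params.hypo_duration_min)

    # AR(1) sensor noise at stationary SD noise_sd.
    if params.noise_sd > 0:
        a = params.noise_autocorr
        innov = rng.normal(0.0, params.noise_sd * np.sqrt(1 - a * a), size=n)
        noise = np.empty(n)
        prev = rng.normal(0.0, params.noise_sd)
        for i in range(n):
            prev = a * prev + innov[i]
            noise[i] = prev
        trace = trace + noise

    trace = np.clip(trace, params.clip_range[0], params.clip_range[1])

    step = timedelta(minutes=params.sampling_period)
    readings = [GlucoseReading(start + i * step, float(v)) for i, v in enumerate(trace)]
    return CGMSeries(subject_id=subject_id or f"sim-{params.seed:04d}",
                     readings=readings, sampling_period=params.sampling_period)


def inject_interruptions(series: CGMSeries, params: SimulationParams) -> CGMSeries:
    """Remove contiguous runs of readings to emulate sensor reading gaps.

    Gap starts follow a Poisson process at ``interruption_rate`` per day; gap
    lengths are exponential with mean ``interruption_mean_len`` minutes.
    Remaining readings are untouched.  Seeded independently of the trace
    generator (same ``params.seed``, separate stream), so the same series +
    params always lose the same readings.
    """
    params.validate()
    if params.interruption_rate == 0 or not series.readings:
        return series
    rng = np.random.default_rng([params.seed, 0x1A7])
    t0 = next(r.timestamp for r in series.readings if r.timestamp is not None)
    t_end = max(r.timestamp for r in series.readings if r.timestamp is not None)
    span_days = (t_end - t0).total_seconds() / 86400.0
    n_gaps = rng.poisson(params.interruption_rate * span_days)
    starts = rng.uniform(0.0, span_days * 24 * 60, size=n_gaps)
    lengths = rng.exponential(params.interruption_mean_len, size=n_gaps)
    keep = np.ones(len(series.readings), dtype=bool)
    offsets = np.array([
        (r.timestamp - t0).total_seconds() / 60.0 if r.timestamp is not None else np.nan
        for r in series.readings
    ])
    for s, ln in zip(starts, lengths):
        keep &= ~((offsets >= s) & (offsets < s + ln))
    from glucodiy.cgm_io import drop_readings

    return drop_readings(series, keep)


def time_in_ranges(series: CGMSeries, hypo: float = 70.0, hyper: float = 180.0) -> tuple[float, float, float]:
    """Fractions of valid readings (below, in, above) the 70–180 mg/dl target range."""
    v = series.values()
    if v.size == 0:
        raise ValueError("series has no valid readings")
    below = float(np.mean(v < hypo))
    above = float(np.mean(v > hyper))
    return below, 1.0 - below - above, above


def synthetic_cohort(n_subjects: int = 29, base_seed: int = 2022,
                     n_days: int = 365) -> list[SimulationParams]:
    """A battery of seeded parameterizations mirroring a 29-subject cohort.

    Subjects vary in basal level, meal behaviour, hypoglycemia propensity
    and interruption burden, spanning a realistic spread of time-in-range.
    """
    rng = np.random.default_rng(base_seed)
    cohort = []
    for i in range(n_subjects):
        cohort.append(SimulationParams(
            n_days=n_days,
            basal_mean=float(rng.uniform(120, 165)),
            circadian_amplitude=float(rng.uniform(10, 30)),
            meal_rate=float(rng.uniform(2.5, 4.0)),
            meal_amplitude_mean=float(rng.uniform(40, 75)),
            hypo_event_rate=float(rng.uniform(0.1, 0.8)),
            interruption_rate=float(rng.uniform(0.1, 1.0)),
            interruption_mean_len=float(rng.uniform(60, 240)),
            seed=int(base_seed * 1000 + i),
        ))
    return cohort


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
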