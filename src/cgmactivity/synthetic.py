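"""Seeded synthetic CGM / heart-rate / exercise cohort generator.

The simulator produces the statistical structure the detection pipeline
assumes in real data: interstitial glucose sampled every 5 minutes with a
slow mean-reverting wander, meal excursions, and an exercise-induced decline
that begins roughly 10-15 minutes after activity onset; a 1 Hz heart-rate and
activity-level stream with a first-order heart-rate rise during episodes;
additive sensor noise on every channel; per-subject body weight; occasional
CGM dropouts; and self-report failures (a configurable fraction of episodes
is generated but never labeled).

Each stochastic ingredient (episodes, meals, glucose wander, each noise
channel, gaps, reporting) consumes its own seeded substream, so two
configurations that differ in a single knob — say the CGM noise level —
produce cohorts whose other ingredients (episode times, meals, weights) are
identical. This makes ceteris-paribus comparisons and mechanism tests exact
rather than approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .records import SubjectSeries, make_series_frame

__all__ = [
    "SimConfig",
    "ExerciseEpisode",
    "GroundTruth",
    "SubjectBundle",
    "ConfigError",
    "generate_subject",
    "generate_cohort",
    "write_ohio_xml",
    "write_d1namo_csv",
]

#: Simulated study start; absolute dates are cosmetic, dynamics use minutes.
EPOCH = pd.Timestamp("2022-01-01 00:00:00")

# Substream identifiers. Each (seed, subject, stream) triple seeds an
# independent generator, so changing e.g. the noise level cannot perturb
# episode placement.
_S_WEIGHT = 0
_S_BASELINE = 1
_S_EPISODES = 2
_S_MEALS = 3
_S_DRIFT = 4
_S_CGM_NOISE = 5
_S_HR_NOISE = 6
_S_ACT_NOISE = 7
_S_GAPS = 8
_S_REPORTED = 9

#: Physiological floor for simulated glucose (mg/dL); counter-regulation
#: prevents indefinite decline in vivo.
BG_FLOOR = 40.0


class ConfigError(ValueError):
    """Raised when a SimConfig field is physically or logically invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    Defaults describe a cohort in which exercise is detectable but not
    trivial: a ~1 mg/dL/min glucose decline at mid intensity (lagged by
    ~12 min), a 20-50 bpm heart-rate elevation, CGM noise of 5 mg/dL and
    three meals a day that act as glycemic confounders.
    """

    n_subjects: int = 10
    days_per_subject: int = 7
    cgm_interval: int = 5  # minutes
    highrate_interval: int = 1  # seconds
    weight_range: tuple[float, float] = (55.0, 95.0)  # kg
    baseline_bg: tuple[float, float] = (140.0, 20.0)  # mg/dL (mean, sd)
    bg_drift: tuple[float, float] = (0.005, 0.4)  # (reversion /min, diffusion mg/dL/sqrt(min))
    meal_rate: float = 3.0  # events/day
    meal_rise: tuple[float, float] = (30.0, 80.0)  # mg/dL
    meal_rise_duration: float = 30.0  # min
    meal_decay_duration: float = 90.0  # min
    exercise_rate: float = 1.2  # events/day
    exercise_duration: tuple[float, float] = (10.0, 90.0)  # min
    exercise_intensity: tuple[int, int] = (3, 8)  # subjective 1-10
    glucose_drop_rate: float = 0.2  # mg/dL per min per unit intensity
    glycemic_lag: float = 12.0  # min between onset and CGM-visible decline
    post_exercise_decay: float = 60.0  # min, recovery time constant
    resting_hr: tuple[float, float] = (70.0, 6.0)  # bpm (mean, sd)
    hr_gain: float = 7.0  # bpm per unit intensity
    hr_onset_tau: float = 2.0  # min, first-order HR response
    cgm_noise_sd: float = 5.0  # mg/dL
    hr_noise_sd: float = 3.0  # bpm
    activity_rest: float = 0.05  # sensor activity units at rest
    activity_gain: float = 0.08  # activity units per unit intensity
    activity_noise_sd: float = 0.02
    unreported_fraction: float = 0.1  # P(an episode is never self-reported)
    gap_rate: float = 0.2  # CGM dropout events/day
    gap_duration: tuple[float, float] = (15.0, 120.0)  # min
    seed: int = 0

    def validate(self) -> None:
        def _positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")

        def _nonneg(name):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

        def _range(name, strict_low=None):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name}: low must not exceed high")
            if strict_low is not None and lo <= strict_low:
                raise ConfigError(f"{name}: low must exceed {strict_low}")

        for name in ("n_subjects", "days_per_subject", "cgm_interval",
                     "highrate_interval", "glycemic_lag", "post_exercise_decay",
                     "hr_onset_tau"):
            _positive(name)
        for name in ("meal_rate", "exercise_rate", "gap_rate", "cgm_noise_sd",
                     "hr_noise_sd", "activity_noise_sd", "glucose_drop_rate",
                     "hr_gain", "activity_gain", "activity_rest",
                     "meal_rise_duration", "meal_decay_duration"):
            _nonneg(name)
        _range("weight_range", strict_low=0.0)
        _range("meal_rise")
        _range("exercise_duration", strict_low=0.0)
        _range("exercise_intensity")
        _range("gap_duration", strict_low=0.0)
        lo, hi = self.exercise_intensity
        if lo < 1 or hi > 10:
            raise ConfigError("exercise_intensity must lie within [1, 10]")
        if not 0.0 <= self.unreported_fraction <= 1.0:
            raise ConfigError("unreported_fraction must lie in [0, 1]")
        if self.baseline_bg[0] <= 0 or self.baseline_bg[1] < 0:
            raise ConfigError("baseline_bg: mean must be positive, sd non-negative")
        if self.resting_hr[0] <= 0 or self.resting_hr[1] < 0:
            raise ConfigError("resting_hr: mean must be positive, sd non-negative")
        if self.bg_drift[0] < 0 or self.bg_drift[1] < 0:
            raise ConfigError("bg_drift: rate and diffusion must be non-negative")
        if (24 * 60) % self.cgm_interval != 0:
            raise ConfigError("cgm_interval must divide 24 hours")


@dataclass(frozen=True)
class ExerciseEpisode:
    start_min: float  # minutes from cohort epoch
    duration_min: float
    intensity: int  # 1-10
    reported: bool

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass
class GroundTruth:
    """All simulated episodes for one subject, reported or not."""

    episodes: list[ExerciseEpisode] = field(default_factory=list)

    def membership(self, t_min: np.ndarray, reported_only: bool = False) -> np.ndarray:
        """Binary membership of each time (minutes) in [start, end) of an episode."""
        out = np.zeros(len(t_min), dtype=np.int8)
        for ep in self.episodes:
            if reported_only and not ep.reported:
                continue
            out |= ((t_min >= ep.start_min) & (t_min < ep.end_min)).astype(np.int8)
        return out


@dataclass
class SubjectBundle:
    series: SubjectSeries
    highrate: Optional[pd.DataFrame]  # 1 Hz [ts, hr_bpm, activity] or None
    truth: GroundTruth


def _rng(config: SimConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, subject_index, stream])
    )


def _sample_episodes(config: SimConfig, subject_index: int) -> GroundTruth:
    horizon = config.days_per_subject * 24 * 60.0
    rng = _rng(config, subject_index, _S_EPISODES)
    rep = _rng(config, subject_index, _S_REPORTED)
    n = rng.poisson(config.exercise_rate * config.days_per_subject)
    episodes: list[ExerciseEpisode] = []
    lo_d, hi_d = config.exercise_duration
    lo_i, hi_i = config.exercise_intensity
    for _ in range(n):
        # rejection sampling keeps episodes non-overlapping -> unambiguous labels;
        # whole-minute starts/durations mirror the resolution of self-reports
        # (and survive any dialect round-trip losslessly)
        for _attempt in range(1000):
            dur = float(np.rint(rng.uniform(lo_d, hi_d)))
            if dur > horizon:
                continue
            start = float(np.rint(rng.uniform(0.0, horizon - dur)))
            if all(start + dur <= e.start_min or start >= e.end_min for e in episodes):
                break
        else:
            continue
        intensity = int(rng.integers(lo_i, hi_i + 1))
        reported = bool(rep.random() >= config.unreported_fraction)
        episodes.append(ExerciseEpisode(start, dur, intensity, reported))
    episodes.sort(key=lambda e: e.start_min)
    return GroundTruth(episodes)


def _exercise_bg_effect(t: np.ndarray, truth: GroundTruth, config: SimConfig) -> np.ndarray:
    """Lagged piecewise-linear decline with exponential post-exercise recovery."""
    effect = np.zeros_like(t, dtype=float)
    lag = config.glycemic_lag
    for ep in truth.episodes:
        s, e = ep.start_min + lag, ep.end_min + lag
        depth = config.glucose_drop_rate * ep.intensity
        during = (t >= s) & (t < e)
        after = t >= e
        effect[during] -= depth * (t[during] - s)
        total = depth * (e - s)
        effect[after] -= total * np.exp(-(t[after] - e) / config.post_exercise_decay)
    return effect


def _meal_effect(t: np.ndarray, config: SimConfig, subject_index: int) -> np.ndarray:
    horizon = config.days_per_subject * 24 * 60.0
    rng = _rng(config, subject_index, _S_MEALS)
    n = rng.poisson(config.meal_rate * config.days_per_subject)
    starts = np.sort(rng.uniform(0.0, horizon, size=n))
    heights = rng.uniform(*config.meal_rise, size=n)
    effect = np.zeros_like(t, dtype=float)
    rise, decay = config.meal_rise_duration, config.meal_decay_duration
    for t0, h in zip(starts, heights):
        rel = t - t0
        rising = (rel >= 0) & (rel < rise)
        falling = rel >= rise
        effect[rising] += h * rel[rising] / rise
        effect[falling] += h * np.exp(-(rel[falling] - rise) / decay)
    return effect


def _ou_wander(t: np.ndarray, config: SimConfig, subject_index: int) -> np.ndarray:
    """Mean-reverting (Ornstein-Uhlenbeck) glucose wander around baseline."""
    theta, sigma = config.bg_drift
    rng = _rng(config, subject_index, _S_DRIFT)
    x = np.zeros(len(t))
    if sigma == 0.0 or len(t) == 0:
        return x
    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        if theta > 0:
            a = math.exp(-theta * dt)
            sd = sigma * math.sqrt((1.0 - a * a) / (2.0 * theta))
        else:
            a, sd = 1.0, sigma * math.sqrt(dt)
        x[k] = a * x[k - 1] + sd * rng.standard_normal()
    return x


def _hr_response(t: np.ndarray, truth: GroundTruth, config: SimConfig) -> np.ndarray:
    """First-order heart-rate elevation above rest, in bpm."""
    resp = np.zeros_like(t, dtype=float)
    tau = config.hr_onset_tau
    for ep in truth.episodes:
        amp = config.hr_gain * ep.intensity
        during = (t >= ep.start_min) & (t < ep.end_min)
        after = t >= ep.end_min
        resp[during] += amp * (1.0 - np.exp(-(t[during] - ep.start_min) / tau))
        peak = amp * (1.0 - math.exp(-ep.duration_min / tau))
        resp[after] += peak * np.exp(-(t[after] - ep.end_min) / tau)
    return resp


def _activity_level(t: np.ndarray, truth: GroundTruth, config: SimConfig) -> np.ndarray:
    act = np.full_like(t, config.activity_rest, dtype=float)
    for ep in truth.episodes:
        during = (t >= ep.start_min) & (t < ep.end_min)
        act[during] += config.activity_gain * ep.intensity
    return act


def _gap_mask(t: np.ndarray, config: SimConfig, subject_index: int) -> np.ndarray:
    """True where a CGM registration survives (is NOT inside a dropout)."""
    keep = np.ones(len(t), dtype=bool)
    rng = _rng(config, subject_index, _S_GAPS)
    horizon = config.days_per_subject * 24 * 60.0
    n = rng.poisson(config.gap_rate * config.days_per_subject)
    for _ in range(n):
        dur = rng.uniform(*config.gap_duration)
        start = rng.uniform(0.0, horizon)
        keep &= ~((t >= start) & (t < start + dur))
    return keep


def generate_subject(
    config: SimConfig, subject_index: int, include_highrate: bool = True
) -> SubjectBundle:
    """Simulate one subject: 5-min CGM series, optional 1 Hz stream, ground truth.

    Deterministic given ``(config.seed, subject_index)``. The series exercise
    column is 1 exactly on grid points inside a *reported* episode, emulating
    self-report; unreported episodes shape glucose and heart rate but carry
    no label.
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(
            f"subject_index {subject_index} out of range [0, {config.n_subjects})"
        )

    horizon_min = config.days_per_subject * 24 * 60.0
    grid = np.arange(0.0, horizon_min, float(config.cgm_interval))

    weight = float(_rng(config, subject_index, _S_WEIGHT).uniform(*config.weight_range))
    baseline = float(
        _rng(config, subject_index, _S_BASELINE).normal(*config.baseline_bg)
    )
    resting = float(_rng(config, subject_index, _S_BASELINE).normal(*config.resting_hr))
    # note: baseline and resting HR share one substream (two sequential draws)

    truth = _sample_episodes(config, subject_index)

    bg = (
        baseline
        + _ou_wander(grid, config, subject_index)
        + _meal_effect(grid, config, subject_index)
        + _exercise_bg_effect(grid, truth, config)
    )
    if config.cgm_noise_sd > 0:
        bg = bg + _rng(config, subject_index, _S_CGM_NOISE).normal(
            0.0, config.cgm_noise_sd, size=len(grid)
        )
    bg = np.maximum(bg, BG_FLOOR)

    hr = resting + _hr_response(grid, truth, config)
    if config.hr_noise_sd > 0:
        hr = hr + _rng(config, subject_index, _S_HR_NOISE).normal(
            0.0, config.hr_noise_sd, size=len(grid)
        )
    hr = np.rint(np.clip(hr, 30.0, 230.0))

    labels = truth.membership(grid, reported_only=True)
    keep = _gap_mask(grid, config, subject_index)

    ts = EPOCH + pd.to_timedelta(grid[keep], unit="m")
    frame = make_series_frame(ts, bg[keep], hr[keep], labels[keep])
    series = SubjectSeries(
        subject_id=f"S{subject_index + 1:02d}",
        weight=weight,
        data=frame,
        nominal_interval=config.cgm_interval,
    )

    highrate = None
    if include_highrate:
        step = config.highrate_interval / 60.0  # minutes
        t_hi = np.arange(0.0, horizon_min, step)
        hr_hi = resting + _hr_response(t_hi, truth, config)
        if config.hr_noise_sd > 0:
            hr_hi = hr_hi + _rng(config, subject_index, _S_HR_NOISE).normal(
                0.0, config.hr_noise_sd, size=len(t_hi)
            )
        act_hi = _activity_level(t_hi, truth, config)
        if config.activity_noise_sd > 0:
            act_hi = act_hi + _rng(config, subject_index, _S_ACT_NOISE).normal(
                0.0, config.activity_noise_sd, size=len(t_hi)
            )
        highrate = pd.DataFrame(
            {
                "ts": EPOCH + pd.to_timedelta(t_hi, unit="m"),
                "hr_bpm": np.clip(hr_hi, 30.0, 230.0),
                "activity": np.maximum(act_hi, 0.0),
            }
        )

    return SubjectBundle(series=series, highrate=highrate, truth=truth)


def generate_cohort(config: SimConfig, include_highrate: bool = True) -> list[SubjectBundle]:
    """Simulate all subjects of the configured cohort, reproducibly."""
    config.validate()
    return [
        generate_subject(config, i, include_highrate=include_highrate)
        for i in range(config.n_subjects)
    ]


# ---------------------------------------------------------------------------
# Dialect writers: round-trip fixtures for the two ingest paths.
# ---------------------------------------------------------------------------

_OHIO_TS = "%d-%m-%Y %H:%M:%S"


def write_ohio_xml(bundle: SubjectBundle, path) -> None:
    """Write a subject as an Ohio-style XML archive.

    Layout: ``<patient id weight>`` with ``glucose_level``, ``exercise`` and
    ``basis_heart_rate`` sections of ``<event>`` elements. Timestamps use the
    ``DD-MM-YYYY HH:MM:SS`` dialect. Only self-reported episodes appear in
    the exercise section; glucose is written in mg/dL.
    """
    from lxml import etree

    series = bundle.series
    root = etree.Element(
        "patient", id=series.subject_id, weight=f"{series.weight:.1f}"
    )
    gl = etree.SubElement(root, "glucose_level")
    for ts, bg in zip(series.data["ts"], series.data["bg_mgdl"]):
        etree.SubElement(gl, "event", ts=ts.strftime(_OHIO_TS), value=f"{bg:.2f}")
    ex = etree.SubElement(root, "exercise")
    for ep in bundle.truth.episodes:
        if not ep.reported:
            continue
        start = EPOCH + pd.to_timedelta(ep.start_min, unit="m")
        etree.SubElement(
            ex,
            "event",
            ts=start.strftime(_OHIO_TS),
            intensity=str(ep.intensity),
            type="exercise",
            duration=f"{ep.duration_min:.0f}",
            competitive="false",
        )
    if series.data["hr_bpm"].notna().any():
        hr = etree.SubElement(root, "basis_heart_rate")
        for ts, v in zip(series.data["ts"], series.data["hr_bpm"]):
            if not np.isnan(v):
                etree.SubElement(hr, "event", ts=ts.strftime(_OHIO_TS), value=f"{v:.0f}")
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def write_d1namo_csv(bundle: SubjectBundle, directory) -> None:
    """Write a subject as a D1namo-style folder.

    ``glucose.csv``: one row per registration, ``date,time,glucose,type``
    with glucose converted to mmol/L and type ``cgm``. ``sensor.csv``: the
    1 Hz stream as ``datetime,hr,activity``. ``weight.txt``: body weight in kg.
    """
    from pathlib import Path

    from .records import MMOL_TO_MGDL

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series = bundle.series

    glucose = pd.DataFrame(
        {
            "date": series.data["ts"].dt.strftime("%Y-%m-%d"),
            "time": series.data["ts"].dt.strftime("%H:%M:%S"),
            "glucose": (series.data["bg_mgdl"] / MMOL_TO_MGDL).round(6),
            "type": "cgm",
        }
    )
    glucose.to_csv(directory / "glucose.csv", index=False)

    if bundle.highrate is None:
        raise ValueError(
            "D1namo dialect requires the 1 Hz stream; "
            "generate the subject with include_highrate=True"
        )
    sensor = pd.DataFrame(
        {
            "datetime": bundle.highrate["ts"].dt.strftime("%Y-%m-%d %H:%M:%S"),
            "hr": bundle.highrate["hr_bpm"].round(1),
            "activity": bundle.highrate["activity"].round(4),
        }
    )
    sensor.to_csv(directory / "sensor.csv", index=False)
    (directory / "weight.txt").write_text(f"{series.weight:.1f}\n")
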