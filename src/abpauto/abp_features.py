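"""The four ABPM/office classifiers and their derived quantities.

Classifiers (all thresholds configurable via :class:`FeatureConfig`, defaults
as used clinically):

* **Orthostatic hypotension (OH)** — sustained fall in SBP >= 20 mmHg or
  DBP >= 10 mmHg within 3 min of standing versus supine/sitting, assessed
  on the means of the available readings; ``delta_oh`` is the systolic fall.
* **Reversal of circadian pattern** — nocturnal mean BP equal to or above
  daytime mean BP (inclusive), night defined by journal sleep/wake times.
* **Postprandial hypotension (PPH)** — SBP fall >= 20 mmHg within 75 min
  after any meal, versus the last reading up to 60 min before the meal.
* **Non-compensatory heart-rate response ("heart rate variability")** —
  over adjacent readings, either (1) SBP falls by more than 20 mmHg with a
  HR rise below 10 beats/min, or (2) DBP falls by more than 10 mmHg with no
  HR rise.

``abp_total`` counts the abnormal trace-level components (0-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .errors import JournalInconsistencyError, UnevaluableError
from .io_formats import ABPTrace, BPReading, JournalEvent, OfficeBPRecord


class FeatureConfig(BaseModel):
    """All classifier thresholds in one place (units in field names)."""

    oh_sbp_drop_mmhg: float = 20.0       # inclusive, on supine-vs-standing means
    oh_dbp_drop_mmhg: float = 10.0       # inclusive
    oh_standing_max_min: float = 3.0     # qualifying standing readings
    reversal_component: str = Field(default="systolic", pattern="^(systolic|diastolic|map)$")
    min_segment_readings: int = 3
    default_sleep: time = time(22, 0)    # fallback night window when journal is silent
    default_wake: time = time(6, 0)
    pph_drop_mmhg: float = 20.0          # inclusive
    pph_window_min: float = 75.0         # post-meal search window (meal, meal+75]
    pph_baseline_max_min: float = 60.0   # baseline = last reading <= 60 min pre-meal
    hrv_sbp_drop_mmhg: float = 20.0      # condition 1 triggers when fall is STRICTLY greater
    hrv_sbp_hr_rise_bpm: float = 10.0    # non-compensatory when HR rise < 10
    hrv_dbp_drop_mmhg: float = 10.0      # condition 2 triggers when fall is STRICTLY greater
    hrv_dbp_hr_rise_bpm: float = 1.0     # "no rise": non-compensatory when HR rise < 1


@dataclass(frozen=True)
class OfficeOHResult:
    is_oh: bool
    delta_sbp: float       # mean supine/sitting SBP - mean standing SBP ("deltaOH")
    delta_dbp: float
    per_reading_flags: tuple[bool, ...]
    n_baseline: int
    n_standing: int


@dataclass(frozen=True)
class CircadianResult:
    day_mean: float
    night_mean: float
    component: str
    reversed: bool
    n_day: int
    n_night: int
    used_default_window: bool


@dataclass(frozen=True)
class MealWindow:
    meal_time: datetime
    baseline_sbp: Optional[float]
    min_post_sbp: Optional[float]
    drop: Optional[float]
    evaluable: bool


@dataclass(frozen=True)
class PostprandialResult:
    per_meal: tuple[MealWindow, ...]
    pph: bool
    n_evaluable: int


@dataclass(frozen=True)
class Episode:
    time_pair: tuple[datetime, datetime]
    delta_sbp: float
    delta_dbp: float
    delta_hr: float
    condition: int  # 1 = SBP-triggered, 2 = DBP-triggered
    noncompensatory: bool


@dataclass(frozen=True)
class CompensationResult:
    episodes: tuple[Episode, ...]
    hrv_abnormal: bool
    n_episodes: int  # count of triggering reading pairs


@dataclass(frozen=True)
class ABPFeatureSummary:
    reversed: Optional[bool]
    pph: Optional[bool]
    hrv_abnormal: Optional[bool]
    abp_total: Optional[int]       # None when any trace component is unevaluable
    delta_oh: Optional[float]
    is_oh: Optional[bool]
    missing: dict = field(default_factory=dict)  # component -> reason


def _sorted_readings(trace: ABPTrace) -> list[BPReading]:
    return sorted(trace.readings, key=lambda r: r.time)


def classify_office_oh(
    records: Sequence[OfficeBPRecord], config: FeatureConfig = FeatureConfig()
) -> OfficeOHResult:
    """Classify orthostatic hypotension from office readings of one subject.

    The fall is computed on the mean of supine/sitting readings versus the
    mean of standing readings taken within ``oh_standing_max_min`` minutes
    of standing; thresholds are inclusive.  Per-standing-reading flags are
    also returned.  Raises :class:`UnevaluableError` when either posture
    group is empty.
    """
    baseline = [r for r in records if r.posture in ("supine", "sitting")]
    standing = [
        r for r in records
        if r.posture == "standing"
        and r.minutes_after_standing is not None
        and r.minutes_after_standing <= config.oh_standing_max_min
    ]
    if not baseline:
        raise UnevaluableError("no supine or sitting office reading")
    if not standing:
        raise UnevaluableError(
            f"no standing reading within {config.oh_standing_max_min:g} min"
        )
    base_sbp = sum(r.sbp for r in baseline) / len(baseline)
    base_dbp = sum(r.dbp for r in baseline) / len(baseline)
    stand_sbp = sum(r.sbp for r in standing) / len(standing)
    stand_dbp = sum(r.dbp for r in standing) / len(standing)
    delta_sbp = base_sbp - stand_sbp
    delta_dbp = base_dbp - stand_dbp
    flags = tuple(
        (base_sbp - r.sbp) >= config.oh_sbp_drop_mmhg
        or (base_dbp - r.dbp) >= config.oh_dbp_drop_mmhg
        for r in standing
    )
    is_oh = delta_sbp >= config.oh_sbp_drop_mmhg or delta_dbp >= config.oh_dbp_drop_mmhg
    return OfficeOHResult(
        is_oh=is_oh, delta_sbp=delta_sbp, delta_dbp=delta_dbp,
        per_reading_flags=flags, n_baseline=len(baseline), n_standing=len(standing),
    )


def _clock_in_window(t: time, start: time, end: time) -> bool:
    if start <= end:
        return start <= t < end
    return t >= start or t < end  # window crosses midnight


def segment_day_night(
    trace: ABPTrace,
    events: Iterable[JournalEvent] = (),
    config: FeatureConfig = FeatureConfig(),
) -> tuple[list[BPReading], list[BPReading], bool]:
    """Split a trace into (day, night) readings using journal sleep/wake times.

    Night is the half-open interval [sleep, wake); it may cross midnight.
    When the journal lacks sleep or wake events a default clock window
    (``default_sleep``-``default_wake``) is used and a warning is emitted.
    Returns ``(day, night, used_default_window)``.
    """
    if not trace.readings:
        raise UnevaluableError("empty trace")
    readings = _sorted_readings(trace)
    sleeps = sorted(e.time for e in events if e.kind == "sleep")
    wakes = sorted(e.time for e in events if e.kind == "wake")
    if sleeps and wakes:
        sleep_t = sleeps[0]
        later_wakes = [w for w in wakes if w > sleep_t]
        if not later_wakes:
            raise JournalInconsistencyError(
                f"trace {trace.subject_id}: wake time precedes sleep time"
            )
        wake_t = later_wakes[0]
        night = [r for r in readings if sleep_t <= r.time < wake_t]
        day = [r for r in readings if not (sleep_t <= r.time < wake_t)]
        return day, night, False
    warnings.warn(
        f"trace {trace.subject_id}: journal lacks sleep/wake events; using default "
        f"{config.default_sleep:%H:%M}-{config.default_wake:%H:%M} night window",
        stacklevel=2,
    )
    night = [
        r for r in readings
        if _clock_in_window(r.time.time(), config.default_sleep, config.default_wake)
    ]
    day = [
        r for r in readings
        if not _clock_in_window(r.time.time(), config.default_sleep, config.default_wake)
    ]
    return day, night, True


def _component_value(r: BPReading, component: str) -> float:
    if component == "systolic":
        return r.sbp
    if component == "diastolic":
        return r.dbp
    if component == "map":
        return (r.sbp + 2.0 * r.dbp) / 3.0
    raise ValueError(f"unknown BP component {component!r}")


def detect_circadian_reversal(
    trace: ABPTrace,
    events: Iterable[JournalEvent] = (),
    config: FeatureConfig = FeatureConfig(),
    component: Optional[str] = None,
) -> CircadianResult:
    """Reverse-dipping test: nocturnal mean >= daytime mean (inclusive).

    Means are computed on the configured BP component (default systolic;
    ``map`` = (SBP + 2 DBP)/3).  Each segment must contain at least
    ``min_segment_readings`` readings.
    """
    component = component or config.reversal_component
    day, night, used_default = segment_day_night(trace, events, config)
    if len(day) < config.min_segment_readings or len(night) < config.min_segment_readings:
        raise UnevaluableError(
            f"trace {trace.subject_id}: segment too small "
            f"(day {len(day)}, night {len(night)}, need >= {config.min_segment_readings})"
        )
    day_mean = sum(_component_value(r, component) for r in day) / len(day)
    night_mean = sum(_component_value(r, component) for r in night) / len(night)
    return CircadianResult(
        day_mean=day_mean, night_mean=night_mean, component=component,
        reversed=night_mean >= day_mean, n_day=len(day), n_night=len(night),
        used_default_window=used_default,
    )


def detect_postprandial_hypotension(
    trace: ABPTrace,
    events: Iterable[JournalEvent],
    config: FeatureConfig = FeatureConfig(),
) -> PostprandialResult:
    """Postprandial hypotension: SBP fall >= ``pph_drop_mmhg`` within
    ``pph_window_min`` minutes after any meal.

    Per meal, baseline is the last reading at or up to
    ``pph_baseline_max_min`` minutes before the meal; the drop is baseline
    SBP minus the minimum SBP over the half-open window (meal, meal+75].
    A meal with no baseline or no post-meal reading is unevaluable; the
    subject's flag is decided on the evaluable meals.  Raises
    :class:`UnevaluableError` when there are no meal events or no
    evaluable meals.
    """
    meals = sorted(e.time for e in events if e.kind == "meal")
    if not meals:
        raise UnevaluableError(f"trace {trace.subject_id}: no meal events")
    readings = _sorted_readings(trace)
    windows: list[MealWindow] = []
    for m in meals:
        pre = [
            r for r in readings
            if timedelta(0) <= m - r.time <= timedelta(minutes=config.pph_baseline_max_min)
        ]
        post = [
            r for r in readings
            if timedelta(0) < r.time - m <= timedelta(minutes=config.pph_window_min)
        ]
        if not pre or not post:
            windows.append(MealWindow(m, pre[-1].sbp if pre else None, None, None, False))
            continue
        baseline = pre[-1].sbp
        min_post = min(r.sbp for r in post)
        windows.append(MealWindow(m, baseline, min_post, baseline - min_post, True))
    evaluable = [w for w in windows if w.evaluable]
    if not evaluable:
        raise UnevaluableError(f"trace {trace.subject_id}: no evaluable meal window")
    pph = any(w.drop >= config.pph_drop_mmhg for w in evaluable)
    return PostprandialResult(per_meal=tuple(windows), pph=pph, n_evaluable=len(evaluable))


def detect_noncompensatory_hr(
    trace: ABPTrace, config: FeatureConfig = FeatureConfig()
) -> CompensationResult:
    """Non-compensatory heart-rate response over adjacent reading pairs.

    Condition 1 triggers when SBP falls by strictly more than
    ``hrv_sbp_drop_mmhg`` and is non-compensatory when the HR rise is below
    ``hrv_sbp_hr_rise_bpm``.  Condition 2 triggers when DBP falls by
    strictly more than ``hrv_dbp_drop_mmhg`` and is non-compensatory when
    HR does not rise (rise < ``hrv_dbp_hr_rise_bpm``).  The subject is
    abnormal when any episode is non-compensatory; a trace with no
    triggering pair is normal.
    """
    readings = _sorted_readings(trace)
    if len(readings) < 2:
        raise UnevaluableError(f"trace {trace.subject_id}: fewer than 2 readings")
    episodes: list[Episode] = []
    triggering_pairs = 0
    for r1, r2 in zip(readings, readings[1:]):
        d_sbp = r2.sbp - r1.sbp
        d_dbp = r2.dbp - r1.dbp
        d_hr = r2.hr - r1.hr
        cond1 = d_sbp < -config.hrv_sbp_drop_mmhg
        cond2 = d_dbp < -config.hrv_dbp_drop_mmhg
        if cond1 or cond2:
            triggering_pairs += 1
        if cond1:
            episodes.append(
                Episode((r1.time, r2.time), d_sbp, d_dbp, d_hr, 1,
                        d_hr < config.hrv_sbp_hr_rise_bpm)
            )
        if cond2:
            episodes.append(
                Episode((r1.time, r2.time), d_sbp, d_dbp, d_hr, 2,
                        d_hr < config.hrv_dbp_hr_rise_bpm)
            )
    abnormal = any(e.noncompensatory for e in episodes)
    return CompensationResult(
        episodes=tuple(episodes), hrv_abnormal=abnormal, n_episodes=triggering_pairs
    )


def summarize_abp(
    oh: Optional[OfficeOHResult],
    circadian: Optional[CircadianResult],
    postprandial: Optional[PostprandialResult],
    compensation: Optional[CompensationResult],
    missing: Optional[dict] = None,
) -> ABPFeatureSummary:
    """Combine classifier outputs; ``abp_total`` = reversal + PPH + HRV.

    Pass ``None`` for an unevaluable component (with its reason in
    ``missing``); ``abp_total`` is then undefined (``None``).
    """
    rev = circadian.reversed if circadian is not None else None
    pph = postprandial.pph if postprandial is not None else None
    hrv = compensation.hrv_abnormal if compensation is not None else None
    total = int(rev) + int(pph) + int(hrv) if None not in (rev, pph, hrv) else None
    return ABPFeatureSummary(
        reversed=rev, pph=pph, hrv_abnormal=hrv, abp_total=total,
        delta_oh=oh.delta_sbp if oh is not None else None,
        is_oh=oh.is_oh if oh is not None else None,
        missing=dict(missing or {}),
    )
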