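"""Synthetic 24-h ABP traces and cohorts with planted abnormalities.

The generator emulates the clinical recording protocol — cuff readings
every 15 min while awake and every 30 min while asleep, with journal
sleep/wake/meal events — and plants threshold-relevant structure:

* a circadian night offset (negative = normal dipping; >= 0 plants a
  reversed circadian pattern), applied with a short 3-reading ramp at the
  sleep and wake transitions so that a normal nocturnal dip never looks
  like an acute BP fall to the adjacent-pair heart-rate detector;
* a transient post-meal SBP dip of ``pph_drop`` mmHg (0 = none) lasting
  up to 60 min after each meal;
* one transient "stress dip" (default 35 mmHg, mid-afternoon, away from
  every meal window) present in every trace, so that whether the
  heart-rate response is compensatory is controlled purely by
  ``compensation_gain`` (beats/min of HR rise per mmHg of transient SBP
  fall): a high gain yields a compensated response, a near-zero gain a
  non-compensatory one;
* Gaussian measurement noise, independent across readings.  ``noise_sd``
  is the systolic standard deviation; diastolic and heart-rate noise use
  half of it, mirroring the roughly 2:1 systolic-to-diastolic variability
  of real 24-h recordings.  All values are rounded to integers as a cuff
  device would report them.

Cohorts are parameterized by the dysfunction prevalence and per-feature
conditional prevalences P(feature | dysfunction) and P(feature | none);
the implied exposure-outcome odds ratio is a derived quantity with a
closed-form consistency check.  Default values emulate the study cohort
this package is designed around (dysfunction 80.8%; reversal 81.9% with
OR 2.32, postprandial hypotension 75.5% with OR 4.83, heart-rate
variability 60.6% with OR 3.75, orthostatic hypotension 77.6% with OR 1).
"""

from __future__ import annotations

import math
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.optimize import brentq

from .errors import SpecificationError
from .io_formats import (
    ABPTrace,
    BPReading,
    JournalEvent,
    OfficeBPRecord,
    write_journal_csv,
    write_office_csv,
    write_trace_csv,
)

# planted-profile constants: margins >= 5 mmHg (or 5 bpm) beyond every threshold
REVERSED_NIGHT_OFFSET = 6.0    # mmHg; night mean ~5 above day mean
DIPPING_NIGHT_OFFSET = -14.0   # mmHg; normal dipper
PPH_PLANT_DROP = 30.0          # mmHg; 10 above the 20-mmHg rule
STRESS_DIP = 35.0              # mmHg; guarantees a >20-mmHg adjacent fall exists
COMPENSATED_GAIN = 0.5         # bpm/mmHg -> HR rise 17.5 bpm at the stress dip
NONCOMP_GAIN = 0.1             # bpm/mmHg -> HR rise 3.5 bpm (< 10)

OH_SUPINE = (152.0, 84.0)      # office means reported for the cohort
OH_STANDING = (115.0, 61.0)    # planted standing means when OH present (fall 37/23)
NO_OH_STANDING = (147.0, 81.0)  # fall 5/3 when OH absent

MAX_SEED = 2**31 - 1


def _round(x: float) -> float:
    return float(math.floor(x + 0.5))


class TraceProfile(BaseModel):
    """Ground-truth parameters for one synthetic 24-h recording."""

    base_day_sbp: float = 135.0
    base_day_dbp: float = 80.0
    night_offset: float = DIPPING_NIGHT_OFFSET   # >= 0 plants circadian reversal
    hr_base: float = 70.0
    night_hr_offset: float = -5.0
    compensation_gain: float = COMPENSATED_GAIN
    pph_drop: float = 0.0                        # >= 20 plants postprandial hypotension
    stress_dip: float = STRESS_DIP
    stress_dip_clock: time = time(16, 0)
    meal_clocks: tuple[time, ...] = (time(8, 0), time(12, 30), time(18, 0))
    sleep_clock: time = time(23, 0)
    wake_clock: time = time(6, 30)
    start: datetime = datetime(2016, 3, 1, 7, 0)
    duration_h: float = 24.0
    awake_cadence_min: int = 15
    asleep_cadence_min: int = 30
    noise_sd: float = Field(default=0.0, ge=0.0)
    seed: int = Field(default=0, ge=0, le=MAX_SEED)

    @property
    def plants_reversal(self) -> bool:
        return self.night_offset >= 0

    @property
    def plants_pph(self) -> bool:
        return self.pph_drop >= 20

    @property
    def plants_noncompensatory(self) -> bool:
        # non-compensatory iff the HR rise at the largest planted fall is < 10 bpm
        biggest = max(self.stress_dip, self.pph_drop)
        return biggest > 20 and self.compensation_gain * biggest < 10


def _on_or_after(anchor: datetime, clock: time) -> datetime:
    t = datetime.combine(anchor.date(), clock)
    while t < anchor:
        t += timedelta(days=1)
    return t


def simulate_trace(
    profile: TraceProfile, subject_id: str = "S"
) -> tuple[ABPTrace, list[JournalEvent]]:
    """Generate one 24-h trace plus its journal from a ground-truth profile.

    Pure function of the profile (including its seed): identical inputs
    yield bit-identical output.  Raises :class:`SpecificationError` when a
    meal falls outside the recording span.
    """
    rng = np.random.default_rng(profile.seed)
    start = profile.start
    end = start + timedelta(hours=profile.duration_h)
    sleep_t = _on_or_after(start, profile.sleep_clock)
    wake_t = _on_or_after(sleep_t + timedelta(minutes=1), profile.wake_clock)
    meals = [_on_or_after(start, c) for c in profile.meal_clocks]
    for m in meals:
        if not start <= m < end:
            raise SpecificationError(f"meal at {m.isoformat()} outside trace span")
    stress_t = _on_or_after(start, profile.stress_dip_clock)

    readings: list[BPReading] = []
    t = start
    night_idx = 0
    postwake_idx = 0
    while t < end:
        asleep = sleep_t <= t < wake_t
        if asleep:
            factor = min(1.0, 0.25 * (night_idx + 1))
            night_idx += 1
        elif t >= wake_t:
            factor = max(0.0, 0.75 - 0.25 * postwake_idx)
            postwake_idx += 1
        else:
            factor = 0.0

        dip = 0.0
        for m in meals:
            if m < t <= m + timedelta(minutes=60):
                dip += profile.pph_drop
        if stress_t <= t < stress_t + timedelta(minutes=profile.awake_cadence_min):
            dip += profile.stress_dip

        noise = rng.normal(0.0, 1.0, size=3) if profile.noise_sd > 0 else np.zeros(3)
        sbp = profile.base_day_sbp + factor * profile.night_offset - dip \
            + profile.noise_sd * noise[0]
        dbp = profile.base_day_dbp + 0.5 * factor * profile.night_offset - 0.25 * dip \
            + 0.5 * profile.noise_sd * noise[1]
        hr = profile.hr_base + factor * profile.night_hr_offset \
            + profile.compensation_gain * dip + 0.5 * profile.noise_sd * noise[2]
        readings.append(BPReading(t, _round(sbp), _round(dbp), _round(hr)))
        t += timedelta(minutes=profile.asleep_cadence_min if asleep
                       else profile.awake_cadence_min)

    events = [JournalEvent(subject_id, "sleep", sleep_t),
              JournalEvent(subject_id, "wake", wake_t)]
    events += [JournalEvent(subject_id, "meal", m) for m in meals]
    return ABPTrace(subject_id, tuple(readings)), events


def simulate_office_readings(
    subject_id: str,
    is_oh: bool,
    seed: int = 0,
    noise_sd: float = 0.0,
    when: datetime = datetime(2016, 3, 1, 9, 0),
) -> list[OfficeBPRecord]:
    """Two supine readings plus standing readings at 1 and 3 min.

    When ``is_oh`` the planted mean systolic fall is 37 mmHg (well beyond
    the 20-mmHg rule); otherwise 5 mmHg (diastolic 3, below the 10-mmHg
    rule).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    standing = OH_STANDING if is_oh else NO_OH_STANDING

    def noisy(v: float, sd: float) -> float:
        return _round(v + (sd * rng.normal() if sd > 0 else 0.0))

    records = [
        OfficeBPRecord(subject_id, "supine", noisy(OH_SUPINE[0], noise_sd),
                       noisy(OH_SUPINE[1], 0.5 * noise_sd), hr=noisy(70.0, 0.5 * noise_sd))
        for _ in range(2)
    ]
    for minutes in (1.0, 3.0):
        records.append(
            OfficeBPRecord(subject_id, "standing", noisy(standing[0], noise_sd),
                           noisy(standing[1], 0.5 * noise_sd),
                           minutes_after_standing=minutes, hr=noisy(78.0, 0.5 * noise_sd))
        )
    return records


class FeatureSpec(BaseModel):
    """Conditional prevalences of one binary ABP feature by dysfunction status."""

    p_given_dys: float = Field(ge=0.0, le=1.0)
    p_given_no: float = Field(ge=0.0, le=1.0)

    @property
    def implied_or(self) -> float:
        p1, p0 = self.p_given_dys, self.p_given_no
        if 0 in (p0, p1) or 1 in (p0, p1):
            return math.inf if p1 > p0 else (0.0 if p1 < p0 else 1.0)
        return (p1 / (1 - p1)) / (p0 / (1 - p0))

    def marginal(self, p_dysfunction: float) -> float:
        return p_dysfunction * self.p_given_dys + (1 - p_dysfunction) * self.p_given_no

    @classmethod
    def from_marginal_or(
        cls, marginal: float, odds_ratio: float, p_dysfunction: float
    ) -> "FeatureSpec":
        """Solve for (p|dys, p|no-dys) reproducing a marginal prevalence and OR.

        Raises :class:`SpecificationError` when no probability pair in
        [0, 1] is consistent with the request.
        """
        if not 0 < marginal < 1:
            raise SpecificationError(f"marginal prevalence {marginal} outside (0, 1)")
        if odds_ratio <= 0:
            raise SpecificationError(f"odds ratio must be positive, got {odds_ratio}")
        if not 0 < p_dysfunction < 1:
            raise SpecificationError(
                f"dysfunction prevalence {p_dysfunction} outside (0, 1)"
            )

        def p1_of(p0: float) -> float:
            return odds_ratio * p0 / (1 + p0 * (odds_ratio - 1))

        def f(p0: float) -> float:
            return p_dysfunction * p1_of(p0) + (1 - p_dysfunction) * p0 - marginal

        try:
            p0 = brentq(f, 1e-12, 1 - 1e-12, xtol=1e-14)
        except ValueError as exc:
            raise SpecificationError(
                f"no conditional prevalences in [0,1] give marginal {marginal} "
                f"with OR {odds_ratio}"
            ) from exc
        spec = cls(p_given_dys=p1_of(p0), p_given_no=p0)
        if not math.isclose(spec.implied_or, odds_ratio, rel_tol=1e-6):
            raise SpecificationError("implied odds ratio does not match target")
        return spec


def _default_features() -> Dict[str, FeatureSpec]:
    d = 0.808
    return {
        "reversed": FeatureSpec.from_marginal_or(0.819, 2.32, d),
        "pph": FeatureSpec.from_marginal_or(0.755, 4.83, d),
        "hrv_abnormal": FeatureSpec.from_marginal_or(0.606, 3.75, d),
        "is_oh": FeatureSpec.from_marginal_or(0.776, 1.0, d),
    }


FEATURE_NAMES = ("reversed", "pph", "hrv_abnormal", "is_oh")


class CohortSpec(BaseModel):
    """Cohort-level generator parameters (defaults emulate the study cohort)."""

    n: int = Field(default=94, ge=1)
    p_dysfunction: float = Field(default=0.808, gt=0.0, lt=1.0)
    features: Dict[str, FeatureSpec] = Field(default_factory=_default_features)
    cass_extra_mean: float = Field(default=1.35, ge=0.0)  # total | dys = 1 + Poisson
    age_mean: float = 71.0
    age_sd: float = 9.0
    p_male: float = Field(default=0.564, ge=0.0, le=1.0)
    comorbidity_rates: Dict[str, float] = Field(
        default_factory=lambda: {
            "htn": 0.383, "dm": 0.096, "cad": 0.181, "lipid": 0.128,
            "cancer": 0.223, "neuro": 0.149, "stroke": 0.085,
        }
    )
    noise_sd: float = Field(default=0.0, ge=0.0)
    seed: int = Field(default=0, ge=0, le=MAX_SEED)

    @field_validator("features")
    @classmethod
    def _has_all_features(cls, v):
        missing = set(FEATURE_NAMES) - set(v)
        if missing:
            raise ValueError(f"features missing {sorted(missing)}")
        return v


def _allocate_cass(rng: np.random.Generator, totals: np.ndarray) -> np.ndarray:
    """Split each CASS total into (sudomotor, cardiovagal, adrenergic)
    uniformly among deficit allocations respecting caps (3, 3, 4)."""
    out = np.zeros((len(totals), 3), dtype=int)
    caps = np.array([3, 3, 4])
    for i, t in enumerate(totals):
        if t > 0:
            out[i] = rng.multivariate_hypergeometric(caps, int(t))
    return out


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with planted exposure-outcome structure.

    Latent dysfunction is Bernoulli at ``p_dysfunction``; the CASS total
    given dysfunction is 1 + Poisson(``cass_extra_mean``) capped at 10
    (zero otherwise) and split into subscores; each ABP feature flag is
    Bernoulli at its conditional prevalence; covariates are drawn at the
    configured marginal rates.  The returned DataFrame also carries
    per-subject ``trace_seed`` / ``office_seed`` derived from the root
    seed, from which :func:`profile_for_subject` and
    :func:`materialize_subject` rebuild the raw data deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    dys = rng.random(n) < spec.p_dysfunction

    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:05d}" for i in range(n)],
        "dysfunction": dys.astype(int),
    })
    for name in FEATURE_NAMES:
        fs = spec.features[name]
        p = np.where(dys, fs.p_given_dys, fs.p_given_no)
        df[name] = (rng.random(n) < p).astype(int)

    extra = rng.poisson(spec.cass_extra_mean, size=n)
    totals = np.where(dys, np.minimum(1 + extra, 10), 0)
    sub = _allocate_cass(rng, totals)
    df["sudomotor"], df["cardiovagal"], df["adrenergic"] = sub[:, 0], sub[:, 1], sub[:, 2]
    df["cass_total"] = totals

    df["age"] = np.round(rng.normal(spec.age_mean, spec.age_sd, size=n))
    df["sex"] = np.where(rng.random(n) < spec.p_male, "M", "F")
    for flag, rate in spec.comorbidity_rates.items():
        df[flag] = (rng.random(n) < rate).astype(int)

    seeds = rng.integers(0, MAX_SEED, size=(n, 2))
    df["trace_seed"] = seeds[:, 0]
    df["office_seed"] = seeds[:, 1]
    return df


def profile_for_subject(row, noise_sd: float = 0.0) -> TraceProfile:
    """Trace profile whose planted features reproduce a cohort row's flags."""
    return TraceProfile(
        night_offset=REVERSED_NIGHT_OFFSET if row["reversed"] else DIPPING_NIGHT_OFFSET,
        pph_drop=PPH_PLANT_DROP if row["pph"] else 0.0,
        compensation_gain=NONCOMP_GAIN if row["hrv_abnormal"] else COMPENSATED_GAIN,
        noise_sd=noise_sd,
        seed=int(row["trace_seed"]),
    )


def materialize_subject(
    row, noise_sd: float = 0.0
) -> tuple[ABPTrace, list[JournalEvent], list[OfficeBPRecord]]:
    """Rebuild one subject's raw trace, journal and office readings."""
    sid = row["subject_id"]
    trace, events = simulate_trace(profile_for_subject(row, noise_sd), sid)
    office = simulate_office_readings(
        sid, bool(row["is_oh"]), seed=int(row["office_seed"]), noise_sd=noise_sd
    )
    return trace, events, office


GROUND_TRUTH_COLUMNS = [
    "subject_id", "dysfunction", "reversed", "pph", "hrv_abnormal", "is_oh",
]


def write_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Simulate a cohort and write the five pipeline CSVs plus ground truth.

    Files written: traces.csv, journal.csv, office.csv, cass.csv,
    covariates.csv and truth.csv (planted flags, for test harnesses).
    Returns the cohort table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = simulate_cohort(spec)

    traces, events, office = [], [], []
    for _, row in df.iterrows():
        t, e, o = materialize_subject(row, spec.noise_sd)
        traces.append(t)
        events.extend(e)
        office.extend(o)
    write_trace_csv(traces, out / "traces.csv")
    write_journal_csv(events, out / "journal.csv")
    write_office_csv(office, out / "office.csv")
    df[["subject_id", "sudomotor", "cardiovagal", "adrenergic"]].to_csv(
        out / "cass.csv", index=False
    )
    cov_cols = ["subject_id", "age", "sex"] + list(spec.comorbidity_rates)
    cov = df[cov_cols].copy()
    cov["age"] = cov["age"].astype(int)
    cov.to_csv(out / "covariates.csv", index=False)
    df[GROUND_TRUTH_COLUMNS].to_csv(out / "truth.csv", index=False)
    return df
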