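"""End-to-end study orchestration.

``extract_features_cohort`` turns raw per-subject inputs (24-h trace,
journal, office readings) into one feature row per subject;
``build_subject_table`` joins features with CASS scores and covariates;
``run_study`` computes the full association analysis: correlation
screening, unadjusted 2x2 odds ratios per feature, an adjusted logistic
model, and the ROC/AUC comparison of the six predictors
{is_oh, delta_oh, abp_total, reversed, pph, hrv_abnormal} against the
CASS-defined dysfunction outcome.

Missing-data policy is pairwise-complete: each statistic uses the
subjects complete for its own variables, and every table reports the n
actually used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import abp_features as feat
from . import stats
from .cass import score_cass
from .errors import (
    ABPError,
    ConvergenceError,
    SeparationError,
    UndefinedStatisticError,
    UnevaluableError,
)
from .io_formats import (
    ABPTrace,
    JournalEvent,
    OfficeBPRecord,
    PlausibilityBounds,
    filter_plausible,
)

logger = logging.getLogger(__name__)

PREDICTORS = ["is_oh", "delta_oh", "abp_total", "reversed", "pph", "hrv_abnormal"]
BINARY_FEATURES = ["reversed", "pph", "hrv_abnormal", "is_oh"]
OUTCOMES = ["dysfunction", "cass_total", "sudomotor_pos", "cardiovagal_pos", "adrenergic_pos"]

SUBGROUP_PRESETS = {
    "no_cancer": lambda df: df["cancer"] == 0,
    "diabetes_only": lambda df: df["dm"] == 1,
    "neurological": lambda df: df["neuro"] == 1,
    "non_neurological": lambda df: df["neuro"] == 0,
    "neuro_or_diabetes": (lambda df: (df["neuro"] == 1) | (df["dm"] == 1)),
}


class StudyConfig(BaseModel):
    """Analysis options for :func:`run_study`."""

    features: feat.FeatureConfig = Field(default_factory=feat.FeatureConfig)
    correlation_method: str = Field(default="pearson", pattern="^(pearson|spearman)$")
    # per-pair override, keyed "x:y"
    correlation_overrides: Dict[str, str] = Field(default_factory=dict)
    adjusted_covariates: List[str] = Field(
        default_factory=lambda: ["neuro", "dm", "is_oh", "reversed", "pph", "hrv_abnormal"]
    )
    subgroups: List[str] = Field(
        default_factory=lambda: ["no_cancer", "non_neurological", "neuro_or_diabetes"]
    )
    min_trace_readings: int = 10


def extract_features_cohort(
    traces: Iterable[ABPTrace],
    journal: Iterable[JournalEvent],
    office: Iterable[OfficeBPRecord],
    config: Optional[StudyConfig] = None,
    bounds: PlausibilityBounds = PlausibilityBounds(),
) -> pd.DataFrame:
    """Per-subject ABP feature summaries with unevaluable-component reasons.

    Returns one row per trace with columns ``subject_id, is_oh, delta_oh,
    reversed, pph, hrv_abnormal, abp_total, reasons``; unevaluable fields
    are NaN and their reasons joined in ``reasons``.
    """
    config = config or StudyConfig()
    fc = config.features
    journal_by: Dict[str, list] = {}
    for e in journal:
        journal_by.setdefault(e.subject_id, []).append(e)
    office_by: Dict[str, list] = {}
    for r in office:
        office_by.setdefault(r.subject_id, []).append(r)

    rows = []
    traces = list(traces)
    if not traces:
        logger.warning("empty cohort: no traces supplied")
    for trace in traces:
        missing: Dict[str, str] = {}
        events = journal_by.get(trace.subject_id, [])
        if not events:
            logger.warning("%s: no journal events; default night window will be used",
                           trace.subject_id)
        try:
            filtered = filter_plausible(trace, bounds, config.min_trace_readings)
            clean = filtered.trace
            for rej in filtered.rejections:
                logger.info("%s: rejected reading at %s (%s)",
                            trace.subject_id, rej.time.isoformat(), rej.reason)
        except ABPError as exc:
            clean = None
            for name in ("reversed", "pph", "hrv_abnormal"):
                missing[name] = str(exc)

        circ = pph_res = comp = None
        if clean is not None:
            for name, fn in (
                ("reversed", lambda: feat.detect_circadian_reversal(clean, events, fc)),
                ("pph", lambda: feat.detect_postprandial_hypotension(clean, events, fc)),
                ("hrv_abnormal", lambda: feat.detect_noncompensatory_hr(clean, fc)),
            ):
                try:
                    res = fn()
                except (UnevaluableError, ABPError) as exc:
                    missing[name] = str(exc)
                    res = None
                if name == "reversed":
                    circ = res
                elif name == "pph":
                    pph_res = res
                else:
                    comp = res

        oh = None
        try:
            oh = feat.classify_office_oh(office_by.get(trace.subject_id, []), fc)
        except UnevaluableError as exc:
            missing["is_oh"] = str(exc)

        s = feat.summarize_abp(oh, circ, pph_res, comp, missing)
        rows.append({
            "subject_id": trace.subject_id,
            "is_oh": np.nan if s.is_oh is None else float(s.is_oh),
            "delta_oh": np.nan if s.delta_oh is None else float(s.delta_oh),
            "reversed": np.nan if s.reversed is None else float(s.reversed),
            "pph": np.nan if s.pph is None else float(s.pph),
            "hrv_abnormal": np.nan if s.hrv_abnormal is None else float(s.hrv_abnormal),
            "abp_total": np.nan if s.abp_total is None else float(s.abp_total),
            "reasons": "; ".join(f"{k}: {v}" for k, v in sorted(missing.items())),
        })
    return pd.DataFrame(rows, columns=["subject_id", "is_oh", "delta_oh", "reversed",
                                       "pph", "hrv_abnormal", "abp_total", "reasons"])


def build_subject_table(
    features: pd.DataFrame,
    cass: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join features, CASS subscores and covariates into the analysis table.

    Adds ``cass_total``, the ``dysfunction`` dichotomy (total >= 1) and
    per-limb positivity flags, validating each subscore row through
    :func:`~abpauto.cass.score_cass`.
    """
    cass = cass.copy()
    scored = [
        score_cass(int(r.sudomotor), int(r.cardiovagal), int(r.adrenergic))
        for r in cass.itertuples()
    ]
    cass["cass_total"] = [s.total for s in scored]
    cass["dysfunction"] = [int(s.dysfunction) for s in scored]
    cass["sudomotor_pos"] = [int(s.limb_positive[0]) for s in scored]
    cass["cardiovagal_pos"] = [int(s.limb_positive[1]) for s in scored]
    cass["adrenergic_pos"] = [int(s.limb_positive[2]) for s in scored]
    df = features.merge(cass, on="subject_id", how="inner", validate="1:1")
    if covariates is not None:
        df = df.merge(covariates, on="subject_id", how="left", validate="1:1")
    return df


@dataclass
class StudyReport:
    """The full analysis output; ``to_json`` is byte-deterministic."""

    n: int
    characteristics: dict
    prevalence: dict
    correlations: list
    unadjusted_or: dict
    adjusted_model: dict
    auc_table: dict
    subgroups: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          allow_nan=False, default=_json_safe)


def _json_safe(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {o!r}")


def _clean_float(x) -> Optional[float]:
    x = float(x)
    return None if np.isnan(x) or np.isinf(x) else x


def _characteristics(df: pd.DataFrame) -> dict:
    out: dict = {"n": int(len(df))}
    if "age" in df:
        out["age_mean"] = _clean_float(df["age"].mean())
        out["age_sd"] = _clean_float(df["age"].std(ddof=1))
    if "sex" in df:
        out["male_pct"] = _clean_float(100.0 * (df["sex"] == "M").mean())
    for flag in ("htn", "dm", "cad", "lipid", "cancer", "neuro", "stroke"):
        if flag in df:
            out[f"{flag}_pct"] = _clean_float(100.0 * df[flag].mean())
    return out


def _prevalence(df: pd.DataFrame) -> dict:
    out = {}
    for col in ("reversed", "pph", "hrv_abnormal", "is_oh", "dysfunction",
                "sudomotor_pos", "cardiovagal_pos", "adrenergic_pos"):
        if col in df:
            vals = df[col].dropna()
            out[col + "_pct"] = _clean_float(100.0 * vals.mean()) if len(vals) else None
    return out


def _correlation_table(df: pd.DataFrame, config: StudyConfig) -> list:
    rows = []
    for x in PREDICTORS:
        for y in OUTCOMES:
            if x not in df or y not in df:
                continue
            method = config.correlation_overrides.get(
                f"{x}:{y}", config.correlation_method
            )
            fn = stats.spearman_correlation if method == "spearman" \
                else stats.pearson_correlation
            pair = df[[x, y]].dropna()
            entry = {"x": x, "y": y, "method": method, "n": int(len(pair))}
            try:
                res = fn(pair[x].to_numpy(), pair[y].to_numpy())
                entry.update(estimate=res.estimate, p=res.p)
            except UndefinedStatisticError as exc:
                entry.update(estimate=None, p=None, reason=str(exc))
            rows.append(entry)
    return rows


def _crosstab_cells(feature: pd.Series, outcome: pd.Series) -> tuple[int, int, int, int]:
    f = feature.astype(int)
    o = outcome.astype(int)
    a = int(((f == 1) & (o == 1)).sum())
    b = int(((f == 1) & (o == 0)).sum())
    c = int(((f == 0) & (o == 1)).sum())
    d = int(((f == 0) & (o == 0)).sum())
    return a, b, c, d


def _or_table(df: pd.DataFrame) -> dict:
    out = {}
    for name in BINARY_FEATURES:
        if name not in df:
            continue
        pair = df[[name, "dysfunction"]].dropna()
        a, b, c, d = _crosstab_cells(pair[name], pair["dysfunction"])
        entry: dict = {"n": int(len(pair)), "table": [a, b, c, d]}
        try:
            res = stats.odds_ratio_2x2(a, b, c, d)
            entry.update(
                or_estimate=res.or_estimate, ci_low=res.ci_low, ci_high=res.ci_high,
                p=res.p, correction_applied=res.correction_applied,
            )
        except UndefinedStatisticError as exc:
            entry.update(or_estimate=None, reason=str(exc))
        out[name] = entry
    return out


def _adjusted_model(df: pd.DataFrame, config: StudyConfig) -> dict:
    covs = [c for c in config.adjusted_covariates if c in df.columns]
    if not covs:
        return {"computed": False, "reason": "no adjusted covariates available"}
    sub = df[["dysfunction"] + covs].dropna()
    try:
        fit = stats.fit_logistic(
            sub["dysfunction"].to_numpy(), sub[covs].to_numpy(dtype=float), names=covs
        )
    except (SeparationError, ConvergenceError, UndefinedStatisticError) as exc:
        return {"computed": False, "reason": str(exc), "n": int(len(sub)),
                "covariates": covs}
    return {
        "computed": True,
        "n": fit.n,
        "n_iterations": fit.n_iterations,
        "intercept": fit.intercept,
        "effects": {
            e.name: {
                "coef": e.coef, "se": e.se,
                "or_estimate": e.odds_ratio.or_estimate,
                "ci_low": e.odds_ratio.ci_low, "ci_high": e.odds_ratio.ci_high,
                "p": e.odds_ratio.p,
            }
            for e in fit.effects
        },
    }


def _auc_table(df: pd.DataFrame) -> dict:
    out = {}
    for name in PREDICTORS:
        if name not in df:
            continue
        pair = df[[name, "dysfunction"]].dropna()
        entry: dict = {"n": int(len(pair))}
        try:
            res = stats.roc_auc(pair[name].to_numpy(), pair["dysfunction"].to_numpy())
            entry.update(auc=res.auc, ci_low=res.ci_low, ci_high=res.ci_high,
                         p=res.p, n_pos=res.n_pos, n_neg=res.n_neg)
        except UndefinedStatisticError as exc:
            entry.update(auc=None, reason=str(exc))
        out[name] = entry
    return out


def run_study(df: pd.DataFrame, config: Optional[StudyConfig] = None) -> StudyReport:
    """Run the complete association analysis on a joined subject table.

    The table must carry the feature columns, ``dysfunction``/``cass_total``
    and (optionally) covariates; see :func:`build_subject_table`.
    Sections that are not computable on the supplied data (single outcome
    class, separation) are marked as such rather than raising.
    """
    config = config or StudyConfig()
    if "dysfunction" not in df.columns:
        raise ValueError("subject table lacks the dysfunction outcome")
    subgroup_reports = {}
    for name in config.subgroups:
        if name not in SUBGROUP_PRESETS:
            raise ValueError(f"unknown subgroup preset {name!r}")
        try:
            mask = SUBGROUP_PRESETS[name](df)
        except KeyError:
            subgroup_reports[name] = {"computed": False,
                                      "reason": "covariate columns absent"}
            continue
        sub = df[mask]
        subgroup_reports[name] = {
            "computed": True,
            "n": int(len(sub)),
            "auc_table": _auc_table(sub),
            "unadjusted_or": _or_table(sub),
        }
    return StudyReport(
        n=int(len(df)),
        characteristics=_characteristics(df),
        prevalence=_prevalence(df),
        correlations=_correlation_table(df, config),
        unadjusted_or=_or_table(df),
        adjusted_model=_adjusted_model(df, config),
        auc_table=_auc_table(df),
        subgroups=subgroup_reports,
    )
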