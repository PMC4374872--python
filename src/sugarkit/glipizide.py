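"""Glipizide-challenge protocol rules and endpoint derivation.

The challenge gives 5 mg glipizide after an overnight fast and samples
glucose/insulin over 240 minutes.  Observation is stopped early for
neuroglycopenic symptoms, glucose <= 2.77 mmol/L with hypoglycemic
symptoms, or glucose < 2.50 mmol/L regardless of symptoms; participants
with fasting glucose below 4.44 mmol/L are not dosed at all.

Endpoints fall into three families: glucose-based (trough, deltas, area
over the curve), insulin-based (peak, deltas, area under the curve), and
the recovery period (trough-to-end deltas and the counter-regulatory
slope).  "Adjusted for baseline" has two operationalizations, both kept:
area endpoints subtract baseline x time, scalar endpoints are cohort-level
regression residuals on the baseline value.  The choice is recorded per
endpoint in the table's provenance metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import (
    FULL_DURATION,
    PROVENANCE_RESIDUAL,
    ChallengeSeries,
    EndpointTable,
    ParticipantRecord,
)

logger = logging.getLogger(__name__)

REASON_NOT_DOSED = "not_dosed"
REASON_NEURO = "neuroglycopenia"
REASON_SYMPTOMATIC = "symptomatic_le_2.77"
REASON_ABSOLUTE = "absolute_lt_2.50"
REASON_COMPLETED = "completed"

#: Endpoints the study flags as its primary ("selected") choices.
SELECTED_GLIPIZIDE_ENDPOINTS = (
    "glucose_trough_adj_baseline_glucose",
    "time_to_glucose_trough_adj_baseline_glucose",
    "insulin_peak_adj_baseline_insulin",
    "counter_reg_slope",
)


@dataclass
class StopRuleConfig:
    """Safety thresholds of the observation protocol, mmol/L."""

    dosing_gate: float = 4.44
    symptomatic_threshold: float = 2.77
    absolute_threshold: float = 2.50
    discharge_threshold: float = 4.44
    full_duration: int = FULL_DURATION

    def __post_init__(self) -> None:
        if not self.absolute_threshold < self.symptomatic_threshold < self.dosing_gate:
            raise ValueError(
                "stop rules require absolute < symptomatic < dosing gate"
            )


def apply_stop_rules(
    series: ChallengeSeries, rules: StopRuleConfig = StopRuleConfig()
) -> Tuple[ChallengeSeries, Optional[int], str]:
    """Scan a glipizide series through the termination rules.

    Returns ``(truncated_series, termination_time, reason)``.  Times after 0
    are scanned in order; the first time whose glucose/symptom state
    violates a rule becomes the termination time, and the series is
    truncated there (inclusive), which makes the engine idempotent.  Rule
    priority: neuroglycopenia, then symptomatic hypoglycemia, then the
    absolute glucose threshold.  A baseline below the dosing gate yields a
    ``not_dosed`` outcome with no truncation.
    """
    if series.glucose[0] < rules.dosing_gate:
        return series, None, REASON_NOT_DOSED
    hypo = series.hypo_flags()
    neuro = series.neuro_flags()
    for i in range(1, series.n_times):
        g = series.glucose[i]
        if neuro[i]:
            reason = REASON_NEURO
        elif g <= rules.symptomatic_threshold and hypo[i]:
            reason = REASON_SYMPTOMATIC
        elif g < rules.absolute_threshold:
            reason = REASON_ABSOLUTE
        else:
            continue
        t = int(series.times[i])
        return series.truncate(t), t, reason
    last = int(series.times[-1])
    term = rules.full_duration if last >= rules.full_duration else last
    return series, term, REASON_COMPLETED


def glucose_trough(series: ChallengeSeries) -> Tuple[float, int]:
    """Minimum glucose over times > 0 and the time it occurs (ties to the
    earliest time).  Baseline is excluded: it is the reference the trough is
    measured against."""
    if series.n_times < 2:
        raise ValueError("glucose trough needs at least 2 time points")
    post = series.glucose[1:]
    i = int(np.argmin(post))  # argmin returns the first minimum: earliest tie
    return float(post[i]), int(series.times[1:][i])


def insulin_peak(series: ChallengeSeries) -> Optional[Tuple[float, int]]:
    """Maximum insulin over times > 0 (ties to the earliest time), skipping
    gaps.  None when no post-baseline insulin was measured."""
    if series.insulin is None:
        return None
    post = series.insulin[1:]
    times = series.times[1:]
    ok = np.isfinite(post)
    if not ok.any():
        return None
    vals, ts = post[ok], times[ok]
    i = int(np.argmax(vals))
    return float(vals[i]), int(ts[i])


def auc_trapezoid(
    series: ChallengeSeries,
    analyte: str,
    t_start: int,
    t_end: int,
    baseline_adjust: bool = False,
) -> Optional[float]:
    """Composite-trapezoid area of ``analyte`` over [t_start, t_end].

    With ``baseline_adjust`` the time-0 value x (t_end - t_start) is
    subtracted, so a flat curve has area 0.  Returns None (endpoint absent,
    with a logged reason) when the range extends past a truncated series or
    the analyte has gaps inside the range; nothing is ever interpolated.
    """
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    arr = series.analyte(analyte)
    if arr is None:
        logger.debug("%s: no %s measurements", series.participant_id, analyte)
        return None
    times = series.times
    if t_start not in times or t_end not in times:
        logger.debug(
            "%s: [%d, %d] exceeds observed times for %s (terminated early?)",
            series.participant_id, t_start, t_end, analyte,
        )
        return None
    mask = (times >= t_start) & (times <= t_end)
    vals = arr[mask]
    if not np.all(np.isfinite(vals)):
        logger.debug(
            "%s: %s has gaps inside [%d, %d]",
            series.participant_id, analyte, t_start, t_end,
        )
        return None
    area = float(np.trapezoid(vals, times[mask]))
    if baseline_adjust:
        base = arr[0]
        if not np.isfinite(base):
            logger.debug("%s: no baseline %s", series.participant_id, analyte)
            return None
        area -= float(base) * (t_end - t_start)
    return area


def aoc_glucose(series: ChallengeSeries, t_end: int = 120) -> Optional[float]:
    """Area over the glucose curve: baseline glucose x t_end minus the
    unadjusted trapezoid area over [0, t_end].  Measures cumulative glucose
    decline below the fasting value."""
    auc = auc_trapezoid(series, "glucose", 0, t_end, baseline_adjust=False)
    if auc is None:
        return None
    return float(series.glucose[0]) * t_end - auc


def counter_reg_slope(
    series: ChallengeSeries,
    participant: ParticipantRecord,
    full_duration: int = FULL_DURATION,
) -> Optional[float]:
    """Endogenous recovery slope: (glucose at 240 - glucose at trough) /
    (240 - time of trough), mmol/L per minute.

    Absent for participants rescued with carbohydrate (the slope would
    reflect the rescue, not counter-regulatory hormones), for early
    terminators, and when the trough sits at 240 (zero denominator).
    """
    if participant.rescued:
        return None
    if participant.termination_time is not None and participant.termination_time < full_duration:
        return None
    trough_val, trough_t = glucose_trough(series)
    if trough_t >= full_duration:
        return None
    g_end = series.value_at("glucose", full_duration)
    if g_end is None:
        return None
    return (g_end - trough_val) / (full_duration - trough_t)


def residual_adjust(
    endpoint_values: pd.Series, covariate_values
) -> pd.Series:
    """Residuals of an OLS fit of endpoint on intercept + covariate(s).

    Participants missing either value are excluded pairwise; the result is
    aligned to the included participants.  Residuals have mean 0 and are
    orthogonal to the covariates by construction.
    """
    y = pd.Series(endpoint_values).astype(float)
    X = pd.DataFrame(covariate_values).astype(float)
    X = X.reindex(y.index)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if len(y) < 3:
        raise ValueError("residual adjustment needs at least 3 complete pairs")
    if (X.std(ddof=0) == 0).any():
        raise ValueError("covariate has zero variance; slope undefined")
    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    coef, *_ = np.linalg.lstsq(design, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - design @ coef
    return pd.Series(resid, index=y.index)


def derive_glipizide_endpoints(
    series: ChallengeSeries,
    participant: ParticipantRecord,
    rules: StopRuleConfig = StopRuleConfig(),
) -> dict:
    """All raw (non-residual) glipizide endpoints for one participant.

    The series is assumed already truncated by the termination engine.
    Endpoints not computable from a truncated series are absent (None) —
    values at uncollected times are never fabricated.
    """
    if not participant.received_glipizide:
        raise ValueError(f"{participant.participant_id} was not dosed with glipizide")
    g0 = float(series.glucose[0])
    trough_val, trough_t = glucose_trough(series)
    peak = insulin_peak(series)
    ep: dict = {
        "baseline_glucose": g0,
        "glucose_trough": trough_val,
        "time_to_glucose_trough": float(trough_t),
        "delta_glucose_0_to_trough": trough_val - g0,
        "rate_to_trough": (trough_val - g0) / trough_t,
    }

    def _delta_glucose(t: int) -> Optional[float]:
        v = series.value_at("glucose", t)
        return None if v is None else v - g0

    ep["delta_glucose_0_to_90"] = _delta_glucose(90)
    ep["delta_glucose_0_to_120"] = _delta_glucose(120)
    ep["glucose_at_120"] = series.value_at("glucose", 120)
    ep["aoc_glucose_0_120"] = aoc_glucose(series, t_end=120)

    base_ins = series.value_at("insulin", 0)
    ep["baseline_insulin"] = base_ins
    if peak is None:
        ep["insulin_peak"] = None
        ep["time_to_insulin_peak"] = None
        ep["delta_insulin_0_to_peak"] = None
        ep["rate_to_insulin_peak"] = None
    else:
        peak_val, peak_t = peak
        ep["insulin_peak"] = peak_val
        ep["time_to_insulin_peak"] = float(peak_t)
        ep["delta_insulin_0_to_peak"] = (
            None if base_ins is None else peak_val - base_ins
        )
        ep["rate_to_insulin_peak"] = (
            None if base_ins is None else (peak_val - base_ins) / peak_t
        )
    ins60 = series.value_at("insulin", 60)
    ep["insulin_at_60"] = ins60
    ep["delta_insulin_0_to_60"] = (
        None if (base_ins is None or ins60 is None) else ins60 - base_ins
    )
    ep["auc_insulin_0_240"] = auc_trapezoid(series, "insulin", 0, 240)
    ep["auc_insulin_0_240_baseline_adj"] = auc_trapezoid(
        series, "insulin", 0, 240, baseline_adjust=True
    )

    g240 = series.value_at("glucose", 240)
    g120 = series.value_at("glucose", 120)
    ep["delta_glucose_120_to_240"] = (
        None if (g120 is None or g240 is None) else g240 - g120
    )
    ep["delta_glucose_trough_to_240"] = None if g240 is None else g240 - trough_val
    ep["counter_reg_slope"] = counter_reg_slope(
        series, participant, full_duration=rules.full_duration
    )
    return ep


#: scalar endpoint -> baseline covariate used for residual adjustment
_RESIDUAL_PAIRS = (
    ("glucose_trough", "baseline_glucose"),
    ("time_to_glucose_trough", "baseline_glucose"),
    ("glucose_at_120", "baseline_glucose"),
    ("insulin_peak", "baseline_insulin"),
    ("insulin_at_60", "baseline_insulin"),
)


def derive_glipizide_cohort(
    series_list: Iterable[ChallengeSeries],
    participants: Iterable[ParticipantRecord],
    rules: StopRuleConfig = StopRuleConfig(),
) -> EndpointTable:
    """Endpoint table for a cohort: per-participant raw endpoints plus the
    cohort-level residual-adjusted variants (suffix
    ``_adj_baseline_glucose`` / ``_adj_baseline_insulin``)."""
    by_id = {p.participant_id: p for p in participants}
    rows = {}
    for s in series_list:
        if s.challenge != "glipizide":
            continue
        p = by_id.get(s.participant_id)
        if p is None or not p.received_glipizide:
            continue
        rows[s.participant_id] = derive_glipizide_endpoints(s, p, rules)
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.index.name = "participant_id"
    provenance = {}
    if not df.empty:
        for endpoint, covariate in _RESIDUAL_PAIRS:
            name = f"{endpoint}_adj_{covariate}"
            try:
                df[name] = residual_adjust(df[endpoint], df[covariate])
            except ValueError as exc:
                logger.warning("skipping %s: %s", name, exc)
                continue
            provenance[name] = PROVENANCE_RESIDUAL
    return EndpointTable(
        values=df, provenance=provenance, selected=SELECTED_GLIPIZIDE_ENDPOINTS
    )


def termination_summary(participants: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flow stratification of the glipizide challenge.

    One row per observed termination time among dosed participants, plus
    summary rows for early terminators and the challenged total, with
    percentages of the challenged count (one decimal, as the study flow
    sheet reports them)."""
    dosed = [p for p in participants if p.received_glipizide]
    n_challenged = len(dosed)
    if n_challenged == 0:
        raise ValueError("no dosed participants to summarize")
    counts = pd.Series(
        [p.termination_time for p in dosed], dtype=int
    ).value_counts().sort_index()
    rows = [
        {"stratum": f"terminated_{t}", "n": int(c),
         "pct": round(100.0 * c / n_challenged, 1)}
        for t, c in counts.items()
    ]
    n_early = sum(1 for p in dosed if p.early_terminator)
    rows.append(
        {"stratum": "early_terminators", "n": n_early,
         "pct": round(100.0 * n_early / n_challenged, 1)}
    )
    rows.append({"stratum": "challenged", "n": n_challenged, "pct": 100.0})
    return pd.DataFrame(rows).set_index("stratum")
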