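"""Metformin-response endpoints, insulin-sensitivity indices, and the
paired/group comparison procedure.

Visit 2 happens after a short metformin course (up to four 500 mg doses)
and includes a fasting draw followed by a two-hour 75-g OGTT; the fasting
sample is the OGTT's time 0.  Deltas are Visit 2 minus Visit 1 and exist
only when both visits' values exist — participants missing one side of a
paired comparison are excluded, never imputed.  Traits flagged as
non-normal (insulin, HOMA-IR, glucagon, proinsulin by default) are
compared on the natural-log scale, so their paired estimates are mean log
differences (exp of which is the geometric-mean ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .glipizide import auc_trapezoid, residual_adjust
from .types import (
    PROVENANCE_RESIDUAL,
    ChallengeSeries,
    EndpointTable,
    ParticipantRecord,
    VisitFasting,
)

logger = logging.getLogger(__name__)

#: HOMA-IR divisor with insulin kept in pmol/L; yields the study's
#: mmol*pmol/L^2 units and ~8 magnitudes.
HOMA_DIVISOR = 22.5

#: Unit conversions for the Matsuda index (its reference formula is in
#: mg/dL and uU/mL).  The insulin factor is assay-dependent; 6.0 pmol/L
#: per uU/mL is the conventional RIA value and is configurable.
GLUCOSE_MGDL_PER_MMOLL = 18.016
INSULIN_PMOLL_PER_UUML = 6.0

#: Traits compared on the log scale by default.
LOG_TRANSFORMED_TRAITS = ("insulin", "homa_ir", "glucagon", "proinsulin")

SELECTED_METFORMIN_ENDPOINTS = ("fg2_adj_fg1",)


def homa_ir(glucose: float, insulin: float) -> float:
    """Homeostasis-model insulin resistance: glucose [mmol/L] x insulin
    [pmol/L] / 22.5, in mmol*pmol/L^2."""
    if glucose <= 0 or insulin <= 0:
        raise ValueError("HOMA-IR requires positive glucose and insulin")
    return glucose * insulin / HOMA_DIVISOR


def matsuda_index(
    fasting_glucose: float,
    fasting_insulin: float,
    mean_glucose: float,
    mean_insulin: float,
    insulin_pmol_per_uu: float = INSULIN_PMOLL_PER_UUML,
) -> float:
    """Whole-body insulin-sensitivity index from fasting and mean OGTT
    glucose/insulin (means are unweighted over the schedule including
    time 0).  Inputs in mmol/L and pmol/L; converted internally to mg/dL
    and uU/mL."""
    for v in (fasting_glucose, fasting_insulin, mean_glucose, mean_insulin):
        if v <= 0:
            raise ValueError("Matsuda index requires positive inputs")
    fg = fasting_glucose * GLUCOSE_MGDL_PER_MMOLL
    mg = mean_glucose * GLUCOSE_MGDL_PER_MMOLL
    fi = fasting_insulin / insulin_pmol_per_uu
    mi = mean_insulin / insulin_pmol_per_uu
    return 10000.0 / math.sqrt(fg * fi * mg * mi)


def derive_metformin_endpoints(
    visit1: Optional[VisitFasting],
    visit2: Optional[VisitFasting],
    ogtt: Optional[ChallengeSeries],
    participant: ParticipantRecord,
) -> dict:
    """Raw (non-residual) metformin endpoints for one participant.

    Deltas require both visits' values (pairwise-complete rule); OGTT areas
    require the full [0, 120] window.  Absent endpoints are None.
    """
    ep: dict = {
        "fg1": None, "fg2": None, "fi1": None, "fi2": None,
        "homa1": None, "homa2": None,
        "delta_fg": None, "delta_fi": None, "delta_homa": None,
        "ogtt_glucose_auc": None, "ogtt_glucose_auc_baseline_adj": None,
        "ogtt_insulin_auc": None, "ogtt_insulin_auc_baseline_adj": None,
        "matsuda_index": None,
        "bmi": participant.bmi,
    }
    if visit1 is not None:
        ep["fg1"] = visit1.glucose
        ep["fi1"] = visit1.insulin
        if visit1.insulin is not None:
            ep["homa1"] = homa_ir(visit1.glucose, visit1.insulin)
    if visit2 is not None:
        ep["fg2"] = visit2.glucose
        ep["fi2"] = visit2.insulin
        if visit2.insulin is not None:
            ep["homa2"] = homa_ir(visit2.glucose, visit2.insulin)
    for delta, a, b in (
        ("delta_fg", "fg1", "fg2"),
        ("delta_fi", "fi1", "fi2"),
        ("delta_homa", "homa1", "homa2"),
    ):
        if ep[a] is not None and ep[b] is not None:
            ep[delta] = ep[b] - ep[a]
    if ogtt is not None:
        ep["ogtt_glucose_auc"] = auc_trapezoid(ogtt, "glucose", 0, 120)
        ep["ogtt_glucose_auc_baseline_adj"] = auc_trapezoid(
            ogtt, "glucose", 0, 120, baseline_adjust=True
        )
        ep["ogtt_insulin_auc"] = auc_trapezoid(ogtt, "insulin", 0, 120)
        ep["ogtt_insulin_auc_baseline_adj"] = auc_trapezoid(
            ogtt, "insulin", 0, 120, baseline_adjust=True
        )
        if ogtt.insulin is not None:
            ins = ogtt.insulin
            fin = np.isfinite(ins)
            fg, fi = float(ogtt.glucose[0]), float(ins[0]) if fin[0] else None
            if fi and fi > 0 and fin.any():
                mean_g = float(np.mean(ogtt.glucose))
                mean_i = float(np.mean(ins[fin]))
                if mean_i > 0:
                    ep["matsuda_index"] = matsuda_index(fg, fi, mean_g, mean_i)
    return ep


#: residual-adjusted endpoint -> (dependent, covariates)
_RESIDUAL_SPECS = (
    ("fg2_adj_fg1", "fg2", ("fg1",)),
    ("fg2_adj_fg1_bmi", "fg2", ("fg1", "bmi")),
    ("delta_fg_adj_bmi", "delta_fg", ("bmi",)),
    ("fi2_adj_fi1", "fi2", ("fi1",)),
    ("fi2_adj_fi1_bmi", "fi2", ("fi1", "bmi")),
    ("delta_fi_adj_bmi", "delta_fi", ("bmi",)),
    ("homa2_adj_homa1", "homa2", ("homa1",)),
    ("homa2_adj_homa1_bmi", "homa2", ("homa1", "bmi")),
    ("delta_homa_adj_bmi", "delta_homa", ("bmi",)),
)


def derive_metformin_cohort(
    visit_fasting: Iterable[VisitFasting],
    ogtt_series: Iterable[ChallengeSeries],
    participants: Iterable[ParticipantRecord],
) -> EndpointTable:
    """Cohort endpoint table: raw per-participant endpoints plus the
    cohort-level residual-adjusted variants (Visit-2 value adjusted for the
    Visit-1 value, optionally also BMI)."""
    v1 = {v.participant_id: v for v in visit_fasting if v.visit == 1}
    v2 = {v.participant_id: v for v in visit_fasting if v.visit == 2}
    ogtt = {s.participant_id: s for s in ogtt_series if s.challenge == "ogtt"}
    rows = {}
    for p in participants:
        pid = p.participant_id
        if pid not in v1 and pid not in v2 and pid not in ogtt:
            continue
        rows[pid] = derive_metformin_endpoints(
            v1.get(pid), v2.get(pid), ogtt.get(pid), p
        )
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    df.index.name = "participant_id"
    provenance = {}
    if not df.empty:
        for name, dep, covs in _RESIDUAL_SPECS:
            try:
                df[name] = residual_adjust(df[dep], df[list(covs)])
            except ValueError as exc:
                logger.warning("skipping %s: %s", name, exc)
                continue
            provenance[name] = PROVENANCE_RESIDUAL
    return EndpointTable(
        values=df, provenance=provenance, selected=SELECTED_METFORMIN_ENDPOINTS
    )


@dataclass
class ComparisonResult:
    """A paired or group contrast: mean difference, 95% CI, p, n."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    transform: str = "identity"
    kind: str = "paired"


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


def paired_comparison(
    values1, values2, transform: str = "identity", alpha: float = 0.05
) -> ComparisonResult:
    """Paired t-test of Visit-2 minus Visit-1 values.

    With the log transform the estimate is the mean paired log difference;
    exponentiating it gives the geometric-mean ratio.  Pairs with a missing
    value on either side are dropped.  Exactly identical vectors give a
    zero difference with a degenerate CI and a logged zero-variance warning.
    """
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must be aligned")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("paired comparison needs at least 2 complete pairs")
    d = _apply_transform(b, transform) - _apply_transform(a, transform)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        logger.warning("paired comparison: zero variance of differences")
        return ComparisonResult(mean, mean, mean, 1.0 if mean == 0 else 0.0,
                                n, transform, "paired")
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    t = mean / se
    p = 2 * stats.t.sf(abs(t), n - 1)
    return ComparisonResult(mean, mean - tcrit * se, mean + tcrit * se,
                            float(p), n, transform, "paired")


def group_comparison(
    values_a, values_b, transform: str = "identity", alpha: float = 0.05
) -> ComparisonResult:
    """Two-sample (pooled-variance) t-test of group a minus group b.

    Degenerate single-value groups yield the difference with NaN CI/p —
    useful for contrasting two printed group means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = _apply_transform(a[np.isfinite(a)], transform)
    b = _apply_transform(b[np.isfinite(b)], transform)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one non-missing value")
    diff = float(np.mean(a) - np.mean(b))
    n = int(a.size + b.size)
    if a.size < 2 or b.size < 2:
        return ComparisonResult(diff, math.nan, math.nan, math.nan, n,
                                transform, "group")
    df = n - 2
    sp2 = (
        (a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)
    ) / df
    if sp2 == 0.0:
        logger.warning("group comparison: zero pooled variance")
        return ComparisonResult(diff, diff, diff, 1.0 if diff == 0 else 0.0,
                                n, transform, "group")
    se = math.sqrt(sp2 * (1 / a.size + 1 / b.size))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    p = 2 * stats.t.sf(abs(diff) / se, df)
    return ComparisonResult(diff, diff - tcrit * se, diff + tcrit * se,
                            float(p), n, transform, "group")


def ancova_group_contrast(
    endpoint: pd.Series, covariate: pd.Series, group_flag: pd.Series,
    transform: str = "identity",
) -> ComparisonResult:
    """Group contrast of an endpoint after residual adjustment for a
    baseline covariate (e.g. OGTT glucose area adjusted for fasting
    glucose, contrasted by metformin exposure).  ``group_flag`` is boolean:
    True group minus False group."""
    resid = residual_adjust(endpoint, covariate)
    flag = pd.Series(group_flag).reindex(resid.index).astype(bool)
    return group_comparison(resid[flag], resid[~flag], transform=transform)


def comparison_report(results: dict) -> pd.DataFrame:
    """Tidy CSV-ready frame from {endpoint name -> ComparisonResult}."""
    rows = [
        {
            "endpoint": name, "kind": r.kind, "n": r.n, "estimate": r.estimate,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
            "transform": r.transform,
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(rows)
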