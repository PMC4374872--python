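"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the two-visit protocol: demographics drawn per
ethnic group (the enrolled cohort is ~67% non-Hispanic White, mean BMI in
the obese range), Hardy-Weinberg genotypes over a 34+14 SNP panel, Visit-1
fasting glucose with an additive per-allele genetic effect, a glipizide
glucose drop (trough modal at 120 min) and insulin rise (peak modal at 60
min) run through the hypoglycemia termination engine, and a Visit-2
fasting draw plus 75-g OGTT after a metformin course that lowers fasting
glucose by about 0.2 mmol/L in treated participants.

The glucose-drop amplitude distribution is calibrated so that about 30% of
dosed participants hit a stopping rule before 240 minutes, matching the
study's early-termination rate.  Trajectory shape is a scaled Gaussian
bump in time evaluated only at the schedule points (the protocol specifies
peak/trough timing, not a functional form), anchored so the curve passes
exactly through the fasting value at time 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .genetics import SnpPanel, grs, synthetic_panel
from .glipizide import StopRuleConfig, apply_stop_rules
from .types import (
    FULL_DURATION,
    GLIPIZIDE_SCHEDULE,
    OGTT_SCHEDULE,
    ChallengeSeries,
    ParticipantRecord,
    VisitFasting,
)

_ETHNICITY_N = {  # enrolled counts by group
    "non_hispanic_white": 436,
    "non_hispanic_black": 133,
    "hispanic": 45,
    "asian": 39,
}
_TOTAL = sum(_ETHNICITY_N.values())

DEFAULT_ETHNICITY_WEIGHTS = {k: v / _TOTAL for k, v in _ETHNICITY_N.items()}

#: per-ethnicity (mean, SD) of age in years and BMI in kg/m^2
DEFAULT_AGE_PARAMS = {
    "non_hispanic_white": (50.94, 16.38),
    "non_hispanic_black": (44.36, 12.49),
    "hispanic": (35.31, 12.79),
    "asian": (37.55, 14.38),
    "other": (47.73, 16.09),
}
DEFAULT_BMI_PARAMS = {
    "non_hispanic_white": (31.02, 7.25),
    "non_hispanic_black": (31.30, 7.14),
    "hispanic": (31.01, 7.41),
    "asian": (26.99, 5.07),
    "other": (30.83, 7.26),
}

#: metformin dose-compliance counts (0..4 doses) among Visit-2 attendees
_DOSE_N = {0: 26, 1: 6, 2: 10, 3: 21, 4: 546}
DEFAULT_DOSE_PROBS = {k: v / sum(_DOSE_N.values()) for k, v in _DOSE_N.items()}


def _default_allele_freqs(panel: SnpPanel) -> Dict[str, float]:
    """Effect-allele frequencies spread over (0.2, 0.85), centered so the
    expected glucose score is ~36/68 and the insulin score ~15/28 (the
    cohort's median scores)."""
    freqs: Dict[str, float] = {}
    for trait, center in (("fasting_glucose", 0.529), ("fasting_insulin", 0.536)):
        snps = panel.snps_for(trait)
        k = len(snps)
        spread = np.linspace(-0.28, 0.28, k) if k > 1 else np.zeros(1)
        for s, d in zip(snps, spread):
            freqs[s] = float(np.clip(center + d, 0.05, 0.95))
    return freqs


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the study conditions; amplitudes
    in mmol/L (glucose) or pmol/L (insulin), times in minutes."""

    n_participants: int = 653
    seed: int = 0

    ethnicity_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_WEIGHTS)
    )
    age_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    bmi_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BMI_PARAMS)
    )
    male_fraction: float = 0.475

    panel: SnpPanel = field(default_factory=synthetic_panel)
    allele_freqs: Optional[Dict[str, float]] = None  # default derived from panel

    # Visit-1 fasting biochemistry
    fg_mean: float = 5.27
    fg_sd: float = 1.06
    beta_fg_per_allele: float = 0.0256
    fi_log_median: float = math.log(36.12)
    fi_log_sd: float = 0.74
    beta_fi_per_allele: float = 0.078

    # glipizide response (calibrated: ~30% of dosed terminate early)
    glipizide_schedule: Tuple[int, ...] = GLIPIZIDE_SCHEDULE
    drop_amplitude_mean: float = 2.45
    drop_amplitude_sd: float = 1.05
    trough_time_probs: Dict[int, float] = field(
        default_factory=lambda: {60: 0.10, 90: 0.15, 120: 0.50, 180: 0.15, 240: 0.10}
    )
    kernel_width_min: float = 60.0
    glucose_noise_sd: float = 0.08
    insulin_peak_log_median: float = math.log(220.0)
    insulin_peak_log_sd: float = 0.6
    insulin_peak_time_probs: Dict[int, float] = field(
        default_factory=lambda: {30: 0.2, 60: 0.6, 90: 0.2}
    )
    symptom_prob_below_symptomatic: float = 0.35  # glucose <= 2.77
    symptom_prob_band: float = 0.08  # 2.77 < glucose <= 3.3
    symptom_band_upper: float = 3.3
    neuroglycopenia_prob: float = 0.02  # glucose <= 2.77
    rescue_all_early: bool = True

    # metformin / Visit 2
    dose_probs: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_PROBS)
    )
    attend_visit2_prob: float = 0.948
    metformin_effect: float = -0.23  # mean delta fasting glucose, treated
    visit2_fg_sd: float = 0.55
    metformin_fi_log_effect: float = -0.19
    visit2_fi_log_sd: float = 0.45

    # OGTT
    ogtt_schedule: Tuple[int, ...] = OGTT_SCHEDULE
    ogtt_excursion_mean: float = 3.5
    ogtt_excursion_sd: float = 1.2
    ogtt_peak_time_probs: Dict[int, float] = field(
        default_factory=lambda: {30: 0.25, 60: 0.50, 90: 0.25}
    )
    ogtt_insulin_log_median: float = math.log(300.0)
    ogtt_insulin_log_sd: float = 0.6

    stop_rules: StopRuleConfig = field(default_factory=StopRuleConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        w = sum(self.ethnicity_weights.values())
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError("ethnicity weights must sum to 1")
        if not math.isclose(sum(self.dose_probs.values()), 1.0, rel_tol=1e-6):
            raise ValueError("dose-compliance probabilities must sum to 1")
        if self.drop_amplitude_sd < 0 or self.fg_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.allele_freqs is None:
            self.allele_freqs = _default_allele_freqs(self.panel)
        for s, f in self.allele_freqs.items():
            if not 0 < f < 1:
                raise ValueError(f"allele frequency for {s} must be in (0, 1)")
        if (
            self.fg_sd == 0
            and self.beta_fg_per_allele == 0
            and self.fg_mean < self.stop_rules.dosing_gate
        ):
            raise ValueError(
                "degenerate config: every participant falls under the dosing "
                "gate (fg_sd = 0 and fg_mean below the gate)"
            )


class SimulatedCohort(NamedTuple):
    participants: List[ParticipantRecord]
    series: List[ChallengeSeries]
    visit_fasting: List[VisitFasting]
    genotypes: pd.DataFrame
    panel: SnpPanel


def _bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unimodal kernel on the schedule: Gaussian in time, re-anchored so it
    is exactly 0 at time 0 and 1 at its center."""
    k = np.exp(-((times - center) ** 2) / (2.0 * width**2))
    k0 = math.exp(-(center**2) / (2.0 * width**2))
    return (k - k0) / (1.0 - k0)


def _draw_categorical(rng, probs: Dict, size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()))
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), size=size, p=p)]


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Returns participants, challenge series (truncated by the termination
    engine), per-visit fasting records, a genotype matrix, and the panel.
    All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    panel = config.panel
    snps = list(panel.table["snp_id"])

    if n == 0:
        return SimulatedCohort(
            [], [], [],
            pd.DataFrame(columns=snps).rename_axis("participant_id"),
            panel,
        )

    pids = [f"S{i + 1:05d}" for i in range(n)]

    # demographics
    eth = _draw_categorical(rng, config.ethnicity_weights, n).astype(object)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = np.empty(n)
    bmi = np.empty(n)
    for group in set(eth):
        m = eth == group
        a_mu, a_sd = config.age_params[group]
        b_mu, b_sd = config.bmi_params[group]
        age[m] = np.clip(rng.normal(a_mu, a_sd, m.sum()), 18.0, 90.0)
        bmi[m] = np.clip(rng.normal(b_mu, b_sd, m.sum()), 16.0, 60.0)

    # genotypes: Hardy-Weinberg at the configured effect-allele frequencies
    geno = pd.DataFrame(
        {s: rng.binomial(2, config.allele_freqs[s], size=n) for s in snps},
        index=pd.Index(pids, name="participant_id"),
        dtype=float,
    )
    g_score = grs(geno, panel, "fasting_glucose")
    i_score = grs(geno, panel, "fasting_insulin")
    g_expect = 2.0 * sum(config.allele_freqs[s] for s in panel.snps_for("fasting_glucose"))
    i_expect = 2.0 * sum(config.allele_freqs[s] for s in panel.snps_for("fasting_insulin"))

    # Visit-1 fasting biochemistry with additive genetic effects
    fg1 = (
        config.fg_mean
        + config.beta_fg_per_allele * (g_score.to_numpy() - g_expect)
        + rng.normal(0.0, config.fg_sd, n)
    )
    # floor far below the distribution's support: positivity guard only,
    # so it cannot truncate the lower tail and bias configured effects
    fg1 = np.clip(fg1, 0.5, None)
    fi1 = np.exp(rng.normal(config.fi_log_median, config.fi_log_sd, n))
    fi1 = np.clip(
        fi1 + config.beta_fi_per_allele * (i_score.to_numpy() - i_expect), 1.0, None
    )

    dosed = fg1 >= config.stop_rules.dosing_gate

    # glipizide response trajectories for dosed participants
    glip_times = np.asarray(config.glipizide_schedule, dtype=int)
    amp = np.clip(
        rng.normal(config.drop_amplitude_mean, config.drop_amplitude_sd, n), 0.2, None
    )
    trough_t = _draw_categorical(rng, config.trough_time_probs, n).astype(float)
    ins_amp = np.exp(
        rng.normal(config.insulin_peak_log_median, config.insulin_peak_log_sd, n)
    )
    ins_peak_t = _draw_categorical(rng, config.insulin_peak_time_probs, n).astype(float)

    # metformin course and Visit 2
    doses = _draw_categorical(rng, config.dose_probs, n).astype(int)
    attended2 = rng.random(n) < config.attend_visit2_prob
    treated = doses >= 1
    fg2 = (
        fg1
        + config.metformin_effect * treated
        + rng.normal(0.0, config.visit2_fg_sd, n)
    )
    fg2 = np.clip(fg2, 0.5, None)
    fi2 = np.clip(
        fi1
        * np.exp(
            config.metformin_fi_log_effect * treated
            + rng.normal(0.0, config.visit2_fi_log_sd, n)
        ),
        1.0,
        None,
    )

    ogtt_times = np.asarray(config.ogtt_schedule, dtype=int)
    ogtt_amp = np.clip(
        rng.normal(config.ogtt_excursion_mean, config.ogtt_excursion_sd, n), 0.5, None
    )
    ogtt_peak_t = _draw_categorical(rng, config.ogtt_peak_time_probs, n).astype(float)
    ogtt_ins_amp = np.exp(
        rng.normal(config.ogtt_insulin_log_median, config.ogtt_insulin_log_sd, n)
    )

    participants: List[ParticipantRecord] = []
    series: List[ChallengeSeries] = []
    visit_fasting: List[VisitFasting] = []

    for i, pid in enumerate(pids):
        termination: Optional[int] = None
        rescued = False
        if dosed[i]:
            kernel = _bump(
                glip_times.astype(float), trough_t[i], config.kernel_width_min
            )
            glucose = fg1[i] - amp[i] * kernel
            noise = rng.normal(0.0, config.glucose_noise_sd, glip_times.size)
            noise[0] = 0.0  # time 0 is the fasting sample itself
            glucose = np.clip(glucose + noise, 1.5, None)
            ins_kernel = _bump(
                glip_times.astype(float), ins_peak_t[i], config.kernel_width_min
            )
            insulin = np.clip(
                fi1[i] + ins_amp[i] * ins_kernel
                + rng.normal(0.0, 5.0, glip_times.size),
                0.5,
                None,
            )
            # symptoms: Bernoulli given the glucose band
            p_sym = np.where(
                glucose <= config.stop_rules.symptomatic_threshold,
                config.symptom_prob_below_symptomatic,
                np.where(
                    glucose <= config.symptom_band_upper,
                    config.symptom_prob_band,
                    0.0,
                ),
            )
            hypo = rng.random(glip_times.size) < p_sym
            neuro = (
                glucose <= config.stop_rules.symptomatic_threshold
            ) & (rng.random(glip_times.size) < config.neuroglycopenia_prob)
            hypo[0] = neuro[0] = False
            full = ChallengeSeries(
                participant_id=pid,
                challenge="glipizide",
                times=glip_times,
                glucose=glucose,
                insulin=insulin,
                symptom_hypoglycemic=hypo,
                symptom_neuroglycopenic=neuro,
            )
            truncated, termination, reason = apply_stop_rules(full, config.stop_rules)
            series.append(truncated)
            rescued = bool(
                config.rescue_all_early
                and termination is not None
                and termination < FULL_DURATION
            )

        if attended2[i]:
            ogtt_kernel = _bump(
                ogtt_times.astype(float), ogtt_peak_t[i], config.kernel_width_min
            )
            o_glucose = np.clip(
                fg2[i] + ogtt_amp[i] * ogtt_kernel
                + np.concatenate(
                    ([0.0], rng.normal(0.0, config.glucose_noise_sd, ogtt_times.size - 1))
                ),
                1.5,
                None,
            )
            o_insulin = np.clip(
                fi2[i] + ogtt_ins_amp[i] * ogtt_kernel
                + rng.normal(0.0, 5.0, ogtt_times.size),
                0.5,
                None,
            )
            o_insulin[0] = fi2[i]
            series.append(
                ChallengeSeries(
                    participant_id=pid,
                    challenge="ogtt",
                    times=ogtt_times,
                    glucose=o_glucose,
                    insulin=o_insulin,
                )
            )

        participants.append(
            ParticipantRecord(
                participant_id=pid,
                age=float(age[i]),
                sex=str(sex[i]),
                ethnicity=str(eth[i]),
                bmi=float(bmi[i]),
                received_glipizide=bool(dosed[i]),
                termination_time=termination if dosed[i] else None,
                rescued=rescued,
                metformin_doses=int(doses[i]),
                attended_visit2=bool(attended2[i]),
            )
        )
        visit_fasting.append(
            VisitFasting(pid, visit=1, glucose=float(fg1[i]), insulin=float(fi1[i]))
        )
        if attended2[i]:
            visit_fasting.append(
                VisitFasting(pid, visit=2, glucose=float(fg2[i]), insulin=float(fi2[i]))
            )

    if not any(p.received_glipizide for p in participants):
        raise ValueError(
            "no participant cleared the dosing gate; check fg_mean/fg_sd "
            "against the gate"
        )
    return SimulatedCohort(participants, series, visit_fasting, geno, panel)


def simulate_null_phenotype(n: int, seed: int) -> np.ndarray:
    """Standard-normal phenotype independent of any genotype (null-model
    oracle input for calibration checks)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return np.random.default_rng(seed).standard_normal(n)
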