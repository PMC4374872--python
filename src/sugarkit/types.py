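"""Core domain types for the acute drug-challenge pipeline.

The study protocol has two visits: an acute sulfonylurea (glipizide)
challenge observed for up to 240 minutes under hypoglycemia stopping rules,
and, a week later, a 75-g oral glucose tolerance test (OGTT) taken after a
short metformin course.  These types carry the per-participant metadata,
the timed analyte series from either challenge, the per-visit fasting
measurements, and the derived phenotype (endpoint) tables shared by every
downstream stage.

Units follow the clinical-chemistry conventions used throughout the
package: time in minutes from the fasting sample, glucose in mmol/L,
insulin in pmol/L, glucagon in ng/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ETHNICITIES = (
    "non_hispanic_white",
    "non_hispanic_black",
    "hispanic",
    "asian",
    "other",
)
SEXES = ("male", "female")
CHALLENGES = ("glipizide", "ogtt")

#: Full observation length of the glipizide challenge, minutes.  A completed
#: challenge is encoded as termination_time == FULL_DURATION, so "early
#: terminator" is the pure predicate ``termination_time < FULL_DURATION``.
FULL_DURATION = 240

#: Default sampling schedules.  Schedules are data, not code: readers and
#: derivations accept any strictly increasing schedule starting at 0.  No
#: samples are drawn at 150 or 210 minutes.
GLIPIZIDE_SCHEDULE = (0, 30, 60, 90, 120, 180, 240)
OGTT_SCHEDULE = (0, 30, 60, 90, 120)


@dataclass
class ParticipantRecord:
    """One enrolled subject: demographics, dosing, and visit disposition.

    ``termination_time`` is present iff the participant received glipizide;
    completed challenges carry the sentinel ``FULL_DURATION`` (240).
    ``termination_override`` records a staff-discretion stop explicitly and
    is never inferred from the series.
    """

    participant_id: str
    age: float
    sex: str
    ethnicity: str
    bmi: float
    received_glipizide: bool = False
    termination_time: Optional[int] = None
    rescued: bool = False
    metformin_doses: int = 0
    attended_visit2: bool = False
    termination_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.participant_id}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"unknown ethnicity {self.ethnicity!r} for {self.participant_id}"
            )
        if not np.isfinite(self.age) or self.age < 0:
            raise ValueError(f"invalid age {self.age} for {self.participant_id}")
        if not np.isfinite(self.bmi) or self.bmi <= 0:
            raise ValueError(f"invalid BMI {self.bmi} for {self.participant_id}")
        if not 0 <= int(self.metformin_doses) <= 4:
            raise ValueError(
                f"metformin_doses must be in [0, 4], got {self.metformin_doses} "
                f"for {self.participant_id}"
            )
        self.metformin_doses = int(self.metformin_doses)
        if self.received_glipizide:
            if self.termination_time is None:
                raise ValueError(
                    f"{self.participant_id}: dosed participants need a "
                    "termination_time (240 = completed)"
                )
            self.termination_time = int(self.termination_time)
            if not 0 < self.termination_time <= FULL_DURATION:
                raise ValueError(
                    f"{self.participant_id}: termination_time "
                    f"{self.termination_time} outside (0, {FULL_DURATION}]"
                )
        elif self.termination_time is not None:
            raise ValueError(
                f"{self.participant_id}: termination_time set but "
                "received_glipizide is false"
            )
        if self.rescued:
            if self.termination_time is None or self.termination_time >= FULL_DURATION:
                raise ValueError(
                    f"{self.participant_id}: rescued participants must have "
                    f"termination_time < {FULL_DURATION}"
                )

    @property
    def early_terminator(self) -> bool:
        return (
            self.termination_time is not None
            and self.termination_time < FULL_DURATION
        )


def _as_float_array(values, name: str, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class ChallengeSeries:
    """Timed analyte measurements for one participant and one challenge.

    Glucose is required at every time point; insulin (and glucagon) may have
    gaps, recorded as NaN and never imputed.  Symptom flags default to "no
    symptoms recorded" when absent.
    """

    participant_id: str
    challenge: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: Optional[np.ndarray] = None
    glucagon: Optional[np.ndarray] = None
    symptom_hypoglycemic: Optional[np.ndarray] = None
    symptom_neuroglycopenic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.challenge not in CHALLENGES:
            raise ValueError(f"unknown challenge {self.challenge!r}")
        self.times = np.asarray(self.times, dtype=int)
        n = self.times.size
        if n < 1 or self.times[0] != 0:
            raise ValueError(
                f"{self.participant_id}/{self.challenge}: times must start at 0 "
                "(the fasting sample)"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"{self.participant_id}/{self.challenge}: times must be "
                "strictly increasing"
            )
        self.glucose = _as_float_array(self.glucose, "glucose", n)
        if not np.all(np.isfinite(self.glucose)) or np.any(self.glucose <= 0):
            raise ValueError(
                f"{self.participant_id}/{self.challenge}: glucose must be "
                "present and > 0 at every time"
            )
        if self.insulin is not None:
            self.insulin = _as_float_array(self.insulin, "insulin", n)
            if np.any(self.insulin[np.isfinite(self.insulin)] < 0):
                raise ValueError(
                    f"{self.participant_id}/{self.challenge}: insulin must be >= 0"
                )
        if self.glucagon is not None:
            self.glucagon = _as_float_array(self.glucagon, "glucagon", n)
        for attr in ("symptom_hypoglycemic", "symptom_neuroglycopenic"):
            flags = getattr(self, attr)
            if flags is not None:
                flags = np.asarray(flags, dtype=bool)
                if flags.shape != (n,):
                    raise ValueError(f"{attr} must have length {n}")
                setattr(self, attr, flags)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def analyte(self, name: str) -> Optional[np.ndarray]:
        if name not in ("glucose", "insulin", "glucagon"):
            raise KeyError(f"unknown analyte {name!r}")
        return getattr(self, name)

    def value_at(self, analyte: str, time: int) -> Optional[float]:
        """Value of ``analyte`` at minute ``time``; None when the time was
        not sampled or the value is missing.  Never interpolates."""
        arr = self.analyte(analyte)
        if arr is None:
            return None
        idx = np.flatnonzero(self.times == time)
        if idx.size == 0:
            return None
        v = float(arr[idx[0]])
        return v if np.isfinite(v) else None

    def hypo_flags(self) -> np.ndarray:
        if self.symptom_hypoglycemic is None:
            return np.zeros(self.n_times, dtype=bool)
        return self.symptom_hypoglycemic

    def neuro_flags(self) -> np.ndarray:
        if self.symptom_neuroglycopenic is None:
            return np.zeros(self.n_times, dtype=bool)
        return self.symptom_neuroglycopenic

    def truncate(self, time: int) -> "ChallengeSeries":
        """New series keeping samples at minutes <= ``time`` (inclusive)."""
        keep = self.times <= time
        take = lambda a: None if a is None else a[keep]
        return ChallengeSeries(
            participant_id=self.participant_id,
            challenge=self.challenge,
            times=self.times[keep],
            glucose=self.glucose[keep],
            insulin=take(self.insulin),
            glucagon=take(self.glucagon),
            symptom_hypoglycemic=take(self.symptom_hypoglycemic),
            symptom_neuroglycopenic=take(self.symptom_neuroglycopenic),
        )


@dataclass
class VisitFasting:
    """Fasting biochemistry at one visit (glucose required)."""

    participant_id: str
    visit: int
    glucose: float
    insulin: Optional[float] = None
    glucagon: Optional[float] = None
    proinsulin: Optional[float] = None

    def __post_init__(self) -> None:
        self.visit = int(self.visit)
        if self.visit not in (1, 2):
            raise ValueError(f"visit must be 1 or 2, got {self.visit}")
        if not np.isfinite(self.glucose) or self.glucose <= 0:
            raise ValueError(
                f"{self.participant_id} visit {self.visit}: glucose must be > 0"
            )


PROVENANCE_RAW = "raw"
PROVENANCE_RESIDUAL = "residual_adjusted"


@dataclass
class EndpointTable:
    """Per-participant derived phenotypes.

    ``values`` is a participants x endpoints frame (NaN = endpoint absent,
    never zero).  ``provenance`` tags each endpoint as ``raw`` or
    ``residual_adjusted``; ``selected`` lists the endpoints flagged as the
    study's primary choices.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    selected: tuple = ()

    def __post_init__(self) -> None:
        if self.values.index.name != "participant_id":
            self.values = self.values.rename_axis("participant_id")
        for col in self.values.columns:
            self.provenance.setdefault(col, PROVENANCE_RAW)

    @property
    def endpoints(self) -> list:
        return list(self.values.columns)

    def column(self, name: str) -> pd.Series:
        return self.values[name]
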