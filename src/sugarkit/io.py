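"""Readers and writers for the package's tabular formats.

All files are UTF-8 CSV (panel files TSV) with a decimal point; floats are
written with 12 significant digits so read-write-read round trips are
lossless at that precision.  Readers are permutation-invariant in row order
and never impute a missing value: gaps stay gaps.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .types import (
    CHALLENGES,
    ETHNICITIES,
    ChallengeSeries,
    EndpointTable,
    ParticipantRecord,
    VisitFasting,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

_PARTICIPANT_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "ethnicity",
    "bmi",
    "received_glipizide",
    "termination_time",
    "rescued",
    "metformin_doses",
    "attended_visit2",
)

_ANALYTE_NAMES = (
    "glucose",
    "insulin",
    "glucagon",
    "symptom_hypoglycemic",
    "symptom_neuroglycopenic",
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        s = ""
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse {column}={value!r} as a flag")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {', '.join(missing)}")


def read_participants(path) -> List[ParticipantRecord]:
    """Read a participant table (one row per enrolled subject).

    Unknown ethnicity strings map to ``other`` with a logged warning;
    non-numeric age/BMI is a hard error naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _PARTICIPANT_COLUMNS, "participants file")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after the header
        try:
            age = float(row["age"])
            bmi = float(row["bmi"])
        except ValueError as exc:
            raise ValueError(f"row {rownum}: non-numeric age or bmi") from exc
        ethnicity = row["ethnicity"].strip()
        if ethnicity not in ETHNICITIES:
            logger.warning(
                "row %d: unknown ethnicity %r mapped to 'other'", rownum, ethnicity
            )
            ethnicity = "other"
        term = row["termination_time"].strip()
        termination_time = int(float(term)) if term else None
        records.append(
            ParticipantRecord(
                participant_id=row["participant_id"].strip(),
                age=age,
                sex=row["sex"].strip().lower(),
                ethnicity=ethnicity,
                bmi=bmi,
                received_glipizide=_parse_bool(
                    row["received_glipizide"], "received_glipizide", rownum
                ),
                termination_time=termination_time,
                rescued=_parse_bool(row["rescued"], "rescued", rownum),
                metformin_doses=int(float(row["metformin_doses"])),
                attended_visit2=_parse_bool(
                    row["attended_visit2"], "attended_visit2", rownum
                ),
            )
        )
    return records


def write_participants(records: Iterable[ParticipantRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "age": r.age,
                "sex": r.sex,
                "ethnicity": r.ethnicity,
                "bmi": r.bmi,
                "received_glipizide": r.received_glipizide,
                "termination_time": "" if r.termination_time is None else r.termination_time,
                "rescued": r.rescued,
                "metformin_doses": r.metformin_doses,
                "attended_visit2": r.attended_visit2,
            }
        )
    pd.DataFrame(rows, columns=list(_PARTICIPANT_COLUMNS)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_series(path) -> List[ChallengeSeries]:
    """Read long-format challenge series.

    Expected columns: participant_id, challenge, time_min, analyte, value.
    One :class:`ChallengeSeries` is built per (participant, challenge) with
    times sorted; duplicate (participant, challenge, time, analyte) rows,
    negative times, and unknown analyte names are hard errors.
    """
    df = pd.read_csv(path)
    _require_columns(
        df, ("participant_id", "challenge", "time_min", "analyte", "value"), "series file"
    )
    if (df["time_min"] < 0).any():
        raise ValueError("series file: negative time_min")
    unknown = set(df["analyte"]) - set(_ANALYTE_NAMES)
    if unknown:
        raise ValueError(f"series file: unknown analyte name(s) {sorted(unknown)}")
    bad = set(df["challenge"]) - set(CHALLENGES)
    if bad:
        raise ValueError(f"series file: unknown challenge(s) {sorted(bad)}")
    dup = df.duplicated(
        subset=["participant_id", "challenge", "time_min", "analyte"], keep=False
    )
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "series file: duplicate measurement for "
            f"({first['participant_id']}, {first['challenge']}, "
            f"{first['time_min']}, {first['analyte']})"
        )

    out = []
    # sorted keys -> deterministic output order regardless of row order
    for (pid, challenge), grp in sorted(
        df.groupby(["participant_id", "challenge"], sort=False),
        key=lambda kv: (str(kv[0][0]), kv[0][1]),
    ):
        times = np.unique(grp["time_min"].to_numpy(dtype=int))
        kwargs = {}
        for analyte in ("glucose", "insulin", "glucagon"):
            sub = grp[grp["analyte"] == analyte]
            if sub.empty:
                continue
            arr = np.full(times.size, np.nan)
            idx = np.searchsorted(times, sub["time_min"].to_numpy(dtype=int))
            arr[idx] = sub["value"].to_numpy(dtype=float)
            kwargs[analyte] = arr
        for flag in ("symptom_hypoglycemic", "symptom_neuroglycopenic"):
            sub = grp[grp["analyte"] == flag]
            if sub.empty:
                continue
            arr = np.zeros(times.size, dtype=bool)
            idx = np.searchsorted(times, sub["time_min"].to_numpy(dtype=int))
            arr[idx] = sub["value"].to_numpy(dtype=float) != 0
            kwargs[flag] = arr
        if "glucose" not in kwargs or np.any(~np.isfinite(kwargs["glucose"])):
            raise ValueError(
                f"series file: ({pid}, {challenge}) lacks glucose at some times"
            )
        out.append(
            ChallengeSeries(
                participant_id=str(pid), challenge=challenge, times=times, **kwargs
            )
        )
    return out


def write_series(series: Iterable[ChallengeSeries], path) -> None:
    rows = []
    for s in series:
        for analyte in ("glucose", "insulin", "glucagon"):
            arr = s.analyte(analyte)
            if arr is None:
                continue
            for t, v in zip(s.times, arr):
                if np.isfinite(v):
                    rows.append((s.participant_id, s.challenge, int(t), analyte, v))
        for flag, arr in (
            ("symptom_hypoglycemic", s.symptom_hypoglycemic),
            ("symptom_neuroglycopenic", s.symptom_neuroglycopenic),
        ):
            if arr is None:
                continue
            for t, v in zip(s.times, arr):
                if v:
                    rows.append((s.participant_id, s.challenge, int(t), flag, 1))
    pd.DataFrame(
        rows, columns=["participant_id", "challenge", "time_min", "analyte", "value"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_visit_fasting(path) -> List[VisitFasting]:
    df = pd.read_csv(path)
    _require_columns(df, ("participant_id", "visit", "glucose"), "visit fasting file")
    if df.duplicated(subset=["participant_id", "visit"]).any():
        raise ValueError("visit fasting file: duplicate (participant, visit)")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    return [
        VisitFasting(
            participant_id=str(row["participant_id"]),
            visit=int(row["visit"]),
            glucose=float(row["glucose"]),
            insulin=_opt(row, "insulin"),
            glucagon=_opt(row, "glucagon"),
            proinsulin=_opt(row, "proinsulin"),
        )
        for _, row in df.iterrows()
    ]


def write_visit_fasting(records: Iterable[VisitFasting], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "visit": r.visit,
            "glucose": r.glucose,
            "insulin": np.nan if r.insulin is None else r.insulin,
            "glucagon": np.nan if r.glucagon is None else r.glucagon,
            "proinsulin": np.nan if r.proinsulin is None else r.proinsulin,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["participant_id", "visit", "glucose", "insulin", "glucagon", "proinsulin"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_genotypes(path) -> pd.DataFrame:
    """Read a participants x SNPs matrix of effect-allele counts.

    Cells are 0/1/2 or empty (missing call, kept as NaN)."""
    df = pd.read_csv(path, index_col="participant_id")
    df.index = df.index.astype(str)
    mat = df.astype(float)
    vals = mat.to_numpy()
    finite = np.isfinite(vals)
    ok = np.isin(vals[finite], (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("genotype matrix: cells must be 0, 1, 2 or empty")
    return mat


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.rename_axis("participant_id").to_csv(path, float_format="%g")


def read_panel(path) -> pd.DataFrame:
    """Read a SNP panel TSV with columns snp_id, effect_allele, trait."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("snp_id", "effect_allele", "trait"), "panel file")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def write_endpoints(table: EndpointTable, path) -> None:
    """Write a wide endpoint table, one row per participant.

    Absent endpoints become empty cells (never 0).  Endpoint names that
    collide case-insensitively are rejected."""
    if table.values.empty:
        raise ValueError("refusing to write an empty endpoint table")
    lowered = [c.lower() for c in table.values.columns]
    if len(set(lowered)) != len(lowered):
        raise ValueError("endpoint names collide when case is ignored")
    table.values.to_csv(path, float_format=_FLOAT_FMT, na_rep="")


def read_endpoints(path) -> EndpointTable:
    df = pd.read_csv(path, index_col="participant_id")
    df.index = df.index.astype(str)
    return EndpointTable(values=df.astype(float))
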