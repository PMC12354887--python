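"""Coded-event tables, phecode mapping, and phenotype-onset derivation.

The shared data backbone: every downstream stage consumes the long-format
event table defined here (one row per coded event, age-stamped in days since
birth) or a table derived from it.

Conventions
-----------
* 1 year = 365.25 days; the age-year index of an event is
  ``floor(age_days / 365.25)``.  All year binning in the package goes through
  :func:`year_index` so sentences, onsets and survival share one clock.
* Phenotypes are called from diagnosis codes only: a single mapped diagnosis
  event qualifies a patient for the phecode, and onset is the earliest such
  event.  Procedure codes (CPT-4) participate in sequences and vocabularies
  but never in phenotype calls.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

CODE_SYSTEMS = ("ICD9", "ICD10", "CPT4")
DIAGNOSIS_SYSTEMS = ("ICD9", "ICD10")

EVENT_COLUMNS = ["patient_id", "age_days", "code", "code_system"]


class ValidationError(ValueError):
    """An event table or map violates a structural invariant."""


def year_index(age_days) -> np.ndarray:
    """Age-year bin of an event: floor(age_days / 365.25)."""
    return np.floor(np.asarray(age_days) / DAYS_PER_YEAR).astype(int)


def week_index(age_days) -> np.ndarray:
    """Age-week bin of an event: floor(age_days / 7)."""
    return (np.asarray(age_days) // 7).astype(int)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    if len(events):
        if (events["age_days"] < 0).any():
            bad = int((events["age_days"] < 0).sum())
            raise ValidationError(f"{bad} events with negative age_days")
        unknown = set(events["code_system"].unique()) - set(CODE_SYSTEMS)
        if unknown:
            raise ValidationError(f"unknown code_system values: {sorted(unknown)}")
        if (events["code"].astype(str).str.len() == 0).any():
            raise ValidationError("empty code token")
    return events


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    return events.sort_values(
        ["patient_id", "age_days", "code"], kind="mergesort"
    ).reset_index(drop=True)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event CSV, validate it, and return it sorted by (patient, age)."""
    try:
        events = pd.read_csv(path, dtype={"patient_id": str, "code": str,
                                          "code_system": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed event file {path}: {exc}") from exc
    if not len(events):
        return pd.DataFrame(columns=EVENT_COLUMNS)
    events["age_days"] = pd.to_numeric(events["age_days"], errors="raise").astype(int)
    return sort_events(validate_events(events[EVENT_COLUMNS]))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)[EVENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phecode map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhecodeMap:
    """Diagnosis code -> phecode mapping plus phecode -> disease-class labels.

    The mapping is a function: each diagnosis code maps to exactly one
    phecode.  Procedure codes are absent from the domain.
    """

    code_to_phecode: dict[str, str]
    phecode_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.code_to_phecode:
            raise ValidationError("empty phecode map")

    @property
    def phecodes(self) -> list[str]:
        return sorted(set(self.code_to_phecode.values()))

    def disease_class(self, phecode: str) -> str:
        return self.phecode_class.get(phecode, "unclassified")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"code": c, "phecode": p, "disease_class": self.disease_class(p)}
            for c, p in sorted(self.code_to_phecode.items())
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhecodeMap":
        df = pd.read_csv(path, dtype=str)
        dup = df["code"].duplicated()
        if dup.any():
            raise ValidationError(
                f"phecode map assigns multiple phecodes to codes: "
                f"{sorted(df.loc[dup, 'code'].unique())[:5]}"
            )
        return cls(
            code_to_phecode=dict(zip(df["code"], df["phecode"])),
            phecode_class=dict(zip(df["phecode"], df["disease_class"])),
        )


def map_to_phecodes(events: pd.DataFrame, pmap: PhecodeMap) -> pd.DataFrame:
    """One row per mapped diagnosis event: (patient_id, phecode, age_days).

    A single occurrence qualifies a patient for the phenotype; procedure
    codes and unmapped diagnosis codes are dropped.
    """
    dx = events[events["code_system"].isin(DIAGNOSIS_SYSTEMS)]
    phe = dx["code"].map(pmap.code_to_phecode)
    out = pd.DataFrame({
        "patient_id": dx["patient_id"],
        "phecode": phe,
        "age_days": dx["age_days"],
    }).dropna(subset=["phecode"])
    return out.sort_values(["patient_id", "phecode", "age_days"],
                           kind="mergesort").reset_index(drop=True)


def compute_onset_table(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Earliest qualifying event per (patient, phecode), in days and floor-years."""
    if not len(occurrences):
        return pd.DataFrame(columns=["patient_id", "phecode",
                                     "onset_age_days", "onset_age_years"])
    onset = (occurrences.groupby(["patient_id", "phecode"], sort=True)["age_days"]
             .min().reset_index().rename(columns={"age_days": "onset_age_days"}))
    onset["onset_age_years"] = year_index(onset["onset_age_days"])
    return onset


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if len(df) and (df["time_years"] < 0).any():
        raise ValidationError("negative survival time")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df[["patient_id", "time_years", "event"]].to_csv(path, index=False)


def events_digest(events: pd.DataFrame) -> str:
    """Stable content hash of an event table (used by the pipeline manifest)."""
    import hashlib

    buf = io.StringIO()
    sort_events(events).to_csv(buf, index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
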