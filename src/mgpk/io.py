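"""NONMEM-style event dataset: container, validation, CSV round trip.

The single interchange object between all stages is :class:`EventDataset`, a
thin wrapper around a pandas DataFrame with one row per dose or observation
event:

======== =======================================================
column   meaning
======== =======================================================
ID       subject identifier
TIME     hours since study start (t = 0 at first dose)
EVID     1 = dose event, 0 = observation
AMT      dose amount in labeled grams of MgSO4 (dose rows only)
DUR      infusion duration in hours (dose rows only)
DV       observed serum magnesium (mg/L elemental Mg internally)
MDV      1 if DV is missing
BASE     subject's endogenous baseline magnesium (mg/L)
...      covariate columns (CCR, BMI, furosemide, ...)
======== =======================================================

On disk DV/BASE may be stored in mmol/L (the clinical reporting unit);
:func:`read_dataset` and :func:`write_dataset` convert according to the
``dv_unit`` argument.  Internally everything is mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_core import DoseEvent, Regimen
from .units import DEFAULT_SALT_FACTOR, MG_PER_MMOL

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV")

#: columns that are part of the event structure rather than covariates
CORE_COLUMNS = set(REQUIRED_COLUMNS) | {"BASE"}


class DatasetValidationError(ValueError):
    """Raised with a per-rule list of offending row numbers."""


@dataclass
class EventDataset:
    df: pd.DataFrame
    salt_factor: float = DEFAULT_SALT_FACTOR

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    # -- accessors -----------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def n_obs(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    def covariate_table(self) -> pd.DataFrame:
        """One row per subject with covariates (and BASE if present)."""
        cols = self.covariate_columns + (["BASE"] if "BASE" in self.df.columns else [])
        return self.df.groupby("ID", sort=False)[cols].first()

    def subject_regimen(self, subject_id) -> Regimen:
        rows = self.doses[self.doses["ID"] == subject_id]
        events = tuple(
            DoseEvent(
                start_time=float(r.TIME),
                amount=float(r.AMT) * self.salt_factor,
                duration=float(r.DUR),
            )
            for r in rows.itertuples()
        )
        return Regimen(events=events, salt_factor=self.salt_factor)

    def subset_subjects(self, ids, relabel: bool = True) -> "EventDataset":
        """Rows of the given subjects, in the given order (with repetition —
        this is what the bootstrap uses). ``relabel`` assigns fresh IDs so
        repeated draws of one subject become distinct subjects."""
        parts = []
        for new_id, sid in enumerate(ids):
            block = self.df[self.df["ID"] == sid].copy()
            if relabel:
                block["ID"] = new_id
            parts.append(block)
        return EventDataset(pd.concat(parts, ignore_index=True), self.salt_factor)

    # -- validation ----------------------------------------------------
    def validate(self, for_estimation: bool = True) -> "EventDataset":
        df = self.df
        problems: list[str] = []

        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing required columns: {missing}")

        def rows_where(mask) -> list[int]:
            return list(np.flatnonzero(np.asarray(mask)))

        bad = rows_where(df["TIME"] < 0)
        if bad:
            problems.append(f"negative TIME at rows {bad}")
        bad = rows_where(~df["EVID"].isin([0, 1]))
        if bad:
            problems.append(f"EVID not in {{0,1}} at rows {bad}")

        doses = df["EVID"] == 1
        bad = rows_where(doses & ~(df["AMT"] > 0))
        if bad:
            problems.append(f"dose rows need AMT > 0 at rows {bad}")
        bad = rows_where(doses & ~(df["DUR"] > 0))
        if bad:
            problems.append(f"dose rows need DUR > 0 at rows {bad}")
        bad = rows_where(doses & df["DV"].notna())
        if bad:
            problems.append(f"dose rows must not carry DV at rows {bad}")

        obs = df["EVID"] == 0
        bad = rows_where(obs & (df["DV"].isna() & (df.get("MDV", 0) == 0)))
        if bad:
            problems.append(f"observation rows need DV (or MDV=1) at rows {bad}")
        bad = rows_where(obs & (df["DV"] < 0))
        if bad:
            problems.append(f"negative DV at rows {bad}")

        for sid, block in df.groupby("ID", sort=False):
            t = block["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                problems.append(f"TIME not non-decreasing within subject {sid!r}")
            if for_estimation and not ((block["EVID"] == 0) & block["DV"].notna()).any():
                problems.append(f"subject {sid!r} has no usable observation")

        if problems:
            raise DatasetValidationError("; ".join(problems))
        return self


def read_dataset(
    path,
    dv_unit: str = "mmol/L",
    salt_factor: float = DEFAULT_SALT_FACTOR,
    validate: bool = True,
) -> EventDataset:
    """Read a CSV event dataset, converting concentrations to internal mg/L."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    if dv_unit == "mmol/L":
        df["DV"] = df["DV"] * MG_PER_MMOL
        if "BASE" in df.columns:
            df["BASE"] = df["BASE"] * MG_PER_MMOL
    elif dv_unit != "mg/L":
        raise ValueError(f"unknown dv_unit {dv_unit!r}")
    ds = EventDataset(df, salt_factor=salt_factor)
    if validate:
        ds.validate()
    return ds


def write_dataset(dataset: EventDataset, path, dv_unit: str = "mmol/L") -> None:
    """Write to CSV in the requested concentration display unit."""
    df = dataset.df.copy()
    if dv_unit == "mmol/L":
        df["DV"] = df["DV"] / MG_PER_MMOL
        if "BASE" in df.columns:
            df["BASE"] = df["BASE"] / MG_PER_MMOL
    elif dv_unit != "mg/L":
        raise ValueError(f"unknown dv_unit {dv_unit!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
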