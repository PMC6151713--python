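"""Longitudinal study container and its CSV interchange format.

A :class:`StudyDataset` is a thin wrapper around a pandas DataFrame in a
NONMEM-like event-record layout, one row per dose or observation:

======  =======================================================
column  meaning
======  =======================================================
ID      integer subject identifier
TIME    event time (h)
EVID    1 = dose record, 0 = observation record
AMT     dose amount (mg/kg); empty on observations
ROUTE   ``ORAL_TEG`` or ``IV_5FU``; dose rows only
DVID    analyte code: 1 = tegafur, 2 = 5-FU, 3 = gimeracil
DV      observed concentration (ng/mL); empty on dose rows
BLQ     1 if the observation is below its quantification limit
GROUP   0 = control, 1 = pretreated
======  =======================================================

Files are plain RFC-4180 CSV (UTF-8, '.' decimal).  Reading validates the
table and reports every offending line in a single error.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .model import Analyte, DoseEvent, Route

__all__ = [
    "StudyDataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "COLUMNS",
    "DVID_TO_ANALYTE",
    "ANALYTE_TO_DVID",
]

COLUMNS = ("ID", "TIME", "EVID", "AMT", "ROUTE", "DVID", "DV", "BLQ", "GROUP")

DVID_TO_ANALYTE = {1: Analyte.TEGAFUR, 2: Analyte.FU, 3: Analyte.GIMERACIL}
ANALYTE_TO_DVID = {v: k for k, v in DVID_TO_ANALYTE.items()}
ROUTE_CODES = {"ORAL_TEG": Route.ORAL_TEGAFUR, "IV_5FU": Route.IV_5FU}
ROUTE_TO_CODE = {v: k for k, v in ROUTE_CODES.items()}


class DatasetError(ValueError):
    """Validation failure; ``errors`` lists every offending line."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid dataset (%d problem%s):\n  %s"
            % (len(self.errors), "s" if len(self.errors) != 1 else "", "\n  ".join(self.errors))
        )


@dataclass
class StudyDataset:
    """Dose events and analyte-coded concentration records for a cohort."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise DatasetError([f"missing column(s): {', '.join(missing)}"])
        self.table = self.table.loc[:, list(COLUMNS)].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def subjects(self) -> list[int]:
        return sorted(int(s) for s in self.table["ID"].unique())

    def group_of(self, subject: int) -> int:
        rows = self.table[self.table["ID"] == subject]
        return int(rows["GROUP"].iloc[0])

    def doses(self, subject: int) -> list[DoseEvent]:
        rows = self.table[(self.table["ID"] == subject) & (self.table["EVID"] == 1)]
        return [
            DoseEvent(time=float(r.TIME), amount=float(r.AMT), route=ROUTE_CODES[r.ROUTE])
            for r in rows.itertuples()
        ]

    def observations(
        self,
        subject: int | None = None,
        analyte: Analyte | str | None = None,
        include_blq: bool = True,
    ) -> pd.DataFrame:
        obs = self.table[self.table["EVID"] == 0]
        if subject is not None:
            obs = obs[obs["ID"] == subject]
        if analyte is not None:
            obs = obs[obs["DVID"] == ANALYTE_TO_DVID[Analyte(analyte)]]
        if not include_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def iter_profiles(
        self, analyte: Analyte | str
    ) -> Iterator[tuple[int, pd.DataFrame]]:
        """Yield (subject, observation rows sorted by time) for one analyte."""
        for subject in self.subjects:
            rows = self.observations(subject, analyte).sort_values("TIME")
            if len(rows):
                yield subject, rows

    def subset(self, subjects: Sequence[int]) -> "StudyDataset":
        keep = self.table["ID"].isin(list(subjects))
        return StudyDataset(self.table[keep].copy(), dict(self.meta))

    def __len__(self) -> int:
        return len(self.table)


def _format_table(ds: StudyDataset) -> pd.DataFrame:
    out = ds.table.copy()
    out["ID"] = out["ID"].astype(int)
    out["EVID"] = out["EVID"].astype(int)
    out["DVID"] = out["DVID"].astype("Int64")
    out["BLQ"] = out["BLQ"].astype(int)
    out["GROUP"] = out["GROUP"].astype(int)
    return out


def write_dataset(ds: StudyDataset, path: str | Path) -> None:
    """Write the dataset as CSV; deterministic byte-for-byte for equal inputs."""
    out = _format_table(ds)
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def to_csv_string(ds: StudyDataset) -> str:
    buf = _io.StringIO()
    write_dataset(ds, buf)  # type: ignore[arg-type]
    return buf.getvalue()


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and validate a study CSV; raises :class:`DatasetError` on problems."""
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DatasetError([f"unreadable CSV: {exc}"]) from exc
    if list(raw.columns) != list(COLUMNS):
        raise DatasetError(
            [f"header must be exactly {','.join(COLUMNS)}; got {','.join(raw.columns)}"]
        )

    errors: list[str] = []
    records = []
    for idx, row in raw.iterrows():
        line = idx + 2  # 1-based, after header
        rec: dict = {}

        def num(col: str, required: bool, integer: bool = False):
            text = row[col].strip()
            if text == "":
                if required:
                    errors.append(f"line {line}: missing {col}")
                return None
            try:
                value = float(text)
            except ValueError:
                errors.append(f"line {line}: malformed numeric {col}={text!r}")
                return None
            if integer and value != int(value):
                errors.append(f"line {line}: {col} must be an integer, got {text!r}")
                return None
            return int(value) if integer else value

        rec["ID"] = num("ID", required=True, integer=True)
        rec["TIME"] = num("TIME", required=True)
        rec["EVID"] = num("EVID", required=True, integer=True)
        rec["AMT"] = num("AMT", required=False)
        rec["DVID"] = num("DVID", required=False, integer=True)
        rec["DV"] = num("DV", required=False)
        rec["BLQ"] = num("BLQ", required=False, integer=True) or 0
        rec["GROUP"] = num("GROUP", required=True, integer=True)
        rec["ROUTE"] = row["ROUTE"].strip()

        if rec["EVID"] not in (None, 0, 1):
            errors.append(f"line {line}: EVID must be 0 or 1, got {rec['EVID']}")
        elif rec["EVID"] == 1:
            if rec["AMT"] is None or rec["AMT"] < 0:
                errors.append(f"line {line}: dose row needs AMT >= 0")
            if rec["ROUTE"] not in ROUTE_CODES:
                errors.append(
                    f"line {line}: dose row needs ROUTE in {sorted(ROUTE_CODES)}, "
                    f"got {rec['ROUTE']!r}"
                )
            if rec["DV"] is not None:
                errors.append(f"line {line}: DV must be empty on a dose row")
        elif rec["EVID"] == 0:
            if rec["DVID"] not in DVID_TO_ANALYTE:
                errors.append(f"line {line}: observation needs DVID in {sorted(DVID_TO_ANALYTE)}")
            if rec["DV"] is None:
                errors.append(f"line {line}: observation needs DV")
            elif rec["DV"] < 0:
                errors.append(f"line {line}: DV must be non-negative, got {rec['DV']}")
            if rec["AMT"] is not None:
                errors.append(f"line {line}: AMT must be empty on an observation row")
        if rec["GROUP"] not in (None, 0, 1):
            errors.append(f"line {line}: GROUP must be 0 or 1, got {rec['GROUP']}")
        if rec["BLQ"] not in (0, 1):
            errors.append(f"line {line}: BLQ must be 0 or 1, got {rec['BLQ']}")
        records.append(rec)

    table = pd.DataFrame.from_records(records, columns=list(COLUMNS))
    if not errors:
        obs = table[table["EVID"] == 0]
        dup = obs.duplicated(subset=["ID", "TIME", "DVID"], keep=False)
        for idx in obs.index[dup]:
            errors.append(
                f"line {idx + 2}: duplicate observation (ID, TIME, DVID)="
                f"({table.at[idx, 'ID']}, {table.at[idx, 'TIME']}, {table.at[idx, 'DVID']})"
            )
        for subject, sub in table.groupby("ID"):
            if not (sub["EVID"] == 1).any():
                errors.append(f"subject {subject}: no dose (EVID=1) record")
            if sub["GROUP"].nunique() > 1:
                errors.append(f"subject {subject}: inconsistent GROUP values")
    if errors:
        raise DatasetError(errors)
    table["AMT"] = table["AMT"].astype(float)
    table["DV"] = table["DV"].astype(float)
    table["DVID"] = table["DVID"].astype("Int64")
    return StudyDataset(table)
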