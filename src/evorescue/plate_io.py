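"""Plate-reader and transfer-series I/O.

Reads kinetic OD600 tables (time × wells), per-transfer endpoint tables
(transfer × populations) and the layout metadata that maps every well or
population to its culture type, stress treatment, dose and replicate id.
Every series emitted by this module carries exactly one layout annotation;
unmapped columns are a hard error, never silently dropped.

All tables are plain delimited text (comma or tab, sniffed or forced);
layouts may also be YAML.  Lines starting with ``#`` are provenance
comments and are ignored on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataError",
    "CultureType",
    "Treatment",
    "PlateLayout",
    "KineticCurve",
    "TransferTrajectory",
    "read_layout",
    "write_layout",
    "read_kinetic_table",
    "write_kinetic_table",
    "read_transfer_table",
    "write_transfer_table",
    "write_metrics_table",
    "read_metrics_table",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


class CultureType(str, Enum):
    PROTOTROPH = "prototroph"
    MUTUALISM = "mutualism"
    MONOCULTURE_DI = "monoculture_dI"
    MONOCULTURE_DM = "monoculture_dM"
    EVOLVED_ISOLATE = "evolved_isolate"
    BLANK = "blank"


class Treatment(str, Enum):
    NONE = "none"
    SALINITY = "salinity"
    PNP = "PNP"
    H2O2 = "H2O2"
    SPECTINOMYCIN = "spectinomycin"


@dataclass(frozen=True)
class PlateLayout:
    """Annotation for one well or population.

    ``dose`` is in treatment-specific units (% NaCl, mM PNP, µM H2O2,
    µg/mL spectinomycin); dose 0 with a named stressor is a valid 0-dose
    control, so dose/treatment consistency is not enforced.
    """

    id: str
    culture_type: CultureType
    treatment: Treatment = Treatment.NONE
    dose: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "culture_type", CultureType(self.culture_type))
        object.__setattr__(self, "treatment", Treatment(self.treatment))


Layout = Mapping[str, PlateLayout]


def make_layout(entries: Iterable[PlateLayout]) -> dict[str, PlateLayout]:
    """Index layout entries by id, enforcing uniqueness."""
    out: dict[str, PlateLayout] = {}
    for e in entries:
        if e.id in out:
            raise DataError(f"duplicate layout id {e.id!r}")
        out[e.id] = e
    return out


@dataclass
class KineticCurve:
    """One well's OD600 readings over a single growth cycle.

    times are minutes from cycle start (strictly increasing, nominally every
    5 min but irregular spacing is accepted); od values are non-negative.
    """

    times: np.ndarray
    od: np.ndarray
    meta: PlateLayout

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise DataError("times and od must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise DataError(f"kinetic curve {self.meta.id!r} has fewer than 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"non-monotone time axis in well {self.meta.id!r}")
        if np.any(self.od < 0):
            raise DataError(f"negative OD reading in well {self.meta.id!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TransferTrajectory:
    """One population's end-of-cycle OD600 across serial transfers.

    Transfer indices are 1-based and contiguous; ``stress_start`` is the
    first transfer at which stress was applied.
    """

    transfers: np.ndarray
    od: np.ndarray
    stress_start: int
    meta: PlateLayout

    def __post_init__(self) -> None:
        self.transfers = np.asarray(self.transfers, dtype=int)
        self.od = np.asarray(self.od, dtype=float)
        if self.transfers.shape != self.od.shape or self.transfers.ndim != 1:
            raise DataError("transfers and od must be 1-D arrays of equal length")
        t = self.transfers
        if len(t) == 0 or t[0] != 1 or np.any(np.diff(t) != 1):
            raise DataError(
                f"transfer indices for {self.meta.id!r} must be contiguous and 1-based"
            )
        if np.any(self.od < 0):
            raise DataError(f"negative OD in trajectory {self.meta.id!r}")
        if not (1 <= self.stress_start <= len(t)):
            raise DataError(
                f"stress_start {self.stress_start} outside 1..{len(t)} "
                f"for {self.meta.id!r}"
            )

    def __len__(self) -> int:
        return len(self.transfers)


# ---------------------------------------------------------------------------
# layout I/O

_LAYOUT_COLUMNS = ["id", "culture_type", "treatment", "dose", "replicate"]


def read_layout(path: str | Path) -> dict[str, PlateLayout]:
    """Read a layout from YAML (list of mappings) or delimited text."""
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise DataError("YAML layout must be a list of entries")
        rows = raw
    else:
        df = pd.read_csv(path, sep=_sniff(path), comment="#")
        missing = set(_LAYOUT_COLUMNS[:2]) - set(df.columns)
        if missing:
            raise DataError(f"layout file missing columns {sorted(missing)}")
        rows = df.to_dict("records")
    entries = []
    for row in rows:
        try:
            entries.append(
                PlateLayout(
                    id=str(row["id"]),
                    culture_type=CultureType(row["culture_type"]),
                    treatment=Treatment(row.get("treatment", "none")),
                    dose=float(row.get("dose", 0.0) or 0.0),
                    replicate=int(row.get("replicate", 1) or 1),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataError(f"bad layout entry {row!r}: {exc}") from exc
    return make_layout(entries)


def write_layout(layout: Layout, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": e.id,
                "culture_type": e.culture_type.value,
                "treatment": e.treatment.value,
                "dose": e.dose,
                "replicate": e.replicate,
            }
            for e in layout.values()
        ],
        columns=_LAYOUT_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# delimited-table helpers

def _sniff(path: str | Path) -> str:
    """Pick the delimiter ({comma, tab}) from the first data line."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter or _sniff(path)
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty table: {path}") from exc


def _lookup(layout: Layout, name: str, kind: str) -> PlateLayout:
    if name not in layout:
        raise DataError(f"{kind} column {name!r} has no layout entry")
    return layout[name]


def _write_with_header(df: pd.DataFrame, path: str | Path,
                       header_lines: Sequence[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# kinetic tables

def read_kinetic_table(
    path: str | Path,
    layout: Layout,
    dialect: str = "wide",
    delimiter: str | None = None,
    time_unit: str = "min",
    subtract_blank: bool = False,
) -> list[KineticCurve]:
    """Read kinetic OD600 curves.

    wide dialect: first column is time, one column per well.
    long dialect: columns (well, time, od).

    Times are converted to minutes (``time_unit`` in {"min", "h"}).  With
    ``subtract_blank`` the per-plate median of all blank-well readings is
    subtracted from every well (clipped at 0); off by default.
    """
    if dialect not in {"wide", "long"}:
        raise DataError(f"unknown dialect {dialect!r}")
    factor = {"min": 1.0, "h": 60.0}.get(time_unit)
    if factor is None:
        raise DataError(f"unknown time unit {time_unit!r}")
    df = _read_table(path, delimiter)

    curves: list[KineticCurve] = []
    if dialect == "wide":
        time = df.iloc[:, 0].to_numpy(dtype=float) * factor
        for col in df.columns[1:]:
            meta = _lookup(layout, str(col), "well")
            curves.append(
                KineticCurve(time, df[col].to_numpy(dtype=float), meta)
            )
    else:
        need = {"well", "time", "od"}
        if not need <= set(df.columns):
            raise DataError(f"long kinetic table needs columns {sorted(need)}")
        for well, sub in df.groupby("well", sort=False):
            meta = _lookup(layout, str(well), "well")
            sub = sub.sort_values("time")
            curves.append(
                KineticCurve(
                    sub["time"].to_numpy(dtype=float) * factor,
                    sub["od"].to_numpy(dtype=float),
                    meta,
                )
            )
    if subtract_blank:
        blanks = np.concatenate(
            [c.od for c in curves if c.meta.culture_type is CultureType.BLANK]
        ) if any(c.meta.culture_type is CultureType.BLANK for c in curves) else None
        if blanks is None:
            raise DataError("subtract_blank requested but layout has no blank wells")
        level = float(np.median(blanks))
        curves = [
            KineticCurve(c.times, np.clip(c.od - level, 0.0, None), c.meta)
            for c in curves
        ]
    return curves


def write_kinetic_table(
    curves: Sequence[KineticCurve],
    path: str | Path,
    dialect: str = "long",
    header_lines: Sequence[str] | None = None,
) -> None:
    if dialect == "long":
        df = pd.DataFrame(
            [
                {"well": c.meta.id, "time": t, "od": o}
                for c in curves
                for t, o in zip(c.times, c.od)
            ],
            columns=["well", "time", "od"],
        )
    elif dialect == "wide":
        if not curves:
            df = pd.DataFrame({"time": []})
        else:
            ref = curves[0].times
            for c in curves:
                if not np.array_equal(c.times, ref):
                    raise DataError("wide output requires a shared time axis")
            df = pd.DataFrame({"time": ref})
            for c in curves:
                df[c.meta.id] = c.od
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    _write_with_header(df, path, header_lines)


# ---------------------------------------------------------------------------
# transfer tables

def read_transfer_table(
    path: str | Path,
    layout: Layout,
    stress_start: int = 4,
    delimiter: str | None = None,
    dialect: str = "auto",
) -> list[TransferTrajectory]:
    """Read end-of-cycle OD600 trajectories.

    long dialect: columns (population, transfer, od).
    wide dialect: first column population, remaining columns transfer
    indices 1..T.  Missing transfer indices inside 1..T are a hard error;
    no interpolation is performed.
    """
    df = _read_table(path, delimiter)
    if dialect == "auto":
        dialect = "long" if {"population", "transfer", "od"} <= set(df.columns) else "wide"

    out: list[TransferTrajectory] = []
    if dialect == "long":
        need = {"population", "transfer", "od"}
        if not need <= set(df.columns):
            raise DataError(f"long transfer table needs columns {sorted(need)}")
        if df.empty:
            raise DataError("transfer table contains no rows")
        for pop, sub in df.groupby("population", sort=False):
            meta = _lookup(layout, str(pop), "population")
            sub = sub.sort_values("transfer")
            t = sub["transfer"].to_numpy(dtype=int)
            if len(t) == 0 or t[0] != 1 or np.any(np.diff(t) != 1):
                missing = sorted(set(range(1, int(t.max()) + 1)) - set(t.tolist())) if len(t) else []
                raise DataError(
                    f"population {pop!r}: transfer indices not contiguous from 1"
                    + (f" (missing {missing})" if missing else "")
                )
            out.append(
                TransferTrajectory(t, sub["od"].to_numpy(dtype=float), stress_start, meta)
            )
    elif dialect == "wide":
        if df.shape[1] < 2 or df.empty:
            raise DataError("wide transfer table needs a population column and data")
        try:
            cols = [int(c) for c in df.columns[1:]]
        except ValueError as exc:
            raise DataError("wide transfer columns must be integer transfer indices") from exc
        order = np.argsort(cols)
        t = np.asarray(cols)[order]
        if t[0] != 1 or np.any(np.diff(t) != 1):
            raise DataError("wide transfer indices must be contiguous from 1")
        for _, row in df.iterrows():
            meta = _lookup(layout, str(row.iloc[0]), "population")
            od = row.iloc[1:].to_numpy(dtype=float)[order]
            out.append(TransferTrajectory(t, od, stress_start, meta))
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    return out


def write_transfer_table(
    trajectories: Sequence[TransferTrajectory],
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    df = pd.DataFrame(
        [
            {"population": tr.meta.id, "transfer": int(t), "od": o}
            for tr in trajectories
            for t, o in zip(tr.transfers, tr.od)
        ],
        columns=["population", "transfer", "od"],
    )
    _write_with_header(df, path, header_lines)


# ---------------------------------------------------------------------------
# metrics tables

def write_metrics_table(
    metrics: Iterable,
    path: str | Path,
    header_lines: Sequence[str] | None = None,
) -> None:
    """Write one row per population for metric dataclasses.

    Accepts any iterable of objects exposing ``to_row() -> dict`` (e.g.
    RescueMetrics, GrowthSummary) or plain dicts.  Undefined values are
    written as empty cells, never as 0.  Floats round-trip at better than
    1e-9 (written with repr precision).
    """
    rows = []
    for m in metrics:
        rows.append(m.to_row() if hasattr(m, "to_row") else dict(m))
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["id"])
    _write_with_header(df, path, header_lines)


def read_metrics_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a metrics table back; empty cells become NaN."""
    sep = delimiter or _sniff(path)
    return pd.read_csv(path, sep=sep, comment="#")
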