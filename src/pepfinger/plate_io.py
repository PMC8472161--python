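"""Plate-reader I/O: time-series tables, plate layouts and fingerprint tables.

Two delimited-text dialects are accepted for time series:

* **wide** — one row per well; first column ``well_id``, remaining columns are
  timepoints in minutes named ``t_<min>`` (or bare numbers).
* **long** — columns ``well_id``, ``time_min``, ``fluorescence_au``; row order
  is irrelevant, readings are sorted by time.

The layout table has columns ``well_id``, ``sample_id``, ``sample_type``,
``substrate``, ``inhibitor_group``, ``dilution_factor``. The delimiter is
auto-detected from the header line (comma default). Time is in minutes at the
I/O boundary throughout.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBSTRATES = ("PepA", "PepB", "PepC", "PepD", "PepE")
INHIBITOR_GROUPS = ("NONE", "MMPi", "COMi", "BOTHi")
SAMPLE_TYPES = ("saliva", "biopsy", "pos_control", "neg_control")

_LAYOUT_COLUMNS = [
    "well_id",
    "sample_id",
    "sample_type",
    "substrate",
    "inhibitor_group",
    "dilution_factor",
]


class PlateIOError(ValueError):
    """Raised on malformed plate tables or layout violations."""


@dataclass
class WellRecord:
    """One well's fluorescence time course plus its assay metadata.

    ``time_min`` must be strictly increasing with at least four points so the
    four-point kinetic fit is possible; ``fluorescence_au`` is the raw reading
    in arbitrary units on the same grid.
    """

    well_id: str
    sample_id: str
    sample_type: str
    substrate: str
    inhibitor_group: str
    dilution_factor: float
    time_min: np.ndarray
    fluorescence_au: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.sample_type not in SAMPLE_TYPES:
            raise PlateIOError(
                f"well {self.well_id!r}: unknown sample_type {self.sample_type!r}"
            )
        if self.substrate != "none" and self.substrate not in SUBSTRATES:
            raise PlateIOError(
                f"well {self.well_id!r}: unknown substrate {self.substrate!r}"
            )
        if self.inhibitor_group not in INHIBITOR_GROUPS:
            raise PlateIOError(
                f"well {self.well_id!r}: unknown inhibitor_group "
                f"{self.inhibitor_group!r}"
            )
        if not self.dilution_factor > 0:
            raise PlateIOError(
                f"well {self.well_id!r}: dilution_factor must be > 0"
            )
        if self.time_min.ndim != 1 or self.time_min.size < 4:
            raise PlateIOError(
                f"well {self.well_id!r}: need >= 4 timepoints, "
                f"got {self.time_min.size}"
            )
        if self.fluorescence_au.shape != self.time_min.shape:
            raise PlateIOError(
                f"well {self.well_id!r}: reading/time length mismatch"
            )
        if not np.all(np.diff(self.time_min) > 0):
            raise PlateIOError(
                f"well {self.well_id!r}: time_min must be strictly increasing"
            )


@dataclass
class PlateLayout:
    """Mapping from well ids to sample / substrate / inhibitor metadata."""

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _LAYOUT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise PlateIOError(f"layout missing columns: {missing}")
        if self.rows["well_id"].duplicated().any():
            dup = self.rows.loc[self.rows["well_id"].duplicated(), "well_id"]
            raise PlateIOError(f"duplicate well ids in layout: {sorted(set(dup))}")
        self.rows = self.rows.reset_index(drop=True)

    def lookup(self, well_id: str) -> pd.Series:
        hit = self.rows[self.rows["well_id"] == well_id]
        if hit.empty:
            raise PlateIOError(f"well {well_id!r} not present in layout")
        return hit.iloc[0]

    def incomplete_groups(self) -> list[tuple[str, str]]:
        """(sample_id, substrate) pairs with inhibited wells but no NONE control."""
        out = []
        assay = self.rows[self.rows["sample_type"].isin(("saliva", "biopsy"))]
        for (sid, sub), grp in assay.groupby(["sample_id", "substrate"]):
            groups = set(grp["inhibitor_group"])
            if groups - {"NONE"} and "NONE" not in groups:
                out.append((sid, sub))
        return sorted(out)


def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate-layout CSV into a validated :class:`PlateLayout`."""
    df = pd.read_csv(path, sep=_sniff_sep(Path(path)))
    df["well_id"] = df["well_id"].astype(str)
    df["dilution_factor"] = df["dilution_factor"].astype(float)
    return PlateLayout(df)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.rows[_LAYOUT_COLUMNS].to_csv(path, index=False)


def _parse_time_column(name: str) -> float:
    tag = name[2:] if name.startswith("t_") else name
    try:
        return float(tag)
    except ValueError:
        raise PlateIOError(f"cannot parse timepoint column {name!r}") from None


def read_timeseries(path: str | Path, layout: PlateLayout) -> list[WellRecord]:
    """Read a wide or long time-series CSV and assemble WellRecords.

    The dialect is detected from the header: a ``time_min`` column marks the
    long format, otherwise all non-``well_id`` columns are timepoints. Every
    well in the table must be covered by the layout.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if "well_id" not in df.columns:
        raise PlateIOError(f"{path}: no well_id column")
    df["well_id"] = df["well_id"].astype(str)

    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if "time_min" in df.columns:  # long dialect
        if "fluorescence_au" not in df.columns:
            raise PlateIOError(f"{path}: long table needs fluorescence_au column")
        for col in ("time_min", "fluorescence_au"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                row = int(df.index[bad | df[col].isna()][0])
                raise PlateIOError(
                    f"{path}: non-numeric or missing value in column {col!r}, "
                    f"row {row}"
                )
        for wid, grp in df.groupby("well_id", sort=False):
            grp = grp.sort_values("time_min")
            series[str(wid)] = (
                grp["time_min"].to_numpy(float),
                grp["fluorescence_au"].to_numpy(float),
            )
    else:  # wide dialect
        tcols = [c for c in df.columns if c != "well_id"]
        times = np.array([_parse_time_column(c) for c in tcols])
        order = np.argsort(times)
        for _, row in df.iterrows():
            vals = pd.to_numeric(row[tcols], errors="coerce").to_numpy(float)
            if np.isnan(vals).any():
                col = tcols[int(np.flatnonzero(np.isnan(vals))[0])]
                raise PlateIOError(
                    f"{path}: non-numeric or missing reading for well "
                    f"{row['well_id']!r}, column {col!r}"
                )
            series[str(row["well_id"])] = (times[order], vals[order])

    records = []
    for wid, (t, f) in series.items():
        if t.size < 4:
            raise PlateIOError(f"well {wid!r}: fewer than 4 timepoints")
        meta = layout.lookup(wid)
        records.append(
            WellRecord(
                well_id=wid,
                sample_id=str(meta["sample_id"]),
                sample_type=str(meta["sample_type"]),
                substrate=str(meta["substrate"]),
                inhibitor_group=str(meta["inhibitor_group"]),
                dilution_factor=float(meta["dilution_factor"]),
                time_min=t,
                fluorescence_au=f,
            )
        )
    return records


def write_timeseries(
    wells: Iterable[WellRecord], path: str | Path, dialect: str = "wide"
) -> None:
    """Write WellRecords as a wide or long time-series CSV."""
    wells = list(wells)
    if not wells:
        raise PlateIOError("no wells to write")
    if dialect == "wide":
        grid = wells[0].time_min
        for w in wells:
            if not np.array_equal(w.time_min, grid):
                raise PlateIOError(
                    "wide dialect requires a shared time grid; use dialect='long'"
                )
        cols = {"well_id": [w.well_id for w in wells]}
        for j, t in enumerate(grid):
            cols[f"t_{t:g}"] = [w.fluorescence_au[j] for w in wells]
        pd.DataFrame(cols).to_csv(path, index=False)
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "time_min": w.time_min,
                    "fluorescence_au": w.fluorescence_au,
                }
            )
            for w in wells
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise PlateIOError(f"unknown dialect {dialect!r}")


def layout_from_wells(wells: Sequence[WellRecord]) -> PlateLayout:
    """Build the layout table implied by a collection of WellRecords."""
    return PlateLayout(
        pd.DataFrame(
            [
                {
                    "well_id": w.well_id,
                    "sample_id": w.sample_id,
                    "sample_type": w.sample_type,
                    "substrate": w.substrate,
                    "inhibitor_group": w.inhibitor_group,
                    "dilution_factor": w.dilution_factor,
                }
                for w in wells
            ]
        )
    )


def write_fingerprints(fingerprints: pd.DataFrame, path: str | Path) -> None:
    """Write a fingerprint table (one row per sample) to CSV.

    The frame must carry a ``sample_id`` column; the column schema is whatever
    :func:`pepfinger.fingerprint.fingerprint_table` produced, written with a
    full-precision header so a read-back reproduces the values.
    """
    if len(fingerprints) == 0:
        raise PlateIOError("refusing to write an empty fingerprint table")
    if "sample_id" not in fingerprints.columns:
        raise PlateIOError("fingerprint table must have a sample_id column")
    buf = io.StringIO()
    # default float formatting is shortest round-trip repr: read-back is exact
    fingerprints.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(Path(path)), float_precision="round_trip")
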