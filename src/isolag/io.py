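"""Readers, writers and container types for trajectories, hair records and isoscapes.

All downstream stages consume only the types defined here:

* :class:`IsoScape` — a gridded δ³⁴S surface (‰ vs V-CDT) with georeferencing
  metadata, serialised as an ESRI ASCII grid.
* :class:`Trajectory` — timestamped planar positions for one animal.
* :class:`HairRecord` — shave/collection dates, total hair length, and the
  ordered per-segment δ³⁴S series (index 0 = proximal, i.e. most recent).

Coordinates are planar map units in any projected CRS; the analysis only ever
needs point-in-cell lookup, so no geodesy is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEGMENT_LENGTH_MM = 8.0

__all__ = [
    "FormatError",
    "IsoScape",
    "Trajectory",
    "HairRecord",
    "SEGMENT_LENGTH_MM",
    "read_trajectories",
    "write_trajectories",
    "read_isoscape",
    "write_isoscape",
    "sample_isoscape",
    "read_hair_records",
    "write_hair_records",
    "parse_date",
]


class FormatError(ValueError):
    """An input file does not conform to its expected layout."""


# ---------------------------------------------------------------------------
# Isoscape
# ---------------------------------------------------------------------------


@dataclass
class IsoScape:
    """Gridded δ³⁴S surface.

    ``grid`` is stored with row 0 as the *northern*-most row (the ESRI ASCII
    convention); missing cells hold NaN.  ``origin_x``/``origin_y`` anchor the
    lower-left corner of the grid; ``cell_size`` is the edge length of a
    (square) cell in map units.

    Cell ownership is half-open in both axes: a point belongs to the cell
    whose extent is ``[edge, edge + cell_size)``, which makes boundary
    behaviour deterministic.
    """

    grid: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("isoscape grid must be 2-D with >=1 row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.grid) | np.isnan(self.grid)):
            raise ValueError("isoscape values must be finite or missing")

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
            self.origin_y + self.nrows * self.cell_size,
        )

    def sample(self, x, y) -> np.ndarray:
        """Vectorised nearest-cell lookup.

        Returns the δ³⁴S value of the cell containing each ``(x, y)``; NaN for
        points outside the extent or on nodata cells.  Accepts scalars or
        arrays and broadcasts.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_s = np.floor((y - self.origin_y) / self.cell_size).astype(int)  # from south
        inside = (col >= 0) & (col < self.ncols) & (row_s >= 0) & (row_s < self.nrows)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        row = self.nrows - 1 - row_s  # grid row 0 is the northern edge
        out[inside] = self.grid[row[inside], col[inside]]
        return out


def sample_isoscape(scape: IsoScape, x: float, y: float) -> float:
    """Scalar nearest-cell lookup; NaN signals a missing value, never an error."""
    return float(scape.sample(x, y))


def read_isoscape(path: str | Path) -> IsoScape:
    """Read an ESRI ASCII grid (``.asc``).

    The header must provide ``ncols, nrows, xllcorner, yllcorner, cellsize``
    and optionally ``NODATA_value``; nodata cells become NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                if len(parts) != 2:
                    raise FormatError(f"malformed header line in {path.name}: {line!r}")
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise FormatError(f"non-numeric grid data in {path.name}: {line!r}") from exc
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise FormatError(f"{path.name}: missing header keys {sorted(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array([v for r in rows for v in r], dtype=float)
    if values.size != nrows * ncols:
        raise FormatError(
            f"{path.name}: expected {nrows * ncols} cells, found {values.size}"
        )
    grid = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    grid[grid == nodata] = np.nan
    return IsoScape(
        grid=grid,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )


def write_isoscape(scape: IsoScape, path: str | Path) -> None:
    """Write an ESRI ASCII grid; NaN cells are emitted as the nodata sentinel."""
    path = Path(path)
    grid = np.where(np.isnan(scape.grid), scape.nodata, scape.grid)
    with path.open("w") as fh:
        fh.write(f"ncols {scape.ncols}\n")
        fh.write(f"nrows {scape.nrows}\n")
        fh.write(f"xllcorner {float(scape.origin_x)!r}\n")
        fh.write(f"yllcorner {float(scape.origin_y)!r}\n")
        fh.write(f"cellsize {float(scape.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(scape.nodata)!r}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Timestamped positions for one animal; timestamps strictly increasing."""

    animal_id: str
    times: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) == 0:
            raise ValueError(f"trajectory {self.animal_id}: no points")
        if len(self.times) != len(self.x) or len(self.times) != len(self.y):
            raise ValueError(f"trajectory {self.animal_id}: ragged columns")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise ValueError(
                f"trajectory {self.animal_id}: timestamps must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.times)


def read_trajectories(path: str | Path) -> dict[str, Trajectory]:
    """Read a trajectory CSV (columns ``id,timestamp,x,y``) into one
    :class:`Trajectory` per animal, rows sorted by timestamp.

    Raises :class:`FormatError` for missing columns; an unparseable timestamp
    raises a row-level error naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path.name}: no points")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        # fall back to per-row parsing so the error can name the line
        parsed = []
        for i, raw in enumerate(df["timestamp"]):
            try:
                parsed.append(pd.Timestamp(raw))
            except (ValueError, TypeError) as exc:
                raise FormatError(
                    f"{path.name} line {i + 2}: unparseable timestamp {raw!r}"
                ) from exc
        df["timestamp"] = parsed
    out: dict[str, Trajectory] = {}
    for animal_id, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("timestamp")
        out[str(animal_id)] = Trajectory(
            animal_id=str(animal_id),
            times=pd.DatetimeIndex(grp["timestamp"]),
            x=grp["x"].to_numpy(),
            y=grp["y"].to_numpy(),
        )
    return out


def write_trajectories(trajs: Iterable[Trajectory] | Mapping[str, Trajectory],
                       path: str | Path) -> None:
    if isinstance(trajs, Mapping):
        trajs = trajs.values()
    frames = [
        pd.DataFrame(
            {"id": t.animal_id, "timestamp": t.times.strftime("%Y-%m-%dT%H:%M:%S"),
             "x": t.x, "y": t.y}
        )
        for t in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Hair records
# ---------------------------------------------------------------------------


def parse_date(raw) -> date:
    """Parse a calendar date given either ISO 8601 or dd/mm/yyyy.

    Field datasets in this domain commonly print day-first dates; API-level
    inputs use ISO 8601.  Both are accepted, day-first only with '/'
    separators so ISO strings are never misread.
    """
    if isinstance(raw, datetime):
        return raw.date()
    if isinstance(raw, date):
        return raw
    s = str(raw).strip()
    for fmt in ("%Y-%m-%d", "%d/%m/%Y"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise FormatError(f"unparseable date {raw!r} (expected ISO 8601 or dd/mm/yyyy)")


@dataclass
class HairRecord:
    """One animal's regrown tail hair.

    ``segments`` holds the ordered per-segment δ³⁴S values with index 0 the
    proximal (most recent) 8 mm section; it may be None for growth-rate-only
    records.  ``days_dry``/``days_wet``/``days_lactating`` are optional
    covariates counting days of the growth period in each condition.
    """

    animal_id: str
    start_date: date
    end_date: date
    length_mm: float
    segments: np.ndarray | None = None
    days_dry: float | None = None
    days_wet: float | None = None
    days_lactating: float | None = None

    def __post_init__(self) -> None:
        self.start_date = parse_date(self.start_date)
        self.end_date = parse_date(self.end_date)
        if self.end_date <= self.start_date:
            raise ValueError(f"{self.animal_id}: end_date must follow start_date")
        if not self.length_mm > 0:
            raise ValueError(f"{self.animal_id}: length_mm must be positive")
        if self.segments is not None:
            self.segments = np.asarray(self.segments, dtype=float)
            expected = math.floor(self.length_mm / SEGMENT_LENGTH_MM)
            if len(self.segments) != expected:
                raise ValueError(
                    f"{self.animal_id}: {len(self.segments)} segment values for a "
                    f"{self.length_mm} mm hair (expected {expected})"
                )
            if not np.all(np.isfinite(self.segments)):
                raise ValueError(f"{self.animal_id}: non-finite segment δ³⁴S value")

    @property
    def n_segments(self) -> int:
        return math.floor(self.length_mm / SEGMENT_LENGTH_MM)


def read_hair_records(hair_path: str | Path,
                      segments_path: str | Path | None = None) -> dict[str, HairRecord]:
    """Read hair metadata (and optionally per-segment δ³⁴S values).

    ``hair_path``: CSV with columns
    ``id,start_date,end_date,length_mm[,days_dry,days_wet,days_lactating]``.
    ``segments_path``: CSV with columns ``id,segment_index,d34S``
    (segment_index 0-based from the proximal end).
    """
    hair_path = Path(hair_path)
    df = pd.read_csv(hair_path, dtype={"id": str})
    required = {"id", "start_date", "end_date", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{hair_path.name}: missing columns {sorted(missing)}")

    seg_map: dict[str, np.ndarray] = {}
    if segments_path is not None:
        seg_df = pd.read_csv(segments_path, dtype={"id": str})
        if not {"id", "segment_index", "d34S"} <= set(seg_df.columns):
            raise FormatError(f"{Path(segments_path).name}: need id,segment_index,d34S")
        for animal_id, grp in seg_df.groupby("id"):
            grp = grp.sort_values("segment_index")
            idx = grp["segment_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise FormatError(
                    f"segments for {animal_id}: indices must be 0..n-1 without gaps"
                )
            seg_map[str(animal_id)] = grp["d34S"].to_numpy(dtype=float)

    out: dict[str, HairRecord] = {}
    for _, row in df.iterrows():
        animal_id = str(row["id"])
        out[animal_id] = HairRecord(
            animal_id=animal_id,
            start_date=parse_date(row["start_date"]),
            end_date=parse_date(row["end_date"]),
            length_mm=float(row["length_mm"]),
            segments=seg_map.get(animal_id),
            days_dry=float(row["days_dry"]) if "days_dry" in df.columns else None,
            days_wet=float(row["days_wet"]) if "days_wet" in df.columns else None,
            days_lactating=(
                float(row["days_lactating"]) if "days_lactating" in df.columns else None
            ),
        )
    return out


def write_hair_records(records: Mapping[str, HairRecord] | Iterable[HairRecord],
                       hair_path: str | Path,
                       segments_path: str | Path | None = None) -> None:
    if isinstance(records, Mapping):
        records = list(records.values())
    else:
        records = list(records)
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.animal_id,
                "start_date": r.start_date.isoformat(),
                "end_date": r.end_date.isoformat(),
                "length_mm": r.length_mm,
                "days_dry": r.days_dry,
                "days_wet": r.days_wet,
                "days_lactating": r.days_lactating,
            }
        )
    pd.DataFrame(rows).to_csv(hair_path, index=False)
    if segments_path is not None:
        seg_rows = [
            {"id": r.animal_id, "segment_index": i, "d34S": repr(float(v))}
            for r in records
            if r.segments is not None
            for i, v in enumerate(r.segments)
        ]
        pd.DataFrame(seg_rows).to_csv(segments_path, index=False)
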