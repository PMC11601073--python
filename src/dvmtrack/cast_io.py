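"""Read, validate and write vertical-cast time series and discrete bottle samples.

The on-disk dialect is a long-format CSV, one row per (cast, depth):

    cast_id,time,depth_m,fluorescence[,chl_ug_L,temperature_C,salinity_PSU]

Depths are meters, positive downward, ``0`` at the surface. Timestamps are
ISO-8601; an explicit UTC offset is expected. Timestamps without an offset
are accepted with a warning and interpreted as local estuary time (UTC-4),
the convention of the field site whose sampling this package targets.

Discrete bottle samples use a second dialect, one row per sample:

    time,depth_m[,chl_ug_L][,count_<taxon>...][,carbon_<taxon>...]

``count_`` columns carry cell concentrations (cells mL^-1) and optional
``carbon_`` columns per-cell carbon weights (pg C cell^-1) for the same
taxon names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Fallback offset applied to naive timestamps (local time at the study site).
DEFAULT_UTC_OFFSET_HOURS = -4

_REQUIRED_CAST_COLUMNS = ("cast_id", "time", "depth_m", "fluorescence")
_OPTIONAL_CAST_COLUMNS = ("chl_ug_L", "temperature_C", "salinity_PSU")

#: Slack allowed between a cast's deepest sample and the nominal site depth
#: (meters); tides at a shallow estuarine station routinely move the true
#: bottom by this much.
SITE_DEPTH_TOLERANCE_M = 2.0


def _as_channel(values, n: int, name: str) -> Optional[np.ndarray]:
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValidationError(
            f"channel {name!r} has length {arr.size}, expected {n}"
        )
    if np.all(np.isnan(arr)):
        return None
    return arr


@dataclass
class Cast:
    """One vertical profile: depth-indexed channels at a single timestamp.

    Rows are canonicalised to strictly increasing depth on construction.
    """

    cast_id: str
    time: pd.Timestamp
    depth_m: np.ndarray
    fluorescence: Optional[np.ndarray] = None
    chl_ug_L: Optional[np.ndarray] = None
    temperature_C: Optional[np.ndarray] = None
    salinity_PSU: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = pd.Timestamp(self.time)
        if self.time.tzinfo is None:
            warnings.warn(
                f"cast {self.cast_id!r}: naive timestamp, assuming "
                f"UTC{DEFAULT_UTC_OFFSET_HOURS:+d}",
                stacklevel=2,
            )
            self.time = self.time.tz_localize(f"UTC{DEFAULT_UTC_OFFSET_HOURS:+03d}:00")
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        n = self.depth_m.size
        if n == 0:
            raise ValidationError(f"cast {self.cast_id!r} has no rows")
        if np.any(self.depth_m < 0):
            raise ValidationError(f"cast {self.cast_id!r} has negative depths")
        order = np.argsort(self.depth_m, kind="stable")
        self.depth_m = self.depth_m[order]
        if np.any(np.diff(self.depth_m) == 0):
            raise ValidationError(
                f"cast {self.cast_id!r} has duplicate depths"
            )
        for name in ("fluorescence", "chl_ug_L", "temperature_C", "salinity_PSU"):
            chan = _as_channel(getattr(self, name), n, name)
            setattr(self, name, chan[order] if chan is not None else None)

    def __len__(self) -> int:
        return int(self.depth_m.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cast):
            return NotImplemented
        if self.cast_id != other.cast_id or self.time != other.time:
            return False
        for name in ("depth_m", "fluorescence", "chl_ug_L", "temperature_C",
                     "salinity_PSU"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b, equal_nan=True):
                return False
        return True


@dataclass
class CastSeries:
    """A time-ordered sequence of casts from one study at one site."""

    casts: list
    site_depth_m: float

    def __post_init__(self) -> None:
        if self.site_depth_m <= 0:
            raise ValidationError("site_depth_m must be positive")
        self.casts = sorted(self.casts, key=lambda c: c.time)
        times = [c.time for c in self.casts]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("cast times must be strictly increasing")
        for c in self.casts:
            if c.depth_m[-1] > self.site_depth_m + SITE_DEPTH_TOLERANCE_M:
                raise ValidationError(
                    f"cast {c.cast_id!r} reaches {c.depth_m[-1]:.2f} m, deeper "
                    f"than site depth {self.site_depth_m:.2f} m + tolerance"
                )

    def __len__(self) -> int:
        return len(self.casts)

    def __iter__(self):
        return iter(self.casts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CastSeries):
            return NotImplemented
        return (
            self.site_depth_m == other.site_depth_m
            and len(self) == len(other)
            and all(a == b for a, b in zip(self.casts, other.casts))
        )


@dataclass
class DiscreteSample:
    """A single bottle sample: extracted Chl-a and/or per-taxon cell counts."""

    time: pd.Timestamp
    depth_m: float
    chl_ug_L: Optional[float] = None
    taxon_counts: dict = field(default_factory=dict)
    carbon_per_cell: Optional[dict] = None

    def __post_init__(self) -> None:
        self.time = pd.Timestamp(self.time)
        if self.time.tzinfo is None:
            self.time = self.time.tz_localize(f"UTC{DEFAULT_UTC_OFFSET_HOURS:+03d}:00")
        if self.depth_m < 0:
            raise ValidationError("sample depth must be >= 0")
        for taxon, count in self.taxon_counts.items():
            if count < 0:
                raise ValidationError(f"negative count for taxon {taxon!r}")


def _parse_times(raw: pd.Series, path) -> pd.Series:
    parsed = []
    any_naive = False
    for idx, value in raw.items():
        try:
            ts = pd.Timestamp(str(value))
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{path}: unparseable timestamp {value!r} at row {idx + 2}"
            ) from exc
        if ts.tzinfo is None:
            any_naive = True
            ts = ts.tz_localize(f"UTC{DEFAULT_UTC_OFFSET_HOURS:+03d}:00")
        parsed.append(ts)
    if any_naive:
        warnings.warn(
            f"{path}: timestamps lack a UTC offset, assuming "
            f"UTC{DEFAULT_UTC_OFFSET_HOURS:+d}",
            stacklevel=3,
        )
    return pd.Series(parsed, index=raw.index)


def read_cast_series(path, site_depth_m: float) -> CastSeries:
    """Parse a long-format cast CSV into a validated :class:`CastSeries`.

    Rows are grouped by ``cast_id``; row order within the file is irrelevant
    (casts are sorted by time, rows by depth).
    """
    df = pd.read_csv(path, dtype={"cast_id": str}, float_precision="round_trip")
    for col in _REQUIRED_CAST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.copy()
    df["time"] = _parse_times(df["time"], path)

    dup = df.duplicated(subset=["cast_id", "depth_m"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (cast_id, depth) = "
            f"({row['cast_id']!r}, {row['depth_m']})"
        )

    casts = []
    for cast_id, group in df.groupby("cast_id", sort=False):
        times = group["time"].unique()
        if len(times) > 1:
            raise ValidationError(
                f"{path}: cast {cast_id!r} has multiple timestamps"
            )
        kwargs = {}
        for col in _OPTIONAL_CAST_COLUMNS:
            if col in group.columns:
                kwargs[col] = group[col].to_numpy(dtype=float)
        casts.append(
            Cast(
                cast_id=str(cast_id),
                time=times[0],
                depth_m=group["depth_m"].to_numpy(dtype=float),
                fluorescence=group["fluorescence"].to_numpy(dtype=float),
                **kwargs,
            )
        )
    return CastSeries(casts=casts, site_depth_m=site_depth_m)


def write_cast_series(series: CastSeries, path) -> str:
    """Write a series in the long CSV dialect; inverse of :func:`read_cast_series`.

    Optional columns that are missing in every cast are omitted from the
    header, and float formatting uses ``repr`` so that a read/write cycle is
    lossless and byte-deterministic.
    """
    present = [
        col for col in _OPTIONAL_CAST_COLUMNS
        if any(getattr(c, col) is not None for c in series)
    ]
    rows = []
    for cast in series:
        n = len(cast)
        base = {
            "cast_id": [cast.cast_id] * n,
            "time": [cast.time.isoformat()] * n,
            "depth_m": cast.depth_m,
            "fluorescence": (
                cast.fluorescence if cast.fluorescence is not None
                else np.full(n, np.nan)
            ),
        }
        for col in present:
            chan = getattr(cast, col)
            base[col] = chan if chan is not None else np.full(n, np.nan)
        rows.append(pd.DataFrame(base))
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(path, index=False)
    return str(path)


def read_discrete_samples(path) -> list:
    """Parse a bottle-sample CSV into a list of :class:`DiscreteSample`.

    Taxon names are recovered from ``count_<name>`` / ``carbon_<name>``
    column suffixes. Row order is preserved.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "depth_m"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    carbon_cols = [c for c in df.columns if c.startswith("carbon_")]
    if "chl_ug_L" not in df.columns and not count_cols:
        raise FormatError(
            f"{path}: need either a 'chl_ug_L' column or 'count_*' columns"
        )
    df = df.copy()
    df["time"] = _parse_times(df["time"], path)

    samples = []
    for _, row in df.iterrows():
        counts = {}
        for col in count_cols:
            value = row[col]
            if pd.isna(value):
                continue
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count in column {col!r}"
                )
            counts[col[len("count_"):]] = float(value)
        carbon = {
            col[len("carbon_"):]: float(row[col])
            for col in carbon_cols
            if not pd.isna(row[col])
        }
        chl = row.get("chl_ug_L")
        samples.append(
            DiscreteSample(
                time=row["time"],
                depth_m=float(row["depth_m"]),
                chl_ug_L=None if chl is None or pd.isna(chl) else float(chl),
                taxon_counts=counts,
                carbon_per_cell=carbon or None,
            )
        )
    return samples


def write_discrete_samples(samples: Sequence[DiscreteSample], path) -> str:
    """Write bottle samples in the dialect read by :func:`read_discrete_samples`."""
    taxa = sorted({t for s in samples for t in s.taxon_counts})
    carbon_taxa = sorted(
        {t for s in samples if s.carbon_per_cell for t in s.carbon_per_cell}
    )
    rows = []
    for s in samples:
        row = {"time": s.time.isoformat(), "depth_m": s.depth_m}
        if any(x.chl_ug_L is not None for x in samples):
            row["chl_ug_L"] = s.chl_ug_L
        for t in taxa:
            row[f"count_{t}"] = s.taxon_counts.get(t, np.nan)
        for t in carbon_taxa:
            row[f"carbon_{t}"] = (
                (s.carbon_per_cell or {}).get(t, np.nan)
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)
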