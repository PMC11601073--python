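"""Migration-event detection and vertical migration rate estimation.

The layer-position track is the sequence of ``z_max`` estimates from
successive relative-chlorophyll profiles. The migration rate between two
adjacent retained profiles is

    w_dvm = |delta z_max| / delta t        [m h^-1],

where profiles flagged homogeneous are skipped and ``delta t`` spans any
skipped profiles. An *event* (one ascent or one descent per calendar day) is
bounded by the last retained profile observed in the departure band (bottom
band for ascents, surface band for descents) and the first retained profile
observed in the arrival band. Its mean rate is the unweighted mean of the
pairwise rates over the bounded stretch; the maximum rate is reported only
when the event is resolved by more than two profiles (with exactly two
profiles a single segment exists and a "maximum" would be meaningless, so it
is suppressed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .relchl import RelChlProfile

ASCENT = "ascent"
DESCENT = "descent"

STATUS_OBSERVED = "observed"
STATUS_NOT_OBSERVED = "not_observed"
STATUS_MAX_SUPPRESSED = "max_suppressed"

#: z_max at or above (shallower than) this depth counts as "at the surface".
DEFAULT_SURFACE_BAND_M = 1.0
#: z_max within this distance of the bottom counts as "at the bottom".
DEFAULT_BOTTOM_BAND_M = 1.0
#: How far outside the clock window the bounding profiles may fall (hours);
#: departures can precede the nominal window start by up to one sampling
#: interval, and arrivals can lag the window end likewise.
DEFAULT_GRACE_H = 2.5


def _clock(text: "str | dt.time") -> dt.time:
    if isinstance(text, dt.time):
        return text
    return dt.time.fromisoformat(text)


@dataclass(frozen=True)
class MigrationWindow:
    """A daily clock window during which one migration leg is expected."""

    kind: str
    start: dt.time
    end: dt.time

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", _clock(self.start))
        object.__setattr__(self, "end", _clock(self.end))
        if self.kind not in (ASCENT, DESCENT):
            raise ValidationError(f"unknown window kind {self.kind!r}")
        if self.start >= self.end:
            raise ValidationError("window start must precede end within one day")


#: Default windows: ascents between 04:00 and 09:00 local, descents between
#: 16:00 and 20:00, the diel pattern of a surface-bloom-forming dinoflagellate.
DEFAULT_ASCENT_WINDOW = MigrationWindow(ASCENT, dt.time(4, 0), dt.time(9, 0))
DEFAULT_DESCENT_WINDOW = MigrationWindow(DESCENT, dt.time(16, 0), dt.time(20, 0))


class TrackPoint(NamedTuple):
    time: pd.Timestamp
    z_max_m: float
    is_homogeneous: bool


@dataclass(frozen=True)
class RateSegment:
    """One pairwise rate between two adjacent retained profiles."""

    t0: pd.Timestamp
    t1: pd.Timestamp
    z0_m: float
    z1_m: float

    @property
    def dt_h(self) -> float:
        return (self.t1 - self.t0) / pd.Timedelta(hours=1)

    @property
    def dz_m(self) -> float:
        """Signed depth change, positive downward."""
        return self.z1_m - self.z0_m

    @property
    def w_dvm_m_per_h(self) -> float:
        return abs(self.dz_m) / self.dt_h


@dataclass
class MigrationEvent:
    """One detected (or explicitly undetected) ascent or descent."""

    kind: str
    day: dt.date
    segments: List[RateSegment] = field(default_factory=list)
    status: str = STATUS_NOT_OBSERVED
    reason: Optional[str] = None

    @property
    def mean_rate_m_per_h(self) -> Optional[float]:
        if not self.segments:
            return None
        return float(np.mean([s.w_dvm_m_per_h for s in self.segments]))

    @property
    def max_rate_m_per_h(self) -> Optional[float]:
        """Maximum pairwise rate; absent when only two profiles resolve the event."""
        if len(self.segments) < 2:
            return None
        return float(max(s.w_dvm_m_per_h for s in self.segments))

    @property
    def net_dz_m(self) -> Optional[float]:
        if not self.segments:
            return None
        return self.segments[-1].z1_m - self.segments[0].z0_m


def zmax_track(profiles: Sequence[RelChlProfile]) -> List[TrackPoint]:
    """Time-ordered (time, z_max, homogeneous) track from profiles.

    Homogeneous profiles stay in the track but are marked for exclusion;
    rate computations skip them while spanning their elapsed time.
    """
    if len(profiles) < 2:
        raise ValidationError("a track needs at least 2 profiles")
    points = [
        TrackPoint(pd.Timestamp(p.time), float(p.z_max_m), bool(p.is_homogeneous))
        for p in profiles
    ]
    return sorted(points, key=lambda p: p.time)


def pairwise_rates(track: Sequence[TrackPoint]) -> List[RateSegment]:
    """One segment per consecutive pair of *retained* track points.

    ``delta t`` is true elapsed time, so excluded (homogeneous) profiles in
    between lengthen the segment rather than splitting it.
    """
    retained = [p for p in track if not p.is_homogeneous]
    times = [p.time for p in retained]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValidationError("track timestamps must be strictly increasing")
    return [
        RateSegment(t0=a.time, t1=b.time, z0_m=a.z_max_m, z1_m=b.z_max_m)
        for a, b in zip(retained, retained[1:])
    ]


def _window_bounds(
    window: MigrationWindow, day: dt.date, tz
) -> Tuple[pd.Timestamp, pd.Timestamp]:
    start = pd.Timestamp(dt.datetime.combine(day, window.start)).tz_localize(tz)
    end = pd.Timestamp(dt.datetime.combine(day, window.end)).tz_localize(tz)
    return start, end


def detect_event(
    track: Sequence[TrackPoint],
    window: MigrationWindow,
    day: dt.date,
    site_depth_m: float,
    surface_band_m: float = DEFAULT_SURFACE_BAND_M,
    bottom_band_m: float = DEFAULT_BOTTOM_BAND_M,
    grace_h: float = DEFAULT_GRACE_H,
) -> MigrationEvent:
    """Detect one migration event for ``day`` inside ``window``.

    For an ascent the departure band is the bottom band
    (``z >= site_depth - bottom_band``) and the arrival band is the surface
    band (``z <= surface_band``); descents are symmetric. The event runs from
    the last retained departure-band profile before arrival to the first
    retained arrival-band profile, both allowed to spill ``grace_h`` hours
    outside the clock window. When no such bracketing pair exists the event
    is reported as not observed.
    """
    if window.kind == ASCENT:
        in_departure = lambda z: z >= site_depth_m - bottom_band_m  # noqa: E731
        in_arrival = lambda z: z <= surface_band_m  # noqa: E731
    else:
        in_departure = lambda z: z <= surface_band_m  # noqa: E731
        in_arrival = lambda z: z >= site_depth_m - bottom_band_m  # noqa: E731

    retained = [p for p in track if not p.is_homogeneous]
    event = MigrationEvent(kind=window.kind, day=day)
    if not retained:
        event.reason = "all profiles homogeneous"
        return event

    tz = retained[0].time.tzinfo
    win_start, win_end = _window_bounds(window, day, tz)
    grace = pd.Timedelta(hours=grace_h)
    lo, hi = win_start - grace, win_end + grace

    if retained[0].time > win_end or retained[-1].time < win_start:
        event.reason = "insufficient coverage"
        return event

    start_pt = end_pt = None
    for cand in retained:
        if not (lo <= cand.time <= hi) or not in_arrival(cand.z_max_m):
            continue
        departures = [
            p for p in retained
            if lo <= p.time < cand.time and in_departure(p.z_max_m)
        ]
        if departures:
            start_pt, end_pt = departures[-1], cand
            break

    if start_pt is None:
        event.reason = "no bracketing departure/arrival pair"
        return event

    stretch = [p for p in retained if start_pt.time <= p.time <= end_pt.time]
    event.segments = pairwise_rates(stretch)
    event.status = (
        STATUS_MAX_SUPPRESSED if len(event.segments) == 1 else STATUS_OBSERVED
    )
    return event


def detect_events(
    track: Sequence[TrackPoint],
    site_depth_m: float,
    windows: Sequence[MigrationWindow] = (
        DEFAULT_ASCENT_WINDOW,
        DEFAULT_DESCENT_WINDOW,
    ),
    surface_band_m: float = DEFAULT_SURFACE_BAND_M,
    bottom_band_m: float = DEFAULT_BOTTOM_BAND_M,
    grace_h: float = DEFAULT_GRACE_H,
) -> List[MigrationEvent]:
    """One event per calendar day per window kind over the span of the track.

    Days whose window does not overlap the track at all yield no event;
    covered-but-undetected days yield a ``not_observed`` event.
    """
    track = sorted(track, key=lambda p: p.time)
    t_min, t_max = track[0].time, track[-1].time
    tz = t_min.tzinfo
    events = []
    day = t_min.date()
    while day <= t_max.date():
        for window in windows:
            win_start, win_end = _window_bounds(window, day, tz)
            grace = pd.Timedelta(hours=grace_h)
            if win_end + grace < t_min or win_start - grace > t_max:
                continue
            events.append(
                detect_event(
                    track, window, day, site_depth_m,
                    surface_band_m=surface_band_m,
                    bottom_band_m=bottom_band_m,
                    grace_h=grace_h,
                )
            )
        day += dt.timedelta(days=1)
    return events


def summarize_rates(
    events: Sequence[MigrationEvent], study: str = ""
) -> pd.DataFrame:
    """Tabulate events as one row each: study, day, kind, max, mean, status.

    Rates are magnitudes (m h^-1); the sign of the motion lives in the
    per-segment ``dz_m``.
    """
    if not events:
        raise ValidationError("no events to summarize")
    rows = []
    for ev in events:
        rows.append(
            {
                "study": study,
                "day": ev.day.isoformat(),
                "kind": ev.kind,
                "max_rate_m_per_h": ev.max_rate_m_per_h,
                "mean_rate_m_per_h": ev.mean_rate_m_per_h,
                "n_segments": len(ev.segments),
                "status": ev.status,
                "reason": ev.reason,
            }
        )
    return pd.DataFrame(rows)
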