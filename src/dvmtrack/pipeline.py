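"""End-to-end convenience wrappers: casts -> binned -> relative -> rates."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .calibration import (
    DEFAULT_BIN_WIDTH_M,
    CalibrationFit,
    apply_calibration,
    bin_profile,
)
from .cast_io import CastSeries
from .errors import DegenerateProfileError, EmptyProfileError
from .rates import (
    DEFAULT_ASCENT_WINDOW,
    DEFAULT_BOTTOM_BAND_M,
    DEFAULT_DESCENT_WINDOW,
    DEFAULT_GRACE_H,
    DEFAULT_SURFACE_BAND_M,
    MigrationEvent,
    MigrationWindow,
    detect_events,
    summarize_rates,
    zmax_track,
)
from .relchl import DEFAULT_CV_THRESHOLD_PERCENT, RelChlProfile, rel_chl


def rel_profiles_from_series(
    series: CastSeries,
    calibration: Optional[CalibrationFit] = None,
    bin_width_m: float = DEFAULT_BIN_WIDTH_M,
    cv_threshold_percent: float = DEFAULT_CV_THRESHOLD_PERCENT,
) -> List[RelChlProfile]:
    """Calibrate (if needed), bin, and normalise every cast in a series.

    Casts that come out degenerate (all-missing or zero-integral) are
    dropped rather than aborting the study.
    """
    profiles = []
    for cast in series:
        if calibration is not None:
            cast = apply_calibration(cast, calibration)
        try:
            binned = bin_profile(
                cast, bin_width_m=bin_width_m, bottom_depth_m=series.site_depth_m
            )
            profiles.append(
                rel_chl(binned, cv_threshold_percent=cv_threshold_percent)
            )
        except (EmptyProfileError, DegenerateProfileError):
            continue
    return profiles


def estimate_rates(
    series: CastSeries,
    calibration: Optional[CalibrationFit] = None,
    bin_width_m: float = DEFAULT_BIN_WIDTH_M,
    cv_threshold_percent: float = DEFAULT_CV_THRESHOLD_PERCENT,
    windows: Sequence[MigrationWindow] = (
        DEFAULT_ASCENT_WINDOW,
        DEFAULT_DESCENT_WINDOW,
    ),
    surface_band_m: float = DEFAULT_SURFACE_BAND_M,
    bottom_band_m: float = DEFAULT_BOTTOM_BAND_M,
    grace_h: float = DEFAULT_GRACE_H,
    study: str = "",
) -> Tuple[List[MigrationEvent], pd.DataFrame, List[RelChlProfile]]:
    """Full rate pipeline for one study; returns (events, table, profiles)."""
    profiles = rel_profiles_from_series(
        series,
        calibration=calibration,
        bin_width_m=bin_width_m,
        cv_threshold_percent=cv_threshold_percent,
    )
    track = zmax_track(profiles)
    events = detect_events(
        track,
        site_depth_m=series.site_depth_m,
        windows=windows,
        surface_band_m=surface_band_m,
        bottom_band_m=bottom_band_m,
        grace_h=grace_h,
    )
    table = summarize_rates(events, study=study)
    return events, table, profiles


def profile_diagnostics(profiles: Sequence[RelChlProfile]) -> pd.DataFrame:
    """Per-profile diagnostics table (z_max, CV, homogeneity, integral)."""
    return pd.DataFrame(
        {
            "cast_id": [p.cast_id for p in profiles],
            "time": [pd.Timestamp(p.time).isoformat() for p in profiles],
            "z_max_m": [p.z_max_m for p in profiles],
            "cv_percent": [p.cv_percent for p in profiles],
            "is_homogeneous": [p.is_homogeneous for p in profiles],
            "integral_mg_m2": [p.integral_mg_m2 for p in profiles],
        }
    )
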