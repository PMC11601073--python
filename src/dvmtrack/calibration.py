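"""Fluorescence-to-Chl-a calibration and fixed-width depth binning.

In situ sonde fluorescence is an uncalibrated proxy for chlorophyll *a*.
A linear calibration against extracted Chl-a from paired discrete samples
(one pooled fit per study) converts it to concentration units, after which
profiles are averaged into uniform depth bins (0.2 m by default) for all
downstream relative-chlorophyll work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats

from .cast_io import Cast
from .errors import CalibrationError, EmptyProfileError, StateError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_M = 0.2


@dataclass(frozen=True)
class CalibrationFit:
    """A linear map from raw fluorescence to Chl-a (ug L^-1)."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise CalibrationError("calibration needs at least 2 pairs")
        if not np.isfinite(self.slope):
            raise CalibrationError("calibration slope is not finite")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError("r_squared must lie in [0, 1]")

    def predict(self, fluorescence) -> np.ndarray:
        return self.slope * np.asarray(fluorescence, dtype=float) + self.intercept

    def to_yaml(self, path) -> str:
        payload = {
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "r_squared": float(self.r_squared),
            "n_pairs": int(self.n_pairs),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return str(path)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class BinnedProfile:
    """Chl-a averaged into uniform half-open depth bins ``[k*w, (k+1)*w)``.

    Empty bins are NaN, never interpolated; downstream operations skip them.
    """

    cast_id: str
    time: object
    bin_width_m: float
    bin_centers_m: np.ndarray
    chl_ug_L: np.ndarray
    bottom_depth_m: float

    def __post_init__(self) -> None:
        self.bin_centers_m = np.asarray(self.bin_centers_m, dtype=float)
        self.chl_ug_L = np.asarray(self.chl_ug_L, dtype=float)
        if self.bin_centers_m.shape != self.chl_ug_L.shape:
            raise ValidationError("bin centers and values differ in length")
        diffs = np.diff(self.bin_centers_m)
        if diffs.size and not np.allclose(diffs, self.bin_width_m, rtol=0, atol=1e-9):
            raise ValidationError("bin centers must be uniformly spaced")
        finite = self.chl_ug_L[np.isfinite(self.chl_ug_L)]
        if np.any(finite < 0):
            raise ValidationError("binned Chl-a must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.chl_ug_L).sum())


def fit_calibration(
    pairs: Sequence[Tuple[float, float]], through_origin: bool = False
) -> CalibrationFit:
    """Ordinary least squares of extracted Chl-a on sonde fluorescence.

    ``r_squared`` is the squared sample correlation of the pairs. Set
    ``through_origin`` to force a zero intercept (slope = sum(xy)/sum(x^2)).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise CalibrationError("need at least 2 (fluorescence, chl) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise CalibrationError("fluorescence values have zero variance")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        r = 0.0 if np.ptp(y) == 0 else float(np.corrcoef(x, y)[0, 1])
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=min(r * r, 1.0),
        n_pairs=int(arr.shape[0]),
    )


def apply_calibration(cast: Cast, fit: CalibrationFit) -> Cast:
    """Return a copy of ``cast`` with ``chl_ug_L = slope*F + intercept``.

    Negative predictions are clipped to zero (Chl-a is a concentration) with
    a logged warning; the raw fluorescence channel is retained.
    """
    if cast.fluorescence is None:
        raise StateError(f"cast {cast.cast_id!r} has no fluorescence channel")
    chl = fit.predict(cast.fluorescence)
    n_neg = int(np.sum(chl < 0))
    if n_neg:
        log.warning(
            "cast %r: clipped %d negative calibrated Chl-a values to 0",
            cast.cast_id, n_neg,
        )
        chl = np.clip(chl, 0.0, None)
    return replace(cast, chl_ug_L=chl)


def bin_profile(
    cast: Cast,
    bin_width_m: float = DEFAULT_BIN_WIDTH_M,
    bottom_depth_m: Optional[float] = None,
) -> BinnedProfile:
    """Average a cast's Chl-a into half-open depth bins anchored at 0 m.

    Bin k spans ``[k*w, (k+1)*w)`` with center ``(k+0.5)*w``; each bin holds
    the arithmetic mean of the in-bin samples. Samples at or below
    ``bottom_depth_m`` (default: the cast's deepest sample) are outside the
    integration domain and ignored.
    """
    if cast.chl_ug_L is None:
        raise StateError(
            f"cast {cast.cast_id!r} has no chl_ug_L channel; calibrate first"
        )
    if bin_width_m <= 0:
        raise ValidationError("bin_width_m must be positive")
    if bottom_depth_m is None:
        bottom_depth_m = float(cast.depth_m[-1])
    n_bins = int(np.ceil(bottom_depth_m / bin_width_m))
    if n_bins < 1:
        raise EmptyProfileError("bottom depth shallower than one bin")

    idx = np.floor(cast.depth_m / bin_width_m).astype(int)
    keep = (idx >= 0) & (idx < n_bins) & np.isfinite(cast.chl_ug_L)
    if not np.any(keep):
        raise EmptyProfileError(
            f"cast {cast.cast_id!r}: no samples fall inside the bin domain"
        )
    sums = np.bincount(idx[keep], weights=cast.chl_ug_L[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    centers = (np.arange(n_bins) + 0.5) * bin_width_m
    return BinnedProfile(
        cast_id=cast.cast_id,
        time=cast.time,
        bin_width_m=float(bin_width_m),
        bin_centers_m=centers,
        chl_ug_L=means,
        bottom_depth_m=float(bottom_depth_m),
    )
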