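"""Relative-chlorophyll profiles, the homogeneity screen, and z_max.

The relative chlorophyll profile normalises each binned Chl-a profile by its
own depth integral,

    rel_chl(z) = chl(z) / integral_0^d chl dz        [units m^-1],

so the vertical *shape* of the chlorophyll layer can be tracked across casts
independently of cast-to-cast changes in total biomass (advection of patchy
water past a fixed station). The depth of the relative-chlorophyll maximum,
``z_max``, is the layer-position estimate used for migration rates.

Profiles with a low coefficient of variation of binned Chl-a (default
<= 5 %) carry no identifiable maximum and are flagged homogeneous; flagged
profiles are excluded from all rate computations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import BinnedProfile
from .errors import DegenerateProfileError, EmptyProfileError

#: Profiles with CV of binned Chl-a at or below this percentage are treated
#: as vertically homogeneous and excluded from rate estimation.
DEFAULT_CV_THRESHOLD_PERCENT = 5.0

#: Minimum number of non-missing bins for a profile to be usable downstream.
MIN_VALID_BINS = 3


@dataclass
class RelChlProfile:
    """Output of the relative-chlorophyll transform for one cast."""

    cast_id: str
    time: object
    bin_width_m: float
    bin_centers_m: np.ndarray
    rel_chl_per_m: np.ndarray
    integral_mg_m2: float
    cv_percent: float
    z_max_m: float
    is_homogeneous: bool


def depth_integral(profile: BinnedProfile) -> float:
    """Depth-integrated Chl-a (mg m^-2) by the rectangle rule on uniform bins.

    1 ug L^-1 == 1 mg m^-3, so summing ``chl * bin_width`` over non-missing
    bins directly yields mg m^-2. Missing bins contribute nothing.
    """
    valid = np.isfinite(profile.chl_ug_L)
    if not np.any(valid):
        raise EmptyProfileError("profile has no non-missing bins")
    return float(np.sum(profile.chl_ug_L[valid]) * profile.bin_width_m)


def coefficient_of_variation(profile: BinnedProfile, ddof: int = 1) -> float:
    """CV (%) of the non-missing binned Chl-a values.

    Uses the sample (n-1) standard deviation by default; set ``ddof=0`` for
    the population convention.
    """
    values = profile.chl_ug_L[np.isfinite(profile.chl_ug_L)]
    if values.size < 2:
        raise DegenerateProfileError("CV needs at least 2 non-missing bins")
    mean = values.mean()
    if mean <= 0:
        raise DegenerateProfileError("CV undefined for zero-mean profile")
    return float(100.0 * values.std(ddof=ddof) / mean)


def find_zmax(
    rel: "RelChlProfile | BinnedProfile",
    tie_break: str = "shallowest",
    previous_z_max: Optional[float] = None,
) -> float:
    """Depth (bin center, m) of the maximum relative chlorophyll.

    Exact ties go to the shallowest tied bin by default, giving a
    deterministic answer; ``tie_break="nearest"`` instead picks the tied bin
    closest to ``previous_z_max`` (useful when chaining a track).
    """
    values = rel.rel_chl_per_m if isinstance(rel, RelChlProfile) else rel.chl_ug_L
    valid = np.isfinite(values)
    if not np.any(valid):
        raise EmptyProfileError("profile has no non-missing bins")
    vmax = np.nanmax(values)
    tied = np.flatnonzero(valid & (values == vmax))
    if tie_break == "nearest" and previous_z_max is not None and tied.size > 1:
        centers = rel.bin_centers_m[tied]
        return float(centers[np.argmin(np.abs(centers - previous_z_max))])
    # centers are sorted ascending, so the first tied index is the shallowest
    return float(rel.bin_centers_m[tied[0]])


def flag_homogeneous(
    cv_percent: float, threshold_percent: float = DEFAULT_CV_THRESHOLD_PERCENT
) -> bool:
    """True when a profile's CV is at or below the homogeneity threshold.

    The boundary itself (CV == threshold) counts as homogeneous.
    """
    return bool(cv_percent <= threshold_percent)


def rel_chl(
    profile: BinnedProfile,
    cv_threshold_percent: float = DEFAULT_CV_THRESHOLD_PERCENT,
    cv_ddof: int = 1,
) -> RelChlProfile:
    """Normalise a binned profile to relative chlorophyll and screen it.

    The result satisfies ``sum(rel * bin_width) == 1`` over non-missing bins.
    Raises :class:`DegenerateProfileError` for a zero integral or fewer than
    three usable bins.
    """
    if profile.n_valid < MIN_VALID_BINS:
        raise DegenerateProfileError(
            f"profile {profile.cast_id!r} has {profile.n_valid} non-missing "
            f"bins; need at least {MIN_VALID_BINS}"
        )
    integral = depth_integral(profile)
    if integral <= 0:
        raise DegenerateProfileError(
            f"profile {profile.cast_id!r} has zero depth-integrated Chl-a"
        )
    rel_values = profile.chl_ug_L / integral
    cv = coefficient_of_variation(profile, ddof=cv_ddof)
    out = RelChlProfile(
        cast_id=profile.cast_id,
        time=profile.time,
        bin_width_m=profile.bin_width_m,
        bin_centers_m=profile.bin_centers_m,
        rel_chl_per_m=rel_values,
        integral_mg_m2=integral,
        cv_percent=cv,
        z_max_m=np.nan,
        is_homogeneous=flag_homogeneous(cv, cv_threshold_percent),
    )
    out.z_max_m = find_zmax(out)
    return out
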