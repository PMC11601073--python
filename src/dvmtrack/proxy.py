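"""Validation of relative chlorophyll as a species-position proxy.

Bulk chlorophyll only tracks a single species' vertical movement when that
species dominates the phytoplankton community. Two checks support the proxy:

* *dominance gating* — a study is admissible when the focal taxon holds more
  than a threshold share (default 80 %) of total carbon biomass at study
  initiation;
* *depth-profile correlation* — across paired (cast, bottle-sample) depth
  points, relative chlorophyll should correlate positively (Spearman) with
  the focal taxon's relative cell abundance over depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cast_io import DiscreteSample
from .errors import ConfigurationError, UndefinedCorrelationError, ValidationError
from .relchl import RelChlProfile

log = logging.getLogger(__name__)

DEFAULT_DOMINANCE_THRESHOLD = 0.8
DEFAULT_MATCH_TOLERANCE_MIN = 30.0

#: Below this sample size the Spearman p-value is computed by exhaustive
#: permutation; above it, by the usual t approximation.
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class DominanceRecord:
    """Focal-taxon abundance and biomass share at one sampling time."""

    time: pd.Timestamp
    focal_taxon: str
    abundance_cells_mL: float
    biomass_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.biomass_fraction <= 1.0):
            raise ValidationError("biomass_fraction must lie in [0, 1]")
        if self.abundance_cells_mL < 0:
            raise ValidationError("abundance must be >= 0")


@dataclass(frozen=True)
class PairedDepthPoint:
    """One (relative chlorophyll, relative abundance) pair at a depth."""

    time: pd.Timestamp
    depth_m: float
    rel_chl_per_m: float
    rel_abundance_per_m: float


def biomass_fraction(sample: DiscreteSample, focal: str) -> float:
    """Focal taxon's share of total carbon biomass in one bottle sample.

    Requires a per-cell carbon weight for every taxon with a non-zero count;
    the result is invariant to rescaling all weights by a common factor.
    """
    if not sample.taxon_counts:
        raise ValidationError("sample has no taxon counts")
    weights = sample.carbon_per_cell or {}
    total = 0.0
    for taxon, count in sample.taxon_counts.items():
        if count == 0:
            continue
        if taxon not in weights:
            raise ConfigurationError(
                f"no carbon weight supplied for counted taxon {taxon!r}"
            )
        total += count * weights[taxon]
    if total == 0:
        raise ValidationError("sample has zero total biomass")
    focal_biomass = sample.taxon_counts.get(focal, 0.0) * weights.get(focal, 0.0)
    return float(focal_biomass / total)


def gate_study(
    records: Sequence[DominanceRecord],
    threshold: float = DEFAULT_DOMINANCE_THRESHOLD,
) -> Tuple[bool, pd.DataFrame]:
    """Admit a study iff its earliest record exceeds the dominance threshold.

    Later records below threshold are reported (and warned about) but do not
    invalidate a study that was initiated above threshold — dominance is a
    study-design precondition evaluated at initiation.
    """
    if not records:
        raise ValidationError("need at least one dominance record")
    ordered = sorted(records, key=lambda r: r.time)
    rows = [
        {
            "time": r.time,
            "focal_taxon": r.focal_taxon,
            "abundance_cells_mL": r.abundance_cells_mL,
            "biomass_fraction": r.biomass_fraction,
            "passes": r.biomass_fraction > threshold,
        }
        for r in ordered
    ]
    report = pd.DataFrame(rows)
    passed = bool(rows[0]["passes"])
    if passed and not report["passes"].all():
        log.warning(
            "study initiated above the %.0f%% dominance threshold but later "
            "records fall below it", 100 * threshold,
        )
    return passed, report


def _cell_widths(depths: np.ndarray) -> np.ndarray:
    """Local depth spacing for each sample (midpoint rule; np.gradient)."""
    if depths.size == 1:
        return np.array([1.0])
    return np.gradient(depths)


def pair_depth_points(
    rel_profiles: Sequence[RelChlProfile],
    samples: Sequence[DiscreteSample],
    focal: str,
    match_tolerance_min: float = DEFAULT_MATCH_TOLERANCE_MIN,
) -> List[PairedDepthPoint]:
    """Pair bottle-sample relative abundances with cast relative chlorophyll.

    Samples are grouped by timestamp into depth profiles (>= 2 depths each).
    Relative abundance of the focal taxon at depth i is
    ``count_i / sum_j(count_j * dz_j)`` with ``dz`` the local depth spacing,
    so that ``sum(rel_abundance * dz) == 1`` per profile — the same per-meter
    convention as relative chlorophyll. Each sample reads relative
    chlorophyll off the nearest bin center of the time-matched cast
    (tolerance ``match_tolerance_min``); unmatched or missing-bin points are
    dropped with a warning.
    """
    prof_times = np.array(
        [pd.Timestamp(p.time).value for p in rel_profiles], dtype=np.int64
    )
    tol = pd.Timedelta(minutes=match_tolerance_min)

    groups: dict = {}
    for s in samples:
        groups.setdefault(pd.Timestamp(s.time), []).append(s)

    points: List[PairedDepthPoint] = []
    for time, group in sorted(groups.items()):
        group = sorted(group, key=lambda s: s.depth_m)
        if len(group) < 2:
            continue
        counts = np.array(
            [g.taxon_counts.get(focal, 0.0) for g in group], dtype=float
        )
        depths = np.array([g.depth_m for g in group], dtype=float)
        widths = _cell_widths(depths)
        norm = float(np.sum(counts * widths))
        if norm <= 0:
            log.warning("profile at %s has zero focal counts; skipped", time)
            continue
        rel_abund = counts / norm

        deltas = np.abs(prof_times - time.value)
        j = int(np.argmin(deltas))
        if pd.Timedelta(int(deltas[j]), unit="ns") > tol:
            log.warning("no cast within %s of %s; profile dropped", tol, time)
            continue
        profile = rel_profiles[j]
        for depth, ra in zip(depths, rel_abund):
            k = int(np.argmin(np.abs(profile.bin_centers_m - depth)))
            rc = profile.rel_chl_per_m[k]
            if not np.isfinite(rc):
                log.warning(
                    "missing bin at %.2f m in cast %r; point dropped",
                    depth, profile.cast_id,
                )
                continue
            points.append(
                PairedDepthPoint(
                    time=time,
                    depth_m=float(depth),
                    rel_chl_per_m=float(rc),
                    rel_abundance_per_m=float(ra),
                )
            )
    return points


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all pairings of the (tie-averaged) ranks; evaluated in
    chunks so n = 10 (3.6M permutations) stays tractable.
    """
    n = rx.size
    rx_c = rx - rx.mean()
    sx = math.sqrt(float(np.dot(rx_c, rx_c)))
    ry_c = ry - ry.mean()
    sy = math.sqrt(float(np.dot(ry_c, ry_c)))
    total = math.factorial(n)
    hits = 0
    target = abs(rho_obs) - 1e-12
    chunk: List[Tuple] = []
    chunk_size = 100_000

    def flush(chunk_rows: List[Tuple]) -> int:
        arr = np.asarray(chunk_rows, dtype=float)
        rhos = (arr - ry.mean()) @ rx_c / (sx * sy)
        return int(np.sum(np.abs(rhos) >= target))

    for perm in permutations(ry_c + ry.mean()):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            hits += flush(chunk)
            chunk = []
    if chunk:
        hits += flush(chunk)
    return hits / total


def spearman_rho(
    points: "Sequence[PairedDepthPoint] | Tuple[np.ndarray, np.ndarray]",
) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    Accepts either paired depth points or an ``(x, y)`` tuple of arrays. For
    n <= 10 the p-value is an exact permutation probability; for larger n the
    standard t approximation is used.
    """
    if isinstance(points, tuple):
        x, y = (np.asarray(v, dtype=float) for v in points)
    else:
        x = np.array([p.rel_chl_per_m for p in points], dtype=float)
        y = np.array([p.rel_abundance_per_m for p in points], dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "Spearman correlation undefined for constant input"
        )
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
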