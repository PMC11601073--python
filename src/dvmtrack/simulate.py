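"""Synthetic water column: a 1-D migrating chlorophyll layer plus observation.

The forward model is a conservative advection--diffusion equation for a
Gaussian chlorophyll layer in a shallow (~6 m) water column, discretised
with first-order upwind advection (positivity-preserving) and explicit
diffusion on a uniform grid with no-flux boundaries. The layer's center
follows a diel schedule: it departs the bottom at the ascent-window start
and swims upward at ``v_ascend`` until it reaches a surface hold depth,
holds there, then departs at the descent-window start and swims downward at
``v_descend`` to a bottom hold depth. If a leg is not finished when its
clock window closes, swimming continues until the hold depth is reached, so
the trajectory closes on itself over a day at any realistic speed.

The observation operator emulates a profiling sonde at a fixed station:

    observed(z) = L_t * conc(z) * eps(z) + background,

with ``L_t`` a per-cast lognormal factor (advection of a patchy bloom past
the station — the variability the relative-chlorophyll transform exists to
cancel) and ``eps`` per-depth multiplicative lognormal sensor noise. Casts
are emitted at grid resolution for later binning. Optional "homogeneous
episodes" replace the water column with its depth mean before observation,
exercising the CV screen. Discrete bottle samples draw Poisson counts of a
dominant focal taxon proportional to the local layer concentration, plus a
uniformly distributed background taxon scaled to a target biomass fraction.

All randomness flows from one seed through three documented substreams
(sensor noise, per-cast heterogeneity, bottle counts), so switching
heterogeneity on or off does not perturb the sensor-noise draws.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cast_io import Cast, CastSeries, DiscreteSample
from .errors import ConfigurationError

LOCAL_TZ = "UTC-04:00"


def _clock(text: "str | dt.time") -> dt.time:
    if isinstance(text, dt.time):
        return text
    return dt.time.fromisoformat(text)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal draws; consumes the same normals for any cv (cv=0 -> 1)."""
    z = rng.standard_normal(size)
    s = _lognormal_sigma(cv)
    return np.exp(s * z - 0.5 * s * s)


@dataclass
class SimulationConfig:
    """Stated world of the synthetic Diel Study.

    Defaults mirror the field setting the package targets: a 6 m estuarine
    station profiled every 1--2 h, a bloom layer swimming at ~1.3 m/h (the
    observed mean for both legs), ascents 04:00--09:00 and descents
    16:00--20:00 local time, and a focal dinoflagellate at ~90 % of carbon
    biomass.
    """

    site_depth_m: float = 6.0
    grid_dz_m: float = 0.05
    step_dt_s: float = 30.0
    v_ascend_m_per_h: float = 1.3
    v_descend_m_per_h: float = 1.3
    ascent_start: str = "04:00"
    ascent_end: str = "09:00"
    descent_start: str = "16:00"
    descent_end: str = "20:00"
    diffusivity_m2_per_h: float = 0.1
    background_chl_ug_L: float = 1.0
    layer_sigma_m: float = 0.3
    layer_mass_mg_m2: float = 60.0
    hold_band_m: float = 0.5
    obs_noise_cv: float = 0.1
    heterogeneity_cv: float = 0.3
    cast_interval_h: float = 1.0
    n_days: int = 1
    homogeneous_episodes: list = field(default_factory=list)  # [[start_h, end_h], ...]
    seed: int = 0
    start_date: str = "2021-08-06"
    focal_taxon: str = "Mpoly"
    background_taxon: str = "other"
    focal_fraction: float = 0.9
    carbon_pg_per_cell: dict = field(
        default_factory=lambda: {"Mpoly": 2000.0, "other": 50.0}
    )
    count_per_chl: float = 40.0  # cells mL^-1 per ug L^-1 for the focal taxon

    def __post_init__(self) -> None:
        if self.site_depth_m <= self.layer_sigma_m:
            raise ConfigurationError("site depth must exceed the layer width")
        if self.layer_sigma_m >= self.hold_band_m:
            raise ConfigurationError(
                "layer_sigma_m must be smaller than hold_band_m, otherwise the "
                "depth-keeping deadband reaches the boundary and the layer "
                "piles up against it"
            )
        if self.obs_noise_cv < 0 or self.heterogeneity_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")
        if not (1.0 <= self.cast_interval_h <= 2.0):
            raise ConfigurationError("cast_interval_h must lie in [1, 2] hours")
        if not (0 < self.focal_fraction < 1):
            raise ConfigurationError("focal_fraction must lie in (0, 1)")
        v_max = max(self.v_ascend_m_per_h, self.v_descend_m_per_h) / 3600.0
        k = self.diffusivity_m2_per_h / 3600.0
        # combined advective + diffusive condition; the sum (not each part
        # alone) is what guarantees positivity of the explicit update
        courant = (
            v_max * self.step_dt_s / self.grid_dz_m
            + 2.0 * k * self.step_dt_s / self.grid_dz_m ** 2
        )
        if courant > 1.0 + 1e-12:
            raise ConfigurationError(
                f"CFL violated: v*dt/dz + 2*K*dt/dz^2 = {courant:.3f} > 1; "
                "reduce step_dt_s or diffusivity"
            )

    # -- clock helpers -----------------------------------------------------
    @property
    def ascent_start_time(self) -> dt.time:
        return _clock(self.ascent_start)

    @property
    def descent_start_time(self) -> dt.time:
        return _clock(self.descent_start)

    @property
    def surface_hold_m(self) -> float:
        return self.hold_band_m

    @property
    def bottom_hold_m(self) -> float:
        return self.site_depth_m - self.hold_band_m

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return str(path)

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(
                f"unknown simulator config keys: {sorted(unknown)}"
            )
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside the synthetic casts."""

    times: List[pd.Timestamp]
    true_center_depth_m: np.ndarray
    true_velocity_m_per_h: np.ndarray
    heterogeneity_factors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [t.isoformat() for t in self.times],
                "true_center_depth_m": self.true_center_depth_m,
                "true_velocity_m_per_h": self.true_velocity_m_per_h,
                "heterogeneity_factor": self.heterogeneity_factors,
            }
        )

    def to_csv(self, path) -> str:
        self.to_frame().to_csv(path, index=False)
        return str(path)


def grid_centers(cfg: SimulationConfig) -> np.ndarray:
    n = int(round(cfg.site_depth_m / cfg.grid_dz_m))
    return (np.arange(n) + 0.5) * cfg.grid_dz_m


def initial_field(cfg: SimulationConfig, center_m: float) -> np.ndarray:
    """Gaussian layer of fixed depth-integrated mass at ``center_m``."""
    z = grid_centers(cfg)
    amp = cfg.layer_mass_mg_m2 / (cfg.layer_sigma_m * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((z - center_m) / cfg.layer_sigma_m) ** 2)


def velocity_schedule(
    t: pd.Timestamp, cfg: SimulationConfig, current_center: float
) -> float:
    """Signed layer velocity (m/h, positive downward) at time ``t``.

    The day splits into an ascent phase (ascent start to descent start) and a
    descent phase (the remainder). In each phase the layer swims toward its
    hold depth at the configured speed and holds once there; swimming thus
    continues past the nominal window end if the hold depth has not been
    reached, so the daily loop always closes.
    """
    clock = t.time()
    in_ascent_phase = cfg.ascent_start_time <= clock < cfg.descent_start_time
    eps = 1e-9
    if in_ascent_phase:
        return -cfg.v_ascend_m_per_h if current_center > cfg.surface_hold_m + eps else 0.0
    return cfg.v_descend_m_per_h if current_center < cfg.bottom_hold_m - eps else 0.0


def step_population(
    conc: np.ndarray,
    v_m_per_h: "float | np.ndarray",
    k_m2_per_h: float,
    dt_s: float,
    dz_m: float,
) -> np.ndarray:
    """Advance the concentration field one explicit step.

    Finite-volume first-order upwind advection plus centered diffusion with
    zero-flux (reflective) boundaries; exactly mass conserving by
    construction. ``v_m_per_h`` is either a uniform scalar velocity or an
    array of per-face velocities (length ``n + 1``; the boundary faces are
    forced to zero flux regardless). Raises on a CFL violation instead of
    going unstable.
    """
    n = conc.size
    k = k_m2_per_h / 3600.0
    v = np.asarray(v_m_per_h, dtype=float) / 3600.0
    if v.ndim == 0:
        v = np.full(n + 1, float(v))
    elif v.shape != (n + 1,):
        raise ConfigurationError("face velocity array must have length n + 1")
    courant = np.max(np.abs(v)) * dt_s / dz_m + 2.0 * k * dt_s / dz_m ** 2
    if courant > 1.0 + 1e-12:
        raise ConfigurationError("CFL violated in step_population")
    flux = np.zeros(n + 1)
    vf = v[1:n]
    flux[1:n] = np.where(vf > 0, vf * conc[:-1], vf * conc[1:])
    if k > 0:
        flux[1:n] -= k * np.diff(conc) / dz_m
    return conc - (dt_s / dz_m) * np.diff(flux)


def swimming_velocity_field(
    cfg: SimulationConfig,
    t: pd.Timestamp,
    center_m: float,
    v_sched_m_per_h: Optional[float] = None,
) -> np.ndarray:
    """Per-face swimming velocity (m/h, positive down) for the whole column.

    The population translates at the scheduled velocity plus a restoring
    component proportional to distance from the layer center (full leg speed
    one layer width away, capped at the faster leg speed). This active
    depth-keeping is what keeps a migrating dinoflagellate layer coherent:
    without it, diffusion plus reflection at the no-flux boundaries slowly
    displaces the concentration maximum off the layer center, and the
    chlorophyll maximum would stop tracking the layer.
    """
    if v_sched_m_per_h is None:
        v_sched_m_per_h = velocity_schedule(t, cfg, center_m)
    clock = t.time()
    in_ascent_phase = cfg.ascent_start_time <= clock < cfg.descent_start_time
    v_restore = cfg.v_ascend_m_per_h if in_ascent_phase else cfg.v_descend_m_per_h
    v_cap = max(cfg.v_ascend_m_per_h, cfg.v_descend_m_per_h)
    z_faces = np.arange(
        int(round(cfg.site_depth_m / cfg.grid_dz_m)) + 1
    ) * cfg.grid_dz_m
    w = v_sched_m_per_h + (v_restore / cfg.layer_sigma_m) * (center_m - z_faces)
    return np.clip(w, -v_cap, v_cap)


def _seed_streams(seed: int) -> Tuple[np.random.Generator, ...]:
    """(sensor noise, heterogeneity, bottle counts) substreams from one seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def sample_cast(
    conc: np.ndarray,
    t: pd.Timestamp,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    heterogeneity_factor: float = 1.0,
    cast_id: str = "sim",
) -> Cast:
    """Observe the field as one sonde cast at grid resolution.

    ``observed = L * conc * eps + background`` with per-depth lognormal
    ``eps`` drawn from ``rng``; temperature and salinity are cosmetic
    diel/tidal sinusoids.
    """
    z = grid_centers(cfg)
    eps = _unit_mean_lognormal(rng, cfg.obs_noise_cv, conc.size)
    observed = heterogeneity_factor * conc * eps + cfg.background_chl_ug_L
    hour = t.hour + t.minute / 60.0
    temperature = (
        28.0
        + 1.5 * np.cos(2.0 * np.pi * (hour - 16.0) / 24.0) * np.exp(-z / 3.0)
    )
    salinity = 22.0 + 1.0 * np.sin(2.0 * np.pi * hour / 12.42) * (z / cfg.site_depth_m)
    return Cast(
        cast_id=cast_id,
        time=t,
        depth_m=z,
        fluorescence=observed,
        chl_ug_L=observed,
        temperature_C=temperature,
        salinity_PSU=salinity,
    )


def _in_episode(hours_since_start: float, episodes: Sequence[Sequence[float]]) -> bool:
    return any(a <= hours_since_start <= b for a, b in episodes)


def generate_series(
    cfg: SimulationConfig,
) -> Tuple[CastSeries, TruthRecord, Dict[pd.Timestamp, np.ndarray]]:
    """Run the forward model and observe it as a cast series.

    Deterministic given ``cfg.seed``. Returns the series, the ground-truth
    trajectory at cast times, and the noise-free concentration field at each
    cast time (for bottle-sample generation).
    """
    rng_noise, rng_het, _ = _seed_streams(cfg.seed)
    start = pd.Timestamp(f"{cfg.start_date}T00:00:00{LOCAL_TZ[3:]}")

    total_h = 24.0 * cfg.n_days
    n_steps = int(round(total_h * 3600.0 / cfg.step_dt_s))
    cast_every = cfg.cast_interval_h * 3600.0

    center = cfg.bottom_hold_m
    conc = initial_field(cfg, center)

    casts: List[Cast] = []
    fields: Dict[pd.Timestamp, np.ndarray] = {}
    truth_t: List[pd.Timestamp] = []
    truth_c: List[float] = []
    truth_v: List[float] = []
    truth_l: List[float] = []

    def observe(step: int) -> None:
        elapsed_s = step * cfg.step_dt_s
        t = start + pd.Timedelta(seconds=elapsed_s)
        het = float(_unit_mean_lognormal(rng_het, cfg.heterogeneity_cv, 1)[0])
        field_now = conc
        if _in_episode(elapsed_s / 3600.0, cfg.homogeneous_episodes):
            field_now = np.full_like(conc, conc.mean())
        cast = sample_cast(
            field_now, t, cfg, rng_noise,
            heterogeneity_factor=het,
            cast_id=f"sim-{len(casts):03d}",
        )
        casts.append(cast)
        fields[t] = field_now.copy()
        truth_t.append(t)
        truth_c.append(center)
        truth_v.append(velocity_schedule(t, cfg, center))
        truth_l.append(het)

    next_cast_s = 0.0
    for step in range(n_steps + 1):
        elapsed_s = step * cfg.step_dt_s
        if elapsed_s + 1e-6 >= next_cast_s:
            observe(step)
            next_cast_s += cast_every
        if step == n_steps:
            break
        t = start + pd.Timedelta(seconds=elapsed_s)
        v = velocity_schedule(t, cfg, center)
        new_center = center + v * cfg.step_dt_s / 3600.0
        new_center = min(max(new_center, cfg.surface_hold_m), cfg.bottom_hold_m)
        # advect with the realised center displacement so field and truth
        # stay aligned even on the arrival step where the hold clamps v
        v_eff = (new_center - center) * 3600.0 / cfg.step_dt_s
        w = swimming_velocity_field(cfg, t, center, v_sched_m_per_h=v_eff)
        conc = step_population(
            conc, w, cfg.diffusivity_m2_per_h, cfg.step_dt_s, cfg.grid_dz_m
        )
        center = new_center

    series = CastSeries(casts=casts, site_depth_m=cfg.site_depth_m)
    truth = TruthRecord(
        times=truth_t,
        true_center_depth_m=np.asarray(truth_c),
        true_velocity_m_per_h=np.asarray(truth_v),
        heterogeneity_factors=np.asarray(truth_l),
    )
    return series, truth, fields


def generate_discrete_samples(
    cfg: SimulationConfig,
    fields: Dict[pd.Timestamp, np.ndarray],
    times: Sequence[pd.Timestamp],
    depths: Sequence[float],
    rng: Optional[np.random.Generator] = None,
) -> List[DiscreteSample]:
    """Draw bottle samples from the noise-free fields at cast times.

    Focal counts are Poisson with rate ``count_per_chl * conc(depth)``; a
    background taxon is Poisson with a depth-uniform rate chosen so the
    focal taxon's expected column biomass fraction matches
    ``cfg.focal_fraction``.
    """
    if rng is None:
        rng = _seed_streams(cfg.seed)[2]
    z = grid_centers(cfg)
    carbon_focal = cfg.carbon_pg_per_cell[cfg.focal_taxon]
    carbon_bg = cfg.carbon_pg_per_cell[cfg.background_taxon]
    f = cfg.focal_fraction

    samples: List[DiscreteSample] = []
    for t in times:
        if t not in fields:
            raise ConfigurationError(f"no simulated field at requested time {t}")
        conc = fields[t]
        mean_focal_biomass = cfg.count_per_chl * float(conc.mean()) * carbon_focal
        bg_rate = mean_focal_biomass * (1.0 - f) / (f * carbon_bg)
        for depth in depths:
            j = int(np.argmin(np.abs(z - depth)))
            lam = cfg.count_per_chl * conc[j]
            focal_count = int(rng.poisson(lam)) if lam > 0 else 0
            bg_count = int(rng.poisson(bg_rate)) if bg_rate > 0 else 0
            samples.append(
                DiscreteSample(
                    time=t,
                    depth_m=float(depth),
                    taxon_counts={
                        cfg.focal_taxon: focal_count,
                        cfg.background_taxon: bg_count,
                    },
                    carbon_per_cell=dict(cfg.carbon_pg_per_cell),
                )
            )
    return samples
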