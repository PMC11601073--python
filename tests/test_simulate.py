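import numpy as np
import pandas as pd
import pytest

from dvmtrack import (
    SimulationConfig,
    generate_discrete_samples,
    generate_series,
    rel_profiles_from_series,
    sample_cast,
    step_population,
    velocity_schedule,
    write_cast_series,
)
from dvmtrack.errors import ConfigurationError
from dvmtrack.simulate import grid_centers, initial_field

TZ = "-04:00"


def ts(hour, minute=0):
    return pd.Timestamp(f"2021-08-06T{hour:02d}:{minute:02d}:00{TZ}")


class TestConfig:
    def test_cfl_violations_rejected_at_construction(self):
        with pytest.raises(ConfigurationError, match="CFL"):
            SimulationConfig(v_ascend_m_per_h=8.0, step_dt_s=120.0)
        with pytest.raises(ConfigurationError, match="CFL"):
            SimulationConfig(diffusivity_m2_per_h=1.0)

    def test_layer_must_fit_inside_hold_band(self):
        with pytest.raises(ConfigurationError, match="hold_band"):
            SimulationConfig(layer_sigma_m=0.6, hold_band_m=0.5)

    def test_yaml_round_trip_exact(self, tmp_path):
        cfg = SimulationConfig(seed=5, v_ascend_m_per_h=2.5, step_dt_s=20.0,
                               homogeneous_episodes=[[10.0, 12.0]])
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "sim.yaml") == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="swim_speed"):
            SimulationConfig.from_dict({"swim_speed": 3})


class TestVelocitySchedule:
    def test_ascending_inside_ascent_window(self):
        cfg = SimulationConfig()
        assert velocity_schedule(ts(5), cfg, 5.0) == -cfg.v_ascend_m_per_h

    def test_surface_hold_at_noon(self):
        cfg = SimulationConfig()
        assert velocity_schedule(ts(12), cfg, cfg.surface_hold_m) == 0.0

    def test_descending_in_descent_window(self):
        cfg = SimulationConfig()
        assert velocity_schedule(ts(17), cfg, 2.0) == cfg.v_descend_m_per_h

    @pytest.mark.parametrize("v", [1.0, 1.3, 2.5])
    def test_daily_loop_closes(self, v):
        # integrating the schedule over 24 h returns the center to its start
        cfg = SimulationConfig(v_ascend_m_per_h=v, v_descend_m_per_h=v,
                               step_dt_s=20.0)
        center = cfg.bottom_hold_m
        t = ts(0)
        dt_h = cfg.step_dt_s / 3600.0
        for _ in range(int(24 / dt_h)):
            center += velocity_schedule(t, cfg, center) * dt_h
            center = min(max(center, cfg.surface_hold_m), cfg.bottom_hold_m)
            t += pd.Timedelta(seconds=cfg.step_dt_s)
        assert abs(center - cfg.bottom_hold_m) <= cfg.grid_dz_m


class TestStepPopulation:
    def test_identity_with_no_velocity_or_diffusion(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0, 10, 120)
        out = step_population(conc, 0.0, 0.0, 30.0, 0.05)
        np.testing.assert_array_equal(out, conc)

    def test_mass_conserved_over_many_steps(self, quiet_sim_config):
        cfg = quiet_sim_config
        conc = initial_field(cfg, 3.0)
        mass0 = conc.sum() * cfg.grid_dz_m
        for i in range(10_000):
            v = 1.3 if (i // 500) % 2 == 0 else -1.3
            conc = step_population(
                conc, v, cfg.diffusivity_m2_per_h, cfg.step_dt_s, cfg.grid_dz_m
            )
        assert conc.sum() * cfg.grid_dz_m == pytest.approx(mass0, rel=1e-8)
        assert conc.min() >= 0

    def test_diffusion_variance_grows_like_heat_kernel(self):
        # narrow pulse, K > 0, v = 0: var(t) = var(0) + 2Kt pre-boundary
        cfg = SimulationConfig(diffusivity_m2_per_h=0.1, layer_sigma_m=0.1)
        z = grid_centers(cfg)
        conc = initial_field(cfg, 3.0)

        def variance(c):
            m = np.sum(c)
            mu = np.sum(z * c) / m
            return np.sum((z - mu) ** 2 * c) / m

        v0 = variance(conc)
        hours = 2.0
        n = int(hours * 3600 / cfg.step_dt_s)
        for _ in range(n):
            conc = step_population(
                conc, 0.0, cfg.diffusivity_m2_per_h, cfg.step_dt_s, cfg.grid_dz_m
            )
        expected = v0 + 2 * cfg.diffusivity_m2_per_h * hours
        assert variance(conc) == pytest.approx(expected, rel=0.05)

    def test_cfl_violation_raises(self):
        conc = np.ones(120)
        with pytest.raises(ConfigurationError):
            step_population(conc, 8.0, 0.0, 120.0, 0.05)


class TestSampleCast:
    def test_zero_noise_reproduces_field(self, quiet_sim_config):
        cfg = quiet_sim_config
        conc = initial_field(cfg, 4.0)
        rng = np.random.default_rng(0)
        cast = sample_cast(conc, ts(10), cfg, rng)
        np.testing.assert_allclose(
            cast.chl_ug_L, conc + cfg.background_chl_ug_L
        )

    def test_heterogeneity_cancels_in_rel_chl(self):
        # scale invariance end to end: a pure per-cast biomass factor leaves
        # the relative-chlorophyll profile unchanged
        from dvmtrack import bin_profile, rel_chl

        cfg = SimulationConfig(
            obs_noise_cv=0.0, heterogeneity_cv=0.0, background_chl_ug_L=0.0
        )
        conc = initial_field(cfg, 4.0)
        rng = np.random.default_rng(0)
        plain = sample_cast(conc, ts(10), cfg, rng, heterogeneity_factor=1.0)
        scaled = sample_cast(conc, ts(10), cfg, rng, heterogeneity_factor=2.7)
        rel_a = rel_chl(bin_profile(plain, 0.2, cfg.site_depth_m))
        rel_b = rel_chl(bin_profile(scaled, 0.2, cfg.site_depth_m))
        np.testing.assert_allclose(
            rel_b.rel_chl_per_m, rel_a.rel_chl_per_m, rtol=1e-9
        )

    def test_noise_factor_is_unit_mean(self):
        cfg = SimulationConfig(obs_noise_cv=0.3, background_chl_ug_L=0.0)
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [
                sample_cast(
                    np.ones(grid_centers(cfg).size), ts(10), cfg, rng
                ).chl_ug_L
                for _ in range(80)
            ]
        )
        assert draws.mean() == pytest.approx(1.0, abs=0.01)


class TestGenerateSeries:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimulationConfig(seed=17)
        s1, _, _ = generate_series(cfg)
        s2, _, _ = generate_series(cfg)
        p1 = write_cast_series(s1, tmp_path / "a.csv")
        p2 = write_cast_series(s2, tmp_path / "b.csv")
        assert open(p1, "rb").read() == open(p2, "rb").read()

    def test_cast_count_24h_hourly(self):
        series, truth, _ = generate_series(SimulationConfig(seed=0))
        assert 24 <= len(series) <= 25
        assert len(truth.times) == len(series)

    def test_truth_trajectory_bounded(self):
        cfg = SimulationConfig(seed=2)
        _, truth, _ = generate_series(cfg)
        assert truth.true_center_depth_m.min() >= 0
        assert truth.true_center_depth_m.max() <= cfg.site_depth_m
        assert np.max(np.abs(truth.true_velocity_m_per_h)) <= max(
            cfg.v_ascend_m_per_h, cfg.v_descend_m_per_h
        )

    def test_homogeneous_episode_flagged_downstream(self):
        cfg = SimulationConfig(
            seed=0, obs_noise_cv=0.0, homogeneous_episodes=[[10.0, 12.0]]
        )
        series, _, _ = generate_series(cfg)
        profiles = rel_profiles_from_series(series)
        flagged_hours = {
            pd.Timestamp(p.time).hour for p in profiles if p.is_homogeneous
        }
        # every cast inside the mixing episode is flagged (noise-free, so
        # no extra false negatives inside the episode)
        assert {10, 11, 12} <= flagged_hours


class TestGenerateDiscreteSamples:
    def test_zero_concentration_gives_zero_counts(self):
        cfg = SimulationConfig(seed=0, background_chl_ug_L=0.0)
        t = ts(0)
        fields = {t: np.zeros(grid_centers(cfg).size)}
        samples = generate_discrete_samples(cfg, fields, [t], [1.0, 3.0])
        assert all(s.taxon_counts[cfg.focal_taxon] == 0 for s in samples)

    def test_large_kappa_recovers_relative_profile(self):
        # law of large numbers: counts converge to the concentration shape
        cfg = SimulationConfig(seed=0, count_per_chl=1e5)
        t = ts(4)
        conc = initial_field(cfg, 3.0)
        fields = {t: conc}
        depths = [1.0, 2.0, 3.0, 4.0, 5.0]
        samples = generate_discrete_samples(cfg, fields, [t], depths)
        z = grid_centers(cfg)
        for s in samples:
            j = int(np.argmin(np.abs(z - s.depth_m)))
            expected = cfg.count_per_chl * conc[j]
            if expected > 1000:
                assert s.taxon_counts[cfg.focal_taxon] == pytest.approx(
                    expected, rel=0.05
                )

    def test_focal_fraction_approximately_achieved(self):
        from dvmtrack import biomass_fraction

        from dvmtrack import DiscreteSample

        cfg = SimulationConfig(seed=1)
        series, _, fields = generate_series(cfg)
        times = list(fields.keys())[::4]
        depths = [0.5, 1.5, 3.0, 4.5, 5.5]
        samples = generate_discrete_samples(cfg, fields, times, depths)
        # dominance is a whole-column property: pool counts over depths
        fracs = []
        for t in times:
            pooled = {cfg.focal_taxon: 0.0, cfg.background_taxon: 0.0}
            for s in samples:
                if s.time == t:
                    for taxon, c in s.taxon_counts.items():
                        pooled[taxon] += c
            fracs.append(
                biomass_fraction(
                    DiscreteSample(
                        time=t, depth_m=0.25, taxon_counts=pooled,
                        carbon_per_cell=cfg.carbon_pg_per_cell,
                    ),
                    cfg.focal_taxon,
                )
            )
        assert all(0.8 <= f <= 1.0 for f in fracs)
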