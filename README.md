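# dvmtrack

Estimate diel vertical migration (DVM) rates of a bloom-dominant
phytoplankton species from repeated vertical chlorophyll-fluorescence
profiles.

Many harmful-algal-bloom dinoflagellates (e.g. *Margalefidinium
polykrikoides* in shallow estuaries) swim to the surface around dawn and
back to the bottom around dusk. When one species dominates the phytoplankton
community, the vertical chlorophyll-*a* distribution tracks that species'
position, and a time series of sonde casts at a fixed station can measure
how fast the population swims. This package implements that measurement as
a tested pipeline, together with a synthetic water-column generator so every
stage can be verified by parameter recovery.

## Method

Each cast's calibrated Chl-a profile is averaged into 0.2 m depth bins and
normalised by its own depth integral,

    Rel_CHL(z) = Chl-a(z) / ∫₀ᵈ Chl-a dz        [m⁻¹],

which removes cast-to-cast changes in total biomass (patchy bloom water
advecting past the station) while preserving the vertical *shape*. The depth
of the Rel_CHL maximum, z_MAX, is the layer-position estimate. Profiles
whose binned Chl-a coefficient of variation is ≤ 5 % are flagged vertically
homogeneous — no identifiable maximum — and excluded from rate work. The
migration rate between adjacent retained profiles is

    w_DVM = |Δz_MAX| / Δt        [m h⁻¹].

Ascent (default 04:00–09:00 local) and descent (16:00–20:00) events are
bounded by the last retained profile in the departure band (within 1 m of
the bottom for ascents, upper 1 m for descents) and the first retained
profile in the arrival band. An event reports the unweighted mean of its
pairwise rates; the maximum rate is reported only when more than two
profiles resolve the event. When no bracketing departure/arrival pair
exists, the event is reported as *not observed* rather than forced.

Proxy validity is checked two ways: dominance gating (the focal taxon must
exceed 80 % of total carbon biomass at study initiation, computed from cell
counts and per-cell carbon weights) and the Spearman rank correlation
between Rel_CHL and the focal taxon's relative depth abundance across paired
bottle samples.

The simulator advances a Gaussian chlorophyll layer through a 1-D
conservative advection–diffusion model (first-order upwind, explicit
diffusion, no-flux boundaries) on a diel swimming schedule with active
depth-keeping, then observes it like a sonde: per-cast lognormal biomass
factors, per-depth lognormal sensor noise, additive background chlorophyll,
and optional fully mixed episodes to exercise the CV screen.

## Worked example

```python
from dvmtrack import SimulationConfig, generate_series, estimate_rates

cfg = SimulationConfig(seed=42, v_ascend_m_per_h=1.3, v_descend_m_per_h=1.3)
series, truth, _ = generate_series(cfg)        # 25 hourly casts, 6 m column
events, table, profiles = estimate_rates(series, study="demo")
print(table.drop(columns=["reason"]).to_string(index=False))
```

```
study        day    kind  max_rate_m_per_h  mean_rate_m_per_h  n_segments   status
 demo 2021-08-06  ascent               1.4               1.20           4 observed
 demo 2021-08-06 descent               1.4               1.25           4 observed
```

The layer truly swims at 1.3 m h⁻¹ in both directions. The recovered mean
rates (1.20 and 1.25 m h⁻¹) differ from truth by less than the depth-bin
quantisation (±0.1 m per profile, i.e. ±0.2 m h⁻¹ on an hourly pairwise
rate); each event is resolved by 4 segments, so maxima are reported too.

The same pipeline runs from the shell on CSV casts:

```sh
dvmtrack simulate -c config.yaml        # synthetic casts + truth + bottles
dvmtrack rates -c config.yaml           # rate table + per-profile diagnostics
dvmtrack validate-proxy -c config.yaml  # Spearman rho of the species proxy
dvmtrack calibrate -c config.yaml       # fluorescence -> Chl-a fit
```

One YAML config drives all commands; every run writes a `manifest.json`
(config hash, seed, package version) so outputs are exactly reproducible.

## Acceptance script

`scripts/acceptance.py` re-runs the package's core computation from scratch:
it simulates studies at true speeds 1.0, 1.3 and 2.5 m h⁻¹ with hourly
casts, 0.2 m bins and 10 % sensor noise, runs the full pipeline, prints the
recovered mean event rates per speed, and validates the proxy correlation on
synthetic bottle samples, writing its results JSON to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/dvmtrack/cast_io.py` — cast / bottle-sample CSV dialects, validation
- `src/dvmtrack/calibration.py` — fluorescence calibration, depth binning
- `src/dvmtrack/relchl.py` — Rel_CHL transform, CV screen, z_MAX
- `src/dvmtrack/rates.py` — event detection, pairwise/mean/max rates
- `src/dvmtrack/proxy.py` — dominance gating, depth-paired Spearman
- `src/dvmtrack/simulate.py` — synthetic water column and observation model
- `src/dvmtrack/pipeline.py`, `src/dvmtrack/cli.py` — wiring and CLI
- `docs/methods.md` — model description, parameter choices, limitations
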