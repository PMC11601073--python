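# Methods

## The estimation problem

A vertically migrating dinoflagellate layer is observed through repeated
sonde casts at a fixed station in a shallow (~6 m) estuary. The quantity of
interest is the swimming speed of the population during its dawn ascent and
dusk descent. Absolute chlorophyll cannot be tracked directly because the
total biomass seen at a fixed point changes from cast to cast as patchy
bloom water advects past; the relative chlorophyll profile

    Rel_CHL(z) = Chl-a(z) / ∫₀ᵈ Chl-a dz

is invariant to any per-cast multiplicative factor, so the depth of its
maximum (z_MAX) tracks the layer position under the assumption that the
migration behaviour itself is spatially uniform near the station. Migration
rate is the first difference of z_MAX over elapsed time between retained
profiles.

### Assumptions

1. One species dominates chlorophyll (gated at > 80 % of carbon biomass at
   study initiation), so bulk Chl-a is a species proxy.
2. Migration timing/speed is the same in all water parcels near the station;
   heterogeneity only rescales each profile.
3. A single well-defined chlorophyll maximum exists; profiles without one
   (coefficient of variation of binned Chl-a ≤ 5 %) carry no position
   information and are excluded, with elapsed time across them preserved.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| bin width | 0.2 | m | depth averaging; sets ±0.1 m position quantisation |
| CV threshold | 5 | % | homogeneity screen (boundary value counts as homogeneous) |
| ascent window | 04:00–09:00 | local clock | when dawn ascents are sought |
| descent window | 16:00–20:00 | local clock | when dusk descents are sought |
| surface band | 1.0 | m | z_MAX ≤ band ⇒ "at the surface" |
| bottom band | 1.0 | m | z_MAX ≥ depth − band ⇒ "at the bottom" |
| window grace | 2.5 | h | bounding profiles may spill this far outside the clock window |

The bands and grace are detection conventions, not physical constants: the
field literature describes surface residence in the top 1–2 m and bottom
departures slightly before the nominal window start, so the stricter 1.0 m
band plus one-sampling-interval grace keeps detection deterministic without
missing departures at coarse (≤ 2 h) sampling. The event mean is the
unweighted arithmetic mean of pairwise rates (a duration-weighted variant is
available); maxima are suppressed for events resolved by only two profiles,
where a single segment exists and "maximum" would duplicate the mean.
Calendar days are processed independently: one potential ascent and one
potential descent per day.

Ties in the profile argmax go to the shallowest tied bin (deterministic); a
"nearest previous z_MAX" mode exists but is off by default. The CV uses the
sample (n−1) standard deviation over binned values; both the ddof and the
use of binned rather than raw samples are exposed.

## Synthetic water column

The generator is a continuum stand-in for the bloom: a Gaussian layer
(initial σ = 0.3 m, depth-integrated mass 60 mg m⁻², ~80 µg L⁻¹ peak) in a
6 m column on a 0.05 m grid, advanced every 30 s by first-order upwind
advection plus explicit diffusion with no-flux boundaries. Stability is
enforced as the combined condition v·Δt/Δz + 2K·Δt/Δz² ≤ 1, which is what
actually guarantees positivity of the explicit update (the two conditions
separately do not). Mass is conserved to machine precision by construction.

The layer's center follows the diel schedule: departure from the bottom
hold depth (0.5 m above bottom) at the ascent-window start, upward at
`v_ascend` until the surface hold depth (0.5 m), hold, then downward at
`v_descend` from the descent-window start. Two deliberate modelling choices
depart from the simplest reading of "swim during the window, hold
otherwise":

* **Swimming continues past the window end** until the hold depth is
  reached. Otherwise any speed below ~1.25 m h⁻¹ strands the layer
  mid-column at the window close and the daily trajectory never returns to
  its starting depth.
* **Holds are active depth-keeping, not v = 0.** The population swims back
  toward the layer center with a velocity proportional to displacement
  (full leg speed one layer-width away, capped at the faster leg speed).
  With passive holds, numerical diffusion of the upwind scheme plus
  reflection at the no-flux boundaries piles concentration against the
  nearest wall within hours, moving the chlorophyll maximum 0.4 m off the
  true layer center and biasing recovered rates high — an artifact of the
  discretisation, not of the estimator. Depth-keeping is also the
  biologically standard account of how thin dinoflagellate layers persist
  against mixing. Its equilibrium layer width is √(K·σ/v) ≈ 0.15–0.2 m at
  the defaults.

Diffusivity defaults to 0.1 m² h⁻¹, mid-range for stratified estuarine
interior mixing (10⁻⁵–10⁻⁴ m² s⁻¹). Strong-mixing periods are modelled
separately as "homogeneous episodes" in which the observed column is
replaced by its depth mean, exercising the CV screen.

The observation operator emulates the sonde:

    observed(z) = L_t · conc(z) · ε(z) + background

with L_t a per-cast lognormal biomass factor (default CV 0.3; the
variability Rel_CHL exists to cancel), ε per-depth lognormal sensor noise
(default CV 0.1) and 1 µg L⁻¹ background chlorophyll. All randomness flows
from one seed through three fixed substreams (sensor noise, heterogeneity,
bottle counts), so toggling heterogeneity does not perturb the noise draws —
paired robustness comparisons are exact. Bottle samples draw Poisson counts
of the focal taxon at 40 cells mL⁻¹ per µg L⁻¹ of layer chlorophyll, plus a
depth-uniform background taxon scaled so the focal column biomass fraction
matches the configured dominance (default 0.9, weights 2000 vs 50 pg C
cell⁻¹).

### What the generator does not emulate

Growth and mortality; tidal advection of along-channel gradients;
fluorescence quenching and non-photochemical effects; thermally modulated
swimming; multiple migrating taxa with distinct schedules; irregular cast
timing and upcast/downcast asymmetry. A green recovery test therefore
establishes that the estimator is unbiased under multiplicative
heterogeneity, sensor noise and depth quantisation — not that it is robust
to, say, quenching artifacts or a second migrating species.

### A note on the proxy correlation

With heterogeneity off and low sensor noise, the depth-paired Spearman
correlation between Rel_CHL and relative focal abundance exceeds 0.9 on
synthetic data. With per-cast biomass factors on, the additive background
(which is *not* advected with the bloom patch in the observation model)
breaks exact scale invariance at off-layer depths and the correlation falls
to roughly 0.75–0.85 — bracketing the value reported from field data. The
validation tests use the low-noise configuration, where the proxy's ceiling
is actually testable.

## Numerical conventions

* Depth bins are half-open `[k·w, (k+1)·w)` anchored at 0 m; a sample
  exactly on a bin edge belongs to the deeper bin. Empty bins are missing
  (never interpolated, never zero) and are skipped by the integral, CV and
  argmax.
* Negative calibrated Chl-a is clipped to 0 with a logged warning.
* Calibration is one pooled ordinary-least-squares fit per study (intercept
  included; a through-origin flag exists because the archived calibration
  protocol is ambiguous on this point).
* Spearman p-values switch from the t approximation to exhaustive
  permutation at n ≤ 10; ties get average ranks in both regimes.
* Timestamps carry explicit UTC offsets; naive input is interpreted as
  UTC−4 (the study region's local time) with a warning.
* CSV floats round-trip exactly (`repr` on write, round-trip parser on
  read), so write∘read is the identity and repeated writes are
  byte-identical.

## Known limitations

* The rate estimator quantises position to the bin width; pairwise rates
  inherit ±(bin width)/Δt uncertainty, so sub-0.2 m h⁻¹ differences at
  hourly sampling are not meaningful.
* Event detection with a single global window pair can misread systems
  whose migration timing drifts across days.
* The mean rate weights all segments equally; if sampling intervals vary
  strongly within an event, the duration-weighted variant is the better
  summary.
* The homogeneity screen is a hard threshold; profiles just above it enter
  rate computations at full weight.
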