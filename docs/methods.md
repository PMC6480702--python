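# Methods

This note records the models behind `heattent`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic fixtures do
and do not demonstrate about real field data.

## Units

Heater sizing works in the imperial units the hardware is rated in
(ft², h·ft²·°F/BTU, BTU/h); everything else works in SI/°C. All
conversions are centralized in `heat_sizing` (1 BTU/h = 0.293 W; a
differential converts °C→°F by ×1.8). Printed sizing figures round half
away from zero to the integer; internal math keeps full precision.

## Sizing

`required_heat` implements the steady conduction load Q = ΔT·A/R. The
default tent is 1100 ft² at R = 0.87 with a 17,065 BTU/h (5000 W)
electric heater and a tank-top propane heater delivering
10,000/12,000/15,000 BTU/h on low/medium/high. The air-exchange
interval divides the heat stored in one tent volume of air
(volume · 0.018 BTU/(ft³·°F) · ΔT) by the infiltration loss rate. Two
constants are not fixed by any rating plate and are configurable:

- **tent volume 3400 ft³** — approximates a 7.2 m × 5.4 m gothic tent of
  ~3 m apex height treated as a half-cylinder-like envelope;
- **air volumetric heat capacity 0.018 BTU/(ft³·°F)** — standard air
  near 20 °C.

With those defaults, a 20,000 BTU/h infiltration loss at a 7.2 °F
differential implies an exchange every ≈1.32 min.

## Tent thermal model

One lumped node (interior air + canopy + near-surface soil) with heat
capacity C, default **500 kJ/°C**: air alone is ~112 kJ/°C for a ~93 m³
tent; the multiplier stands in for canopy and soil mass that exchanges
heat on the minutes timescale. Losses are two parallel conductances in
BTU/(h·°F): conduction A/R (1264.4 for the default tent) and
infiltration. The closed-vent infiltration coefficient defaults to the
**calibrated** value 2772.4 = 29,065/7.2 − 1264.4, i.e. chosen so the
full installed capacity holds exactly the 4 °C design differential at
steady state (`calibrate_infiltration` solves this in general). The
open-vent coefficient defaults to 12,000 BTU/(h·°F): large enough that
the interior tracks ambient within a fraction of a degree even against a
2 kW solar gain, while keeping the open-vent time constant (~79 s) safely
above the integration step so explicit Euler remains smooth — an
arbitrarily huge coefficient would model the same physics but force a
much smaller step for nothing.

Integration is explicit Euler, default dt = 10 s (closed-tent time
constant ≈ 235 s, ratio > 20; the step is capped at 60 s). Heaters are
constant sources at their rated output — propane radiant and unthrottled
at its setting, electric switched by the thermostat. The optional solar
gain is a half-sine over 06:00–20:00, peak 2000 W, off by default for
night-only work. Daytime mechanisms like morning greenhouse warming
(observed as a ~2.5 °C transient peak in real tents) are only represented
through this optional term; the simulator makes no claim to reproduce a
particular season's daytime trace.

## Weather generator

Temperature is a skewed diurnal cycle — cosine rise from the daily
minimum (default 06:00) to the maximum (16:00), cosine fall back — plus
AR(1) noise with coefficient 0.9 at a 1-min step (rescaled as φ^step for
other steps) and stationary SD `noise_sd`. Defaults (mean 15 °C,
amplitude 8 °C, RH mean 65% with 20% anti-phase amplitude, SD 0.5 °C)
emulate a late-spring continental-plains grain-filling window. RH is in
exact anti-phase with the noiseless cycle and clipped to [0, 100]; PAR
is a daylight half-sine peaking at 1400 µmol m⁻² s⁻¹. Identical seed and
parameters reproduce the series bit for bit. The generator does not
model fronts, rain, wind or day-to-day persistence — tests passing on it
show the control and analysis logic is correct, not that any particular
field season is reproduced.

## Thermostat

The decision rule is deliberately strict bang-bang: ON when the
differential is strictly below the setpoint, OFF strictly above, retain
at equality (the equality case is unreachable in practice with
continuous readings; retaining is the conservative tie-break). An
optional symmetric hysteresis band (default 0) is provided because real
relays chatter; it is an extension, not the baseline behaviour. Sensor
reads add a uniform error within ±accuracy (a datasheet-style bound,
default ±0.5 °C), quantize to the resolution (default 1/16 °C), and fail
with a configurable per-read probability; a failure freezes the heater
command until a valid reading arrives, mirroring the SENSOR fault state
of the hardware.

The closed-loop simulation polls both sensors and advances the thermal
model every **2 s** during the night (the physical device slept 0.5 s
between iterations; 2 s keeps per-poll overshoot of an oversized heater
well under the log resolution while running three simulated nights in
under a second) and coasts at 10 s steps during the day with heaters off
and vents open. Logging defaults to one record per 60 s — fine enough to
resolve heater cycling — in the device dialect: headerless CSV,
temperatures at three decimals, a blank line before each session, one
session per night. `write_log ∘ read_log` is byte-identical.

## Microclimate analytics

Streams of heterogeneous cadence are linearly interpolated onto a common
grid spanning their overlap; grid points whose bracketing source samples
are more than a gap limit apart (default 60 min) stay missing.
Differential statistics use pairwise-complete samples and are flagged
when in-window coverage drops below 80%. The night window is
[19:15, 05:45) local clock by default, matching the field schedule; both
the pooled night mean and per-night means are reported, since "average
differential" is ambiguous between the two. VPD uses the Tetens
saturation form (constants 0.6108 / 17.27 / 237.3, kPa/°C), the agronomy
standard; the constants are module-level and configurable. Interior RH
in the pipeline's HOBO-style export is a statistical stand-in — ambient
RH plus a constant offset (default +15.6%, the elevation a sealed tent
holds over ambient) — not a humidity mass balance.

## Phenotype analysis

QY = (FM′ − Ft)/FM′ and ETR = QY · PAR · 0.84 · 0.5 (0.84 leaf
absorptance, 0.5 PSII share of absorbed quanta). Trial summaries report
per-genotype means ± SE (sd/√n) per treatment and percent reductions;
the grand reduction is emitted both as the unweighted mean of
per-genotype reductions and as the pooled-mean reduction, which differ
whenever control means vary across genotypes — both are labeled rather
than picking one silently.

The treatment-effect test is a within-genotype × replicate permutation
test: the control/stress labels of each paired plot are swapped at
random, the unweighted mean reduction is recomputed, and
p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1). This replaces a split-plot
ANOVA by design: it needs no variance-component assumptions, respects
the pairing, and is exactly calibrated under the null (verified at
α = 0.05 over 1000 null trials).

The synthetic trial generator draws 12 genotypes × 2 treatments × 3
replicates: control yield means uniform on 250–450 g/m² (the magnitude
of winter-wheat plot yields), per-genotype true reductions spanning
6.9–41.4% with the extremes planted exactly and the remainder
Beta-distributed so the population mean reduction is exactly 20.3%, and
unit-mean log-normal replicate noise with CV 0.1 (yields stay positive,
expectations stay unbiased). ETR columns follow the same recipe with
flag-leaf reductions on 0.5–14.3% and spike reductions on 5.7–19.4%.
These settings emulate the magnitude and spread of a real HNT trial;
individual genotype values from any particular field year are not
targets.

## Pipeline

`run_experiment` executes weather → controller → analysis (→ optional
trial) from one YAML config. Every data artifact is stamped (comment
line or manifest) with a 12-hex config hash and the seed; identical
config + seed yields byte-identical data artifacts. The closed-vent
infiltration coefficient is auto-calibrated to the setpoint from the
installed capacity unless given explicitly
(`thermal.calibrate_to_setpoint: false` or an explicit
`infiltration_ua_closed` disables this).

## Problem sizes

Default study sizes keep everything desk-scale: 1–3 simulated days of
weather at 1-min resolution, nights polled at 2 s, trial recovery
studies of 200 seeded trials, and permutation-test calibration over 1000
null trials at 199 permutations each (vectorized over permutations).

## Known limitations

- Single thermal node: no spatial gradients, so multi-sensor "heat
  distribution" differences within a tent can only come from sensor
  error models, not physics.
- No humidity or CO₂ mass balance; interior RH is an offset model.
- The open-loop shortfall seen in real systems (a ~3.2 °C achieved mean
  against a 4 °C target) mixes heater undersizing, sensor error and
  control lag; the simulator exposes each knob (heater capacity,
  `SensorSpec`, poll/log intervals) but asserts no canonical
  decomposition — an undersized-heater configuration is provided as a
  calibration fixture, not as a reproduction of any field season.
- A sealed-tent "volume-only" heating figure sometimes quoted for such
  systems is not computed: it depends on a volume and air-constant
  convention that is not fixed by the physics above, and no operation
  here needs it.
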