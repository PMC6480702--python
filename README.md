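# heattent

Desk-scale simulator and analysis toolkit for **field heat-tent experiments
that impose high night-time temperature (HNT) stress** on crop plots.

Rising nocturnal minimum temperatures cut grain yield more sharply than
daytime warming, and field phenotyping of this stress relies on plastic
heat tents placed over plots and heated at night to a fixed differential
above ambient. `heattent` reproduces such a cyber-physical system end to
end, in software: the heater-sizing physics, the diurnal weather the
controller must track, a lumped heat-balance model of a tent, the
differential bang-bang thermostat with its exact CSV logging dialect, the
microclimate statistics computed from the sensor streams, and the
genotype × treatment phenotype analysis of the resulting trial. Its
audience is anyone designing, tuning or teaching such a system — or
validating analysis code against known ground truth before pointing it at
field data.

## The model in brief

**Sizing.** The conductive heating load to hold a differential ΔT (°F)
across a covering of area A (ft²) and thermal resistance R is

    Q = ΔT · A / R        [BTU/h],   1 BTU/h = 0.293 W.

A tent that is not airtight also loses heat to air infiltration; the
installed capacity minus Q is the infiltration budget, and one tent
volume of warmed air divided by that budget gives the implied
air-exchange interval.

**Tent thermal model.** A single lumped node obeys

    C dT_in/dt = Q_heaters − (UA_cond + UA_inf)(T_in − T_out) [+ Q_solar],

with UA coefficients in BTU/(h·°F) converted internally, integrated by
explicit Euler at a step small against the time constant C/UA.

**Control.** The thermostat polls an interior and an exterior sensor and
switches the electric heater fully ON when T_in − T_out is strictly below
the setpoint (default 4 °C) and fully OFF strictly above it; at exactly
the setpoint the previous command is retained. Invalid readings raise a
SENSOR condition that freezes the heater command. Logs are headerless
CSV rows `timestamp,indoor,outdoor,status`, with a blank line delimiting
each session.

**Analytics.** Interior−exterior mean differentials by night/day window,
stream alignment across heterogeneous cadences (1-min controller log vs
15-min HOBO-style logger), vapor pressure deficit via the Tetens form
`es(T) = 0.6108·exp(17.27T/(T+237.3))`, diurnal profiles, the
chlorophyll-fluorescence quantities `QY = (FM′ − Ft)/FM′` and
`ETR = QY · PAR · 0.84 · 0.5`, per-genotype yield reductions with
standard errors, and a within-genotype permutation test for the
treatment effect.

## Worked example

```sh
$ heattent size
conductive load Q = 9103 BTU/h (2667 W)
installed capacity = 29065 BTU/h
infiltration budget = 19962 BTU/h
air exchange interval = 1.32 min
```

Holding a 4 °C (7.2 °F) differential across an 1100 ft², R = 0.87 tent
takes 9103 BTU/h of conduction alone, but the electric heater plus the
propane heater on medium (29,065 BTU/h installed) leave ~20,000 BTU/h to
cover infiltration — equivalent to a complete air exchange every 1.3
minutes.

```python
import heattent as ht

w = ht.generate_weather(seed=21, n_days=1, noise_sd=0.2)
run = ht.run_controller(w, ht.TentSpec(), ht.ThermalParams(), ht.ControlConfig(),
                        ht.SensorSpec(accuracy=0, resolution=0),
                        ht.SensorSpec(accuracy=0, resolution=0), seed=21)
print(f"night mean differential: {run.mean_night_differential():.2f} C")
print(f"heater duty cycle: {run.night_duty_cycle():.2f}")

table = ht.generate_synthetic_trial(seed=21)
s = ht.summarize_trial(table)
p = ht.permutation_treatment_test(table, n_perm=999, seed=21)
print(f"mean reduction: {s.mean_reduction_pct:.1f}% "
      f"(pooled {s.pooled_reduction_pct:.1f}%), p = {p:.4f}")
```

prints

```
night mean differential: 3.93 C
heater duty cycle: 0.95
mean reduction: 22.6% (pooled 22.8%), p = 0.0010
```

— the calibrated tent holds ~3.9 °C of its 4 °C target over the night
(start-up transient included) with the electric heater cycling 95% of
the time, and one synthetic 12-genotype trial shows a clearly significant
~22% mean yield reduction under HNT (population mean 20.3%).

The full pipeline — weather → controller → microclimate summary →
phenotype trial — runs from a YAML config via
`heattent report --config cfg.yaml --seed 7 --out outdir`, writing a
bundle whose data artifacts are byte-identical for identical
config + seed.

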