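# commutair

Low-cost optical particle counters (OPCs) mounted on buses can map urban
particulate matter (PM2.5/PM10) at high spatial and temporal resolution —
but only after their humidity-confounded readings are calibrated against
reference instruments, and only if the resulting concentration fields are
turned into quantities a commuter can act on: the dose they inhale on a
trip, the exhaust PM their transport choice emits, and the route that
minimises their exposure. `commutair` implements that full chain for
researchers and practitioners in exposure assessment:

* **Regression calibration** of a sensor against a reference, with the
  sensor as response: `PM_sensor = a·PM_ref + b` (SLR) and multilinear
  variants adding temperature and/or relative humidity; correction inverts
  the fitted equation.
* **κ-Köhler humidity correction.** Hygroscopic particles swell with water
  uptake, so an OPC sampling humid air overshoots the dry mass by the
  growth factor

  ```
  m/m0 = 1 + (ρw/ρp) · κ / (1/aw − 1),      aw = RH/100
  ```

  κ is estimated as the slope of the *humidogram* (sensor/reference ratio
  binned over RH) and the correction divides the wet reading by the
  modelled growth factor. A diagnostic recommends κ-Köhler only when the
  humidogram shows a clear exponential rise with RH, and plain MLR
  otherwise.
* **Inhaled dose** per trip: `D = PM_out × I/O × t × IR`, with
  mode-specific cabin indoor/outdoor ratios and inhalation rates.
* **Per-passenger emissions**: `E = EF × d / p` over an emission-factor
  table stratified by vehicle, fuel and Euro standard.
* **Mapping and routing**: aggregation of georeferenced records into metric
  concentration grids, and Dijkstra routing under a `fastest` or
  `avoid_pollution` (minimum inhaled dose) objective.
* **Synthetic campaigns**: generators for co-location and paired
  indoor/outdoor bus-trip data with the statistical structure the pipeline
  assumes, so every stage is testable without field data.

The calibration and humidity-correction cores are scikit-learn style
estimators (`SensorCalibrator`, `KappaHumidityCorrector`) that compose with
sklearn pipelines; everything is also reachable through plain functions and
the `commutair` command-line tool (`simulate`, `calibrate`, `correct`,
`map`, `dose`, `emissions`, `route`).

## Worked example

```python
import commutair as ca

# inhaled dose over the packaged instrumented bus campaign
config = ca.load_config()
trips = ca.trips_from_frame(ca.load_bus_trip_table())
results = ca.trip_dose_table(trips, config.inhalation, config.io_ratios)
for r in results[:3]:
    print(f"{r.route_id:32s} {r.start_label:7s} "
          f"PM2.5 {r.dose_pm25:5.1f} ug   PM10 {r.dose_pm10:5.1f} ug")

# humidity correction on a synthetic 14-day co-location
ambient = ca.simulate_ambient(ca.AmbientScenario(seed=1))   # 14 days at 1-min steps
response = ca.SensorResponseModel(kappa_true=0.4, noise_relative=0.10)
sensor = ca.simulate_sensor(ambient["pm25"].to_numpy(), ambient["rh"].to_numpy(),
                            response, seed=42)
humidogram = ca.build_humidogram(sensor, ambient["pm25"].to_numpy(),
                                 ambient["rh"].to_numpy())
model = ca.fit_kappa(humidogram)
corrected = ca.correct_humidity(model, sensor, ambient["rh"].to_numpy())
before = ca.comparison_stats(ambient["pm25"].to_numpy(), sensor)
after = ca.comparison_stats(ambient["pm25"].to_numpy(), corrected)
print(f"kappa_hat = {model.kappa:.3f}")
print(f"slope {before.slope:.2f} -> {after.slope:.2f},  "
      f"R2 {before.r_squared:.2f} -> {after.r_squared:.2f}")
```

prints

```
Restauradores-Oriente            8 a.m.  PM2.5  12.5 ug   PM10  49.1 ug
Restauradores-Moscavide          8 a.m.  PM2.5   9.2 ug   PM10  43.6 ug
Restauradores-Moscavide          8 p.m.  PM2.5   8.2 ug   PM10  25.7 ug
kappa_hat = 0.397
slope 1.50 -> 1.00,  R2 0.62 -> 0.96
```

The first block is the measured-cabin dose of a two-way bus trip (cabin
mean × travel time × bus inhalation rate 0.76 m³ h⁻¹): a morning
Restauradores–Oriente commuter inhales about 12.5 µg of PM2.5. The second
block shows the humidity pipeline on data whose generating hygroscopicity
is κ = 0.4: the estimate lands at 0.397, and drying the readings restores
the sensor-vs-reference slope from 1.50 (wet overshoot) to 1.00 while
raising R² from 0.62 to 0.96.

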