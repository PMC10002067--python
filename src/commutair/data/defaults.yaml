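# Default configuration: inhalation rates per transport mode (m^3 h^-1),
# cabin indoor/outdoor ratios per size fraction, exhaust PM emission factors
# (g km^-1) stratified by vehicle / fuel / Euro standard, and correction
# settings for the humidity pipeline.  Values are the deployment defaults of
# the exposure model; update them as better measurements become available.
inhalation_rates:
  bicycle: 1.41
  car: 0.71
  bus: 0.76
  motorcycle: 0.94
  walking: 1.15

io_ratios:
  bus: {pm25: 2.10, pm10: 2.50}
  car: {pm25: 0.96, pm10: 0.93}
  motorcycle: {pm25: 1.0, pm10: 1.0}
  bicycle: {pm25: 1.0, pm10: 1.0}
  walking: {pm25: 1.0, pm10: 1.0}

emission_factors:
  - {vehicle: car, fuel: petrol, euro: Euro 5, ef: 0.00061}
  - {vehicle: car, fuel: diesel, euro: Euro 5, ef: 0.00025}
  - {vehicle: car, fuel: electric, euro: "-", ef: 0.0}
  - {vehicle: bus, fuel: biodiesel, euro: Euro 5, ef: 0.03138}
  - {vehicle: bus, fuel: diesel, euro: Euro 5, ef: 0.03138}
  - {vehicle: bus, fuel: electric, euro: "-", ef: 0.0}
  - {vehicle: bus, fuel: CNG, euro: Euro 5, ef: 0.01}
  - {vehicle: motorcycle, fuel: petrol, euro: Euro 5, ef: 0.00297}

occupancy:
  bus: 50
  car: 1
  motorcycle: 1

correction:
  method: auto          # kohler | mlr | auto
  rho_w: 1.0            # water density, g cm^-3
  rho_p: 1.65           # assumed particle density, g cm^-3
  aw_cap: 0.95          # water-activity cap near saturation
  rh_bin_width: 2.0     # humidogram bin width, % RH
  min_bin_count: 10     # minimum samples per retained humidogram bin
  tendency_margin: 0.1  # R^2 margin for recommending the kappa correction
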