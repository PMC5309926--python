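# Bundled demonstration: one temperature-anchored (niche-conservative) and
# one latitude-anchored (niche-plastic) synthetic taxon under the default
# cooling (1959-1984) then warming (1984-2008) scenario.  Matches
# nichetrack.pipeline.demo_config().
seed: 76542
scenario:
  base_temp: 12.0
  reference_latitude: 54.5
  lat_gradient: 0.4          # degC per degree latitude, cooler northwards
  trend_segments:
    - [1954, 1959, 0.0]
    - [1959, 1984, -0.03]    # cooling, degC per year
    - [1984, 2008, 0.04]     # warming
    - [2008, 2014, 0.0]
  seasonal_amplitude: 1.0
  noise_sd: 0.2
  seed: 76542
sampling:
  n_tows_per_year: 2000
  route_style: random
  seed: 76543
taxa:
  - name: conservative_tracker
    niche_mode: conservative
    thermal_optimum: 12.0
    thermal_sd: 1.0
    peak_month: 8
    peak_width: 1.5
    mean_log_abundance: 3.0
    seed: 76553
  - name: plastic_resident
    niche_mode: plastic
    home_latitude: 54.5
    home_sd: 2.5
    peak_month: 8
    peak_width: 1.5
    mean_log_abundance: 3.0
    seed: 76554
isotherm_temps: [11.0, 12.0, 13.0]
sst_grid_step: 1.0
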