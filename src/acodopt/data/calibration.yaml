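# Default calibration of the synthetic digestion-experiment generator.
#
# The additive main-effect profiles below (grand mean + per-factor level
# means, raw response scale) set the true nine-run means of the generated
# L9 experiment; they are calibrated to the screening study's observed run
# means so the synthetic and packaged fixtures share shape.  Kinetic-shape
# and noise constants are the generator's own phenomenological choices.
responses:
  bgp_ml_per_gvs:
    grand_mean: 131.995556
    level_means:
      A: [106.913333, 178.85, 110.223333]
      B: [182.503333, 164.603333, 48.88]
      C: [93.16, 160.103333, 142.723333]
      D: [180.8, 100.646667, 114.54]
  bmp_ml_per_gvs:
    grand_mean: 65.988889
    level_means:
      A: [52.226667, 88.163333, 57.576667]
      B: [91.216667, 78.55, 28.2]
      C: [44.77, 84.496667, 68.7]
      D: [89.333333, 50.453333, 58.18]
  cods_removal_pct:
    grand_mean: -22.843333
    level_means:
      A: [-105.953333, 11.863333, 25.56]
      B: [72.033333, 5.003333, -145.566667]
      C: [19.143333, -44.91, -42.763333]
      D: [15.056667, -45.92, -37.666667]

kinetics:
  # Gompertz max rate Rm as a fraction of the plateau P per day, by
  # temperature level (faster fermentation at higher temperature).
  rate_frac_per_level_B: [0.07, 0.10, 0.13]
  # Lag phase in days by sonication level; level 3 is the untreated
  # (0 min) control, hence the longest lag.
  lag_days_per_level_C: [4.0, 2.5, 6.0]
  # TAN release plateau model: tan_max = tan_base + tan_per_ts * TS%
  #                       + tan_per_degC * (T - 36) + tan_per_cm * (100 - ORWW%)
  tan_base: 800.0
  tan_per_ts: 140.0
  tan_per_degc: 25.0
  tan_per_cm: 8.0
  tan_tau_days: 8.0
  # TVFA plateau for inhibited runs and transient peak for healthy runs.
  tvfa_inhibited_max: 14000.0
  tvfa_healthy_peak: 3000.0
  tvfa_healthy_floor: 500.0
  # Acid profile fractions (acetic, propionic, butyric, valeric).
  vfa_fracs_healthy: [0.55, 0.18, 0.17, 0.10]
  vfa_fracs_inhibited: [0.30, 0.45, 0.15, 0.10]

noise:
  # Replicate coefficients of variation (multiplicative lognormal) for the
  # positive-scale responses; additive sd in percent points for the
  # COD-removal rate, whose inhibited runs cross zero.
  bgp_cv: 0.05
  bmp_cv: 0.08
  cods_sd: 12.0
  # Measurement noise on generated kinetic series.
  kinetics_cv: 0.03
  ph_sd: 0.05
  temp_sd: 0.3
  # Observation noise on the ANN targets (biogas yield precise, methane
  # content less so).
  ann_bgp_cv: 0.02
  ann_bmp_cv: 0.05

schedule:
  max_days: 60
  min_days: 20
  ann_sample_every_days: 2
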