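"""Parameter recovery: do the mixed models give back the generating slopes?

Replicates the whole synthetic study and refits the speed and frequency
models each time.  With mode="video" every replicate goes through camera
projection, calibration, triangulation and smoothing; mode="truth" (used
here for speed) skips the videogrammetry and checks the statistical stage.
"""

from escapeflight import GroundTruthParams, recovery_study

params = GroundTruthParams()
df = recovery_study(params, n_replicates=25, seed=0, mode="truth")

truth = {
    "loading_slope": params.speed_loading_slope,
    "day_slope_control": params.speed_day_slope_by_treatment["control"],
    "freq_day_slope": params.freq_day_slope,
}
print(f"{len(df)} replicates of the 18-bird study\n")
print(f"{'estimate':20} {'mean':>9} {'sd':>8} {'truth':>8}")
for col, true_val in truth.items():
    print(f"{col:20} {df[col].mean():9.4f} {df[col].std():8.4f} "
          f"{true_val:8.4f}")
print("\nMeans sit on the generating values; the per-replicate sd is the "
      "sampling noise\nof an 18-bird experiment, not estimator bias.")
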