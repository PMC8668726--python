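"""Generate the synthetic study cohort and trial schedule.

18 great tits, 3 per sex x treatment cell (control / 0.9 g / 1.2 g tag),
tested on days 1, 7, 14 and 28 after tagging with 5 escape flights per day.
"""

import numpy as np

from escapeflight import (GroundTruthParams, disk_loading, generate_cohort,
                          simulate_trials)

params = GroundTruthParams()
cohort = generate_cohort(params)
trials = simulate_trials(cohort, params)

print(f"{len(cohort)} birds, {len(trials)} trials\n")
print(f"{'bird':8} {'sex':7} {'treatment':12} {'mass g':>7} {'b_max m':>8} "
      f"{'W/A N/m2':>9}")
for b in cohort[:6]:
    wa = disk_loading(b.body_mass_day1_g * 1e-3, b.wingspan_bmax_m)
    print(f"{b.bird_id:8} {b.sex:7} {b.treatment:12} "
          f"{b.body_mass_day1_g:7.2f} {b.wingspan_bmax_m:8.4f} {wa:9.2f}")
print("...\n")

for sex in ("female", "male"):
    wa = [disk_loading(b.body_mass_day1_g * 1e-3, b.wingspan_bmax_m)
          for b in cohort if b.sex == sex]
    print(f"mean fictive disk loading, {sex}s: {np.mean(wa):.2f} N/m^2")

speeds = np.array([t.true_speed for t in trials])
print(f"\ntrue escape speeds: {speeds.mean():.2f} +/- {speeds.std():.2f} m/s")
print("(the analysis pipeline has to recover these from pixel tracks)")
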