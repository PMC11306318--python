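"""Compute the H₂S exposure index for one worker-day of detector readings.

A personal electrochemical detector samples every 15 s.  The index rewards
what a time-weighted average hides: short peaks.  Each excursion (a maximal
run of readings at or above the 0.1 ppm floor) counts in every concentration
band its peak reaches, minutes in band are added, and so is the daily
maximum.
"""

from h2sindex import (
    DATASET_BC_CONSTANTS,
    GasLog,
    band_profile,
    compute_index,
    compute_twa,
    detect_excursions,
    exceeds_ceiling,
)

# an 8-minute window: background zero, a brief 12-ppm spike while opening a
# manhole, and a smaller 2-ppm tail
readings = [0.0] * 8 + [2.1, 7.4, 12.0, 6.3, 1.8] + [0.0] * 10 + [2.0] + [0.0] * 8
log = GasLog.from_ppm(readings, person_id="WN007")

excursions = detect_excursions(log)
profile = band_profile(log, mode="cumulative")
index = compute_index(profile)
twa = compute_twa(log, DATASET_BC_CONSTANTS)

print(f"readings:            {len(log)} at 15 s")
print(f"excursions:          {len(excursions)} "
      f"(peaks {[e.peak_ppm for e in excursions]} ppm)")
print(f"peak counts:         0.1-1: {profile.h2s01}  1.1-5: {profile.h2s1}  "
      f"5.1-10: {profile.h2s5}  >10: {profile.h2s10}")
print(f"minutes 0.1-5 ppm:   {profile.duration01_min:.2f}")
print(f"minutes >5 ppm:      {profile.duration5_min:.2f}")
print(f"daily maximum:       {profile.max_ppm:.1f} ppm")
print(f"ceiling (10 ppm) exceeded: {exceeds_ceiling(log)}")
print(f"H2S index:           {index:.2f}   (unitless daily risk score)")
print(f"8-h TWA:             {twa:.5f} ppm  (far below the 5 ppm OEL -")
print("                     the TWA alone would call this day harmless)")
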