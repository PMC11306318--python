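"""Render what three sampling strategies observe on the same latent cohort.

A = expert campaign (small targeted subset, LOD 0.1 ppm),
B = routine self-assessed collection (weekly docking + alarms; the 16-h
    wraparound memory loses un-docked days; LOD 1.6 ppm),
C = daily campaign collection (every worn day in three 2-week periods,
    LOD 1.6 ppm, logbooks attached).

Strategies only select and censor days — concentrations are never altered —
so any difference below is pure observation design.
"""

from h2sindex import (
    STRATEGY_A,
    STRATEGY_B,
    STRATEGY_C,
    SimParams,
    apply_strategy,
    simulate_latent_cohort,
    summarize_dataset,
)

params = SimParams(
    n_persons={"wastewater_network": 10, "treatment_plant": 6,
               "pumping_station": 3, "water_network": 6},
    study_weeks=32,
    seed=7,
)
latent = simulate_latent_cohort(params)
print(f"latent person-days: {len(latent)}\n")

print(f"{'':12}{'measured':>9}{'detect%':>9}{'CV%':>7}{'>20ppm%':>9}")
for strat, seed in ((STRATEGY_A, 1), (STRATEGY_B, 2), (STRATEGY_C, 3)):
    ds = apply_strategy(latent, strat, seed=seed)
    meas = [d for d in ds.days if d.status.status == "measured"]
    det = sum(d.profile.max_ppm > 1.6 for d in meas)
    cv = sum(d.cv_exceeded for d in meas)
    high = sum(d.profile.max_ppm > 20.0 for d in meas)
    print(f"strategy {strat.label:3}{len(meas):>9}{100*det/len(meas):>8.0f}%"
          f"{100*cv/len(meas):>6.0f}%{100*high/len(meas):>8.1f}%")

print("\nThe expert campaign (A) finds the highest peaks but covers few days;")
print("routine docking (B) loses most un-docked days yet always keeps alarm")
print("days; daily campaign collection (C) gives the most complete picture")
print("of ordinary exposure below the 10 ppm ceiling.")
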