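# h2sindex

Characterization of occupational hydrogen sulfide (H₂S) exposure from
personal gas-detector logs.

## The problem

H₂S in water and wastewater work is a *peak* hazard: workers spend most
days at zero, then meet a short excursion in a manhole or a pump sump that
can exceed the 10 ppm ceiling value (CV) within seconds.  The conventional
8-h time-weighted average (TWA) against the 5 ppm occupational exposure
limit averages these peaks into invisibility — H₂S does not follow Haber's
law, so concentration × time is the wrong risk currency.  Personal
electrochemical alarm detectors that log concentration every 15 s make a
peak-sensitive characterization possible.

This package is for occupational hygienists and exposure modellers.  It
turns raw detector logs and worker logbooks into per-day exposure records,
daily **H₂S index** values, study-level summaries under different sampling
strategies, and a worker-random-effect variance decomposition.

## The index

For one worker-day, with excursions defined as maximal runs of readings at
or above the 0.1 ppm detection floor,

```
index = 0.1·H₂S₀₁ + 0.1·Duration₀₁ + 1·H₂S₁ + 5·H₂S₅ + 5·Duration₅ + 10·H₂S₁₀ + H₂Sₘₐₓ
```

where H₂S₀₁/H₂S₁/H₂S₅/H₂S₁₀ count peaks reaching the 0.1–1.0, 1.1–5.0,
5.1–10.0 and >10 ppm bands, Duration₀₁/Duration₅ are minutes spent in
0.1–5.0 ppm and above 5.0 ppm, and H₂Sₘₐₓ is the daily maximum (ppm).  By
default an excursion counts in *every* band its peak reaches (the
"cumulative" convention); a "max_band" option counts only the highest band.
Days with no reading at the instrument's limit of detection (LOD) are
left-censored and imputed with the lowest attainable index at the LOD
divided by √2 — 1.927 for the 1.6-ppm-LOD alarm detectors at 15-s sampling.

On top of the per-day records the package provides:

* **Cohort assembly** — aggregation to one record per person-day, weekend
  zero-day rules, real-zero vs missing classification against a work-log
  roster, summary tables, and the decade-scaled daily-maximum histograms.
* **Variance-components model** — `log(index) ~ SEG + season + (1|worker)`
  by REML (statsmodels MixedLM), −2·log-likelihood model comparison,
  back-transformed cell means with 95% CIs, and a seeded split-half
  robustness procedure (50% ± 2.5% overall, 50% ± 3.5% per SEG).
* **Synthetic cohorts** — a generator for sporadic, log-normal-peaked
  exposure with real-zero/missing days, and operators that render what an
  expert campaign (A), routine self-assessed collection with weekly docking
  and 16-h wraparound memory (B), or daily campaign collection (C) would
  observe from the same latent days.

## Worked example

```python
from h2sindex import (GasLog, band_profile, compute_index, compute_twa,
                      detect_excursions, DATASET_BC_CONSTANTS)

readings = [0.0]*8 + [2.1, 7.4, 12.0, 6.3, 1.8] + [0.0]*10 + [2.0] + [0.0]*8
log = GasLog.from_ppm(readings, person_id="WN007")

profile = band_profile(log, mode="cumulative")
print(len(detect_excursions(log)))                  # 2
print(profile.h2s10, profile.max_ppm)               # 1 12.0
print(round(compute_index(profile), 2))             # 33.02
print(round(compute_twa(log, DATASET_BC_CONSTANTS), 5))  # 0.01646
```

Two excursions, one of them crossing the 10 ppm ceiling, give an index of
33.02 — while the 8-h TWA of the same day is 0.016 ppm, three hundred times
below the exposure limit.  That gap *is* the argument for peak-sensitive
surveillance.

The `examples/` directory holds one narrative script per capability
(`01_daily_index.py` … `05_logbook_cleaning.py`); each builds a small input,
runs the method and explains the numbers it prints.  A thin CLI wraps the
same functions for batch use:

```sh
h2sindex simulate --seed 7 --out sim/ --weeks 8
h2sindex index --gaslog sim/gaslog.csv --logbook sim/logbook.csv --out daily/
h2sindex compare daily/daily_exposure.csv other/daily_exposure.csv --out cmp/
h2sindex model --daily daily/daily_exposure.csv --out model/ --seed 3
```

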