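# Methods

## The exposure model

H₂S exposure in water/wastewater work is modelled as a per-day point
process of short excursions riding on a zero baseline.  A personal
electrochemical detector samples instantaneous concentration every 15 s at
0.1 ppm resolution over a 0.1–100 ppm range; the stored value is the
instant reading, not an interval mean, so each reading is treated as
representing one full sampling interval when durations and TWAs are
computed.

An **excursion** is a maximal run of consecutive readings at or above the
0.1 ppm detection floor.  A dip below the floor for at least one reading
ends the excursion; dips *within* a band (e.g. 12 → 6 → 12 ppm) do not
create extra peaks in the upper band.  This is the simplest rule consistent
with counting "peaks in an interval", and it makes the count well defined
on noisy traces.  Runs never join across a transfer gap longer than the
zero-refill limit (below).

The daily **index** is

    0.1·n01 + 0.1·dur01 + 1·n1 + 5·n5 + 5·dur5 + 10·n10 + max

with band counts n01/n1/n5/n10 for peaks reaching 0.1–1.0, 1.1–5.0,
5.1–10.0 and >10 ppm, minutes dur01 in 0.1–5.0 ppm, minutes dur5 above
5.0 ppm, and the daily maximum in ppm.  Two counting conventions exist:

* **cumulative** (default): an excursion increments every band its peak
  reaches.  This convention reproduces the published below-LOD imputation
  constant 1.927 = (0.1 + 0.025 + 1 + 1.6)/√2 for a single 1.6-ppm reading
  at 15-s sampling, and is therefore the default.
* **max_band**: an excursion increments only its highest band (same single
  reading gives 2.625, imputation constant 1.856).

Both are retained because the published "lowest possible index when the
ceiling is exceeded, 21.4" is closer to the max_band computation (21.35)
than to the cumulative one (27.45); the conventions genuinely disagree and
the choice is recorded in output metadata.  The index is deliberately
peak-count sensitive; as a consequence it is **not monotone** under run
merging — filling the gap between two excursions replaces two counted peaks
by one, which can lower the value more than the added duration raises it.
The property suite documents this explicitly and asserts the true
monotonicity (raising an already-detected reading never lowers the index).

Band membership is decided on half-grid edges (0.05, 1.05, 5.05,
10.05 ppm) so that 0.1-resolution readings never sit on a boundary;
reports print the conventional edges.  Ceiling exceedance (>10 ppm) is
strict: a 10.0 ppm maximum does not exceed, 10.1 does.  Readings flagged
as instrument overload enter all metrics as 100 ppm and are reported in a
separate "above 100 ppm" bin.

**TWA** uses a fixed 480-min denominator regardless of log span, because
the reference quantity is the 8-h shift average the instrument itself
displays.  Alarm-only datapoints (a maximum stored by the alarm slot
without a surrounding log) carry no duration: they contribute to the daily
maximum and ceiling flag but not to durations or the TWA.  The TWA of an
empty log is undefined (an error), not zero.

## Parsing and cleaning

Gas-log CSVs (`person_id,device_id,timestamp,ppm,flag`) may omit all-zero
stretches (the storage unit skips zero intervals at transfer).  Gaps up to
4 h are reinstated as explicit zeros; longer gaps split the log into
segments, since a longer silence is more plausibly a shift break than a
zero-skip.  The 4-h limit is a package choice — the transfer behaviour is
documented, shift schedules are not.

Logbook durations were frequently written as end times.  The codified
rule: a raw value that parses as a clock time later than the task start,
or that read as minutes would exceed 12 h or cross midnight, is
reinterpreted as an end time; every reinterpretation is flagged on the
task record so audits can diff the corrections.  Entries covering a date
range are expanded one record per date.  Weekend/holiday measurement days
with only below-LOD readings are dropped unless the person also has an
activity registration.  Person-days with neither sensor nor logbook data
are classified against a work-log roster: absence reasons (sick leave,
holiday, education, union work, compensation days) give *confirmed real
zero*; anything else is *missing data*.

## Censoring and imputation

A measured day with no reading or alarm at the LOD is left-censored; its
pre-imputation index is 0 (sub-LOD readings are not trusted as
measurements).  Censored measured days receive the imputation constant
lowest-index-at-LOD/√2 (1.927 at LOD 1.6 ppm/15 s; 0.200 + 0.1·t/60 at
LOD 0.1 ppm before division, which depends on the unstated logging
interval t of those instruments and is therefore not asserted as a
reproduction target).  Confirmed real-zero days are never imputed: they
stay in descriptive tables but are excluded from the model frame.

## Variance-components model

Daily index values are modelled on the log scale (default) as

    log y_ij = μ + SEG_i + season_j + b_i + e_ij,
    b_i ~ N(0, σ²_B),  e_ij ~ N(0, σ²_W)

fitted by REML via statsmodels MixedLM.  The log transform is the default
because index values are positive and right-skewed and published cell
means carry asymmetric confidence intervals; a raw-scale option is
retained.  Cell means are fixed-effect linear combinations with Wald 95%
CIs using normal quantiles, symmetric on the model scale and exponentiated
(hence asymmetric) when the response is logged.  Normal quantiles are the
simplest defensible default; they undercover by a point or two in small
designs (t-quantiles would be the refinement).  Model comparison reports
the difference of −2·log-likelihood (smaller is better).  When the
compared models differ in *fixed* effects, fits should use `reml=False`,
since REML likelihoods are not comparable across fixed-effect structures;
the comparison refuses models fit to different response vectors.  Rows
lacking factor metadata (e.g. days without a logbook, hence no SEG) are
dropped with a logged count before fitting.  Degenerate boundary fits
(between-worker variance ≈ 0) fall back to a derivative-free optimizer.

The split-half robustness procedure assigns each positive measurement to a
half by a fair coin flip and redraws until each half holds 50% ± 2.5% of
all datapoints and 50% ± 3.5% within every SEG, reporting the number of
draws; a SEG too small to satisfy its tolerance (e.g. a single datapoint)
is detected up front and named.  Splits are reproducible from the seed and
always re-checked by an independent verifier.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular deposited
dataset.  Defaults: 60 workers in four similar-exposure groups (24
wastewater network, 15 treatment plant, 6 pumping stations, 15 water
network); 32 study weeks of 5-day workweeks on an 8-h shift (1920 readings
at 15 s); per-day real-zero probability 0.23 and missing probability 0.11;
logbook reporting rate 0.81; per-SEG exposure probabilities 0.55–0.65.
Exposed days carry a zero-truncated Poisson (mean 1.5) number of
excursions with truncated-geometric lengths on 1–15 readings (most are a
single reading; 15 readings ≈ 4 min) and log-normal peak heights
(μ = 2.0, σ = 0.55 on the log scale) scaled by a per-worker log-normal
effect (SD 0.4).  These peak parameters were calibrated once, against the
generator's own distribution, so that the daily-maximum mode among
detected days falls in 5–8 ppm and the probability of exceeding the
100 ppm instrument ceiling is small but nonzero (~10⁻⁴); they are config
defaults, not claims about the real process.  Manhole-entry tasks are
generated at per-SEG daily rates whose water-network to wastewater-network
contrast is 18× per worker.

Observation regimes act only by selecting, truncating, or censoring latent
days — never by altering a concentration (a tested invariant):

* **A, expert campaign**: 93 person-day measurements; with probability
  `targeting_bias` (default 0.5) a day is drawn from the exposed pool with
  weight proportional to its true maximum (experts and workers steer
  measurements toward expected hazards), otherwise uniformly. LOD 0.1 ppm.
* **B, routine self-assessed collection**: devices dock weekly and after
  alarms; the 16-h wraparound memory holds two 8-h shifts, so a day's
  readings survive only if a dock happens within two worn days; alarm
  maxima survive regardless as single datapoints. LOD 1.6 ppm.
* **C, daily campaign**: every worn day inside three 2-week campaign
  windows, with logbooks attached. LOD 1.6 ppm.

What passing tests show — and what they do not: the generator is
time-homogeneous (day labels independent, no seasonal or epoch structure
in exposure intensity, Poisson placement of excursions within a shift).
Consequently strategy B's alarm-forced retention *enriches* detected days
relative to C on the same latent cohort; the lower detect fraction the
real routine-collection study observed relative to its daily-campaign
counterpart arose from different exposure epochs (a 5.5-year window
including a pandemic versus a 7-month campaign year), which this generator
deliberately does not model.  Tests therefore assert the mechanism's
faithful consequences (B loses most un-docked days, alarms always survive,
A's targeting yields the highest share of >20 ppm days) rather than
between-dataset contrasts that depend on epoch effects.  Real within-day
clustering of excursions is unknown; Poisson placement is a labelled
stand-in.

## Numerical choices

* Rounding for printed values: half away from zero at the printed
  precision (index 1 decimal, percentages integer, constants 3 decimals).
* Histogram bins over the common detection range (1.6, 100]: width 1/10 of
  the upper decade — (1.6, 2], (2, 3] … (9, 10], (10, 20] … (90, 100] —
  with one bin above 100 ppm and explicit rejection counts for values at
  or below 1.6.  The 10.0 edge closes its bin because it is the ceiling
  value.
* Index-vs-TWA fits are least squares in log10–log10 space, per ceiling
  stratum and pooled, with R²; rows with zero TWA or index are excluded
  and counted.  The fit space is a package choice recorded in output
  metadata.
* Season mapping is meteorological (Dec–Feb winter, …) and overridable,
  since the original season partition is not printed.
* Study workday bookkeeping: study workdays = measurement days × persons;
  study-duration workdays = months × persons × 220/12, rounded half away
  from zero.  Where a study frame counts scheduled person-days that are
  not derivable from days × persons, the frame size is an explicit input.
* Problem sizes in the test suite: the full-scale synthetic comparison
  runs ~10⁴ person-days (60 workers × 32 weeks); parameter-recovery checks
  use 200 replicates of 60 workers × 15 days for the variance fraction and
  one 10⁴-person-day cohort for rates.  These sizes give Monte-Carlo error
  comfortably inside the asserted tolerances.

## Known limitations

* No sensor physics: drift, calibration cycles, bump-check failures and CO
  cross-sensitivity are out of scope.
* Post-hoc characterization only; no real-time alarm logic.
* The mixed model assumes log-normal residuals and a single random
  grouping; with 30–80% of days below the LOD, fixed-value imputation
  makes the cell means descriptive rather than distributional estimates —
  the package computes them for comparability, not as compliance
  statistics.
* Logbook cleaning codifies rules that were originally manual; flagged
  records make the codification auditable but cannot recover the original
  judgement calls.
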